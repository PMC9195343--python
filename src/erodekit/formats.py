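"""Domain types, coordinate conventions, and file I/O.

All internal coordinates are 0-based half-open (BED convention); the only
place 1-based coordinates appear is ``VariantRecord.pos`` and the score
track, both of which follow their on-disk formats (VCF, TSV) and are
converted at the parser boundary.

Soft-masked (lowercase) reference bases are treated as their uppercase
equivalents in all sequence logic; repeat exclusion is driven solely by
explicit repeat BED files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class MalformedIntervalError(ValueError):
    """Raised for an interval with start >= end."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSequence:
    """A named reference sequence over {A,C,G,T,N} (case preserved)."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise ValueError(f"invalid sequence name: {self.name!r}")
        if len(self.bases) < 1:
            raise ValueError(f"empty sequence: {self.name}")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read (merged or paired-end mate) on the reference.

    ``start``/``end`` are 0-based half-open reference coordinates of the
    aligned span; ``is_merged`` marks an overlapping read pair collapsed
    into a single sequence (the standard representation of short ancient
    DNA fragments).
    """

    query_name: str
    ref_name: str
    start: int
    end: int
    strand: str
    mapq: int
    base_qualities: tuple[int, ...]
    is_merged: bool = True
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"alignment {self.query_name}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"alignment {self.query_name}: bad strand {self.strand!r}")
        if any(q < 0 or q > 93 for q in self.base_qualities):
            raise ValueError(f"alignment {self.query_name}: base quality out of [0, 93]")


#: Sentinel for a missing genotype, distinct from homozygous-reference (0, 0).
MISSING_GT = None


@dataclass(frozen=True)
class SampleCall:
    """Per-sample genotype call at one site.

    ``genotype`` is a pair of allele indices into [REF] + ALTs, or ``None``
    for a missing call — never conflated with (0, 0) homozygous reference.
    """

    genotype: tuple[int, int] | None
    dp: int | None = None
    ad: tuple[int, ...] | None = None

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site (1-based ``pos``) with per-sample GT/DP/AD calls."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    site_qual: float | None
    map_qual: float | None
    calls: dict[str, SampleCall]

    def __post_init__(self) -> None:
        if not self.ref_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: empty REF allele")
        n_alleles = 1 + len(self.alt_alleles)
        for sample, call in self.calls.items():
            if call.ad is not None and len(call.ad) != n_alleles:
                raise ValueError(
                    f"{self.chrom}:{self.pos} sample {sample}: AD length "
                    f"{len(call.ad)} != allele count {n_alleles}"
                )
            if call.genotype is not None and any(
                a >= n_alleles for a in call.genotype
            ):
                raise ValueError(
                    f"{self.chrom}:{self.pos} sample {sample}: genotype index "
                    f"out of range"
                )

    @property
    def pos0(self) -> int:
        """0-based position of the site."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) > 1 or any(
            len(a) != len(self.ref_allele) for a in self.alt_alleles
        )


Interval = tuple[str, int, int]


class GenomeIntervalSet:
    """Normalized 0-based half-open genomic intervals.

    After construction the intervals are sorted by (chrom, start) and are
    non-overlapping and non-adjacent within each chromosome.
    """

    __slots__ = ("intervals",)

    def __init__(self, raw: Iterable[Interval] = ()):
        self.intervals: tuple[Interval, ...] = tuple(normalize_intervals(raw))

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomeIntervalSet) and self.intervals == other.intervals
        )

    def __repr__(self) -> str:
        return f"GenomeIntervalSet({list(self.intervals)!r})"

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position (binary search)."""
        import bisect

        keyed = [(c, s) for c, s, _ in self.intervals]
        i = bisect.bisect_right(keyed, (chrom, pos0)) - 1
        if i < 0:
            return False
        c, s, e = self.intervals[i]
        return c == chrom and s <= pos0 < e

    def union(self, other: "GenomeIntervalSet") -> "GenomeIntervalSet":
        return GenomeIntervalSet(list(self.intervals) + list(other.intervals))

    def subtract(self, other: "GenomeIntervalSet") -> "GenomeIntervalSet":
        return subtract_intervals(self, other)

    def intersect(self, other: "GenomeIntervalSet") -> "GenomeIntervalSet":
        # a ∩ b = a \ (a \ b)
        return self.subtract(self.subtract(other))


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def normalize_intervals(raw: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent intervals; preserves covered bases."""
    checked = []
    for iv in raw:
        chrom, start, end = iv
        if start >= end:
            raise MalformedIntervalError(f"interval with start >= end: {iv!r}")
        checked.append((chrom, int(start), int(end)))
    checked.sort()
    merged: list[Interval] = []
    for chrom, start, end in checked:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def subtract_intervals(
    a: GenomeIntervalSet, b: GenomeIntervalSet
) -> GenomeIntervalSet:
    """Bases covered by ``a`` but not by ``b``."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in b:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: list[Interval] = []
    for chrom, s, e in a:
        cuts = by_chrom.get(chrom, [])
        cursor = s
        for cs, ce in cuts:
            if ce <= cursor or cs >= e:
                continue
            if cs > cursor:
                out.append((chrom, cursor, cs))
            cursor = max(cursor, ce)
            if cursor >= e:
                break
        if cursor < e:
            out.append((chrom, cursor, e))
    return GenomeIntervalSet(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> list[ReferenceSequence]:
    records = [
        ReferenceSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences in FASTA {path}")
    return records


def write_fasta(path: str, seqs: Sequence[ReferenceSequence]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs],
        path,
        "fasta",
    )


# ---------------------------------------------------------------------------
# BED (headerless, 3-column, 0-based half-open)
# ---------------------------------------------------------------------------


def read_bed(path: str) -> GenomeIntervalSet:
    raw: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            raw.append((fields[0], int(fields[1]), int(fields[2])))
    return GenomeIntervalSet(raw)


def write_bed(path: str, ivs: GenomeIntervalSet) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in ivs:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# SAM text (via pysam)
# ---------------------------------------------------------------------------


def read_sam(path: str) -> list[AlignmentRecord]:
    """Read mapped records from a SAM text file into AlignmentRecords.

    Unmapped records are skipped at this boundary; secondary/supplementary
    records are kept but flagged non-primary so downstream stages can reject
    them explicitly.
    """
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            quals = tuple(aln.query_qualities) if aln.query_qualities is not None else ()
            out.append(
                AlignmentRecord(
                    query_name=aln.query_name,
                    ref_name=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    base_qualities=quals,
                    is_merged=not aln.is_paired,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                )
            )
    return out


def write_sam(
    path: str, records: Sequence[AlignmentRecord], ref_lengths: dict[str, int]
) -> None:
    """Write AlignmentRecords as minimal SAM text (fully-matching CIGAR)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": l} for n, l in ref_lengths.items()],
        }
    )
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.query_name
            length = rec.end - rec.start
            a.query_sequence = "N" * length
            a.flag = (16 if rec.strand == "-" else 0) | (
                0 if rec.is_primary else 256
            )
            a.reference_id = header.get_tid(rec.ref_name)
            a.reference_start = rec.start
            a.mapping_quality = rec.mapq
            a.cigartuples = [(0, length)]
            if rec.base_qualities and len(rec.base_qualities) == length:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in rec.base_qualities)
                )
            sam.write(a)


# ---------------------------------------------------------------------------
# VCF (via pysam)
# ---------------------------------------------------------------------------


def _gt_from_pysam(gt) -> tuple[int, int] | None:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return None
    if len(gt) == 1:  # haploid call promoted to homozygous diploid
        return (gt[0], gt[0])
    return (gt[0], gt[1])


def read_vcf(path: str) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF into VariantRecords; returns (records, sample names)."""
    records = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = tuple(a for a in (rec.alts or ()) if a not in (".", "<*>"))
            mq = rec.info.get("MQ")
            if isinstance(mq, tuple):
                mq = mq[0] if mq else None
            calls = {}
            for s in samples:
                sc = rec.samples[s]
                ad = sc.get("AD")
                if ad is not None:
                    ad = tuple(0 if x is None else int(x) for x in ad)
                    # pad/trim to allele count (pysam may drop trailing fields)
                    n_all = 1 + len(alts)
                    ad = tuple(list(ad[:n_all]) + [0] * (n_all - len(ad)))
                dp = sc.get("DP")
                calls[s] = SampleCall(
                    genotype=_gt_from_pysam(sc.get("GT")),
                    dp=None if dp is None else int(dp),
                    ad=ad,
                )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    site_qual=rec.qual,
                    map_qual=None if mq is None else float(mq),
                    calls=calls,
                )
            )
    return records, samples


def write_vcf(
    path: str,
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    contigs: dict[str, int],
) -> None:
    """Write VariantRecords as VCF 4.2 text with GT/DP/AD FORMAT fields."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in records:
            alleles = (v.ref_allele,) + v.alt_alleles
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos0, alleles=alleles, qual=v.site_qual
            )
            if v.map_qual is not None:
                rec.info["MQ"] = v.map_qual
            for s in samples:
                call = v.calls.get(s, SampleCall(genotype=None))
                rec.samples[s]["GT"] = (
                    (None, None) if call.genotype is None else call.genotype
                )
                if call.dp is not None:
                    rec.samples[s]["DP"] = call.dp
                if call.ad is not None:
                    rec.samples[s]["AD"] = call.ad
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Score track: tab-separated chrom / pos (1-based) / score
# ---------------------------------------------------------------------------


def read_score_track(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "pos", "score"],
        dtype={"chrom": str, "pos": int, "score": float},
        comment="#",
    )
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError(f"duplicate positions in score track {path}")
    if not df["score"].map(lambda x: x == x and abs(x) != float("inf")).all():
        raise ValueError(f"non-finite score in {path}")
    return df


def write_score_track(path: str, df: pd.DataFrame) -> None:
    df[["chrom", "pos", "score"]].to_csv(path, sep="\t", header=False, index=False)
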