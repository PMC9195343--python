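"""GERP-score-weighted relative mutational load.

Pipeline context: each outgroup genome is split into non-overlapping 35 bp
fragments which are mapped to the target reference (mapping itself is
external); per-site rejected-substitution (RS) conservation scores come in
as a track. Here we (1) write the fragment FASTA, (2) polarize variants
into ancestral/derived states from per-site outgroup bases, (3) count
derived alleles per genotype (het = 1, homozygous derived = 2), and
(4) compute the per-sample relative load: the derived-allele-weighted mean
RS score over sites whose score lies within a user-chosen window,

    load = sum_i RS_i * d_i / sum_i d_i   over sites with d_i >= 1 and
           min_score <= RS_i <= max_score (both ends inclusive).

Positive RS indicates evolutionary constraint, so the minimum score should
be at least zero; a percentile utility approximates a threshold from a
genome-wide histogram of scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats import ReferenceSequence, VariantRecord


@dataclass(frozen=True)
class AncestralCall:
    chrom: str
    pos: int  # 1-based, VCF convention
    ancestral_base: str  # A/C/G/T or "unknown"
    n_outgroups_covering: int
    n_agreeing: int

    def __post_init__(self) -> None:
        if self.n_agreeing > self.n_outgroups_covering:
            raise ValueError("n_agreeing cannot exceed n_outgroups_covering")


@dataclass(frozen=True)
class LoadEstimate:
    sample: str
    n_sites_used: int
    n_derived_alleles: int
    sum_weighted: float
    min_score: float
    max_score: float

    @property
    def defined(self) -> bool:
        return self.n_derived_alleles >= 1

    @property
    def relative_load(self) -> float:
        """Weighted mean RS; NaN sentinel when no derived allele passed."""
        if not self.defined:
            return float("nan")
        return self.sum_weighted / self.n_derived_alleles


def fragment_outgroups(
    seqs: Sequence[ReferenceSequence], frag_len: int = 35
) -> list[ReferenceSequence]:
    """Split sequences into consecutive non-overlapping fragments.

    The terminal remainder shorter than ``frag_len`` is discarded.
    Fragment names encode source and 0-based offset.
    """
    if frag_len < 1:
        raise ValueError("frag_len must be >= 1")
    if not seqs:
        raise ValueError("no input sequences")
    frags = []
    for seq in seqs:
        n = seq.length // frag_len
        if n == 0:
            import warnings

            warnings.warn(
                f"sequence {seq.name} shorter than {frag_len} bp: no fragments"
            )
        frags.extend(
            ReferenceSequence(
                f"{seq.name}:{i * frag_len}-{(i + 1) * frag_len}",
                seq.bases[i * frag_len : (i + 1) * frag_len],
            )
            for i in range(n)
        )
    return frags


def infer_ancestral(
    variants: Sequence[VariantRecord],
    outgroup_bases: Mapping[tuple[str, int], Sequence[str]],
    min_coverage: int = 1,
) -> list[AncestralCall]:
    """Ancestral state per site by strict majority over covering outgroups.

    ``outgroup_bases`` maps (chrom, 1-based pos) to the base each covering
    outgroup shows there. Ties, insufficient coverage, and a majority base
    not among the site's alleles all yield "unknown" (excluded downstream).
    """
    calls = []
    for v in variants:
        bases = [
            b.upper()
            for b in outgroup_bases.get((v.chrom, v.pos), ())
            if b.upper() in "ACGT"
        ]
        n_cov = len(bases)
        if n_cov < max(min_coverage, 1):
            calls.append(AncestralCall(v.chrom, v.pos, "unknown", n_cov, 0))
            continue
        counts = Counter(bases)
        (top, n_top), *rest = counts.most_common()
        if rest and rest[0][1] == n_top:  # tie for majority
            calls.append(AncestralCall(v.chrom, v.pos, "unknown", n_cov, n_top))
            continue
        site_alleles = {v.ref_allele.upper(), *(a.upper() for a in v.alt_alleles)}
        if top not in site_alleles:
            calls.append(AncestralCall(v.chrom, v.pos, "unknown", n_cov, n_top))
            continue
        calls.append(AncestralCall(v.chrom, v.pos, top, n_cov, n_top))
    return calls


def count_derived(
    v: VariantRecord, sample: str, ancestral: AncestralCall
) -> int | None:
    """Derived-allele count of one genotype: het = 1, hom derived = 2.

    The derived allele is the biallelic site's non-ancestral allele; a
    homozygous-reference genotype at a site whose ancestral state is the
    ALT counts 2 (the REF itself is derived). Returns None (site skipped)
    for unknown ancestral state, missing genotype, or non-biallelic sites.
    """
    if ancestral.ancestral_base == "unknown":
        return None
    alleles = (v.ref_allele.upper(),) + tuple(a.upper() for a in v.alt_alleles)
    if len(alleles) > 2 or ancestral.ancestral_base not in alleles:
        return None
    call = v.calls.get(sample)
    if call is None or call.genotype is None:
        return None
    anc_index = alleles.index(ancestral.ancestral_base)
    return sum(1 for a in call.genotype if a != anc_index)


def relative_load(
    sites: Iterable[tuple[float, int]],
    min_score: float,
    max_score: float,
    sample: str = "sample",
) -> LoadEstimate:
    """Relative mutational load over (RS score, derived count) pairs.

    Sites with zero derived alleles or a score outside the inclusive
    [min_score, max_score] window are ignored. A total derived count of
    zero yields a defined=False estimate (NaN load), never zero.
    """
    if min_score > max_score:
        raise ValueError("min_score must not exceed max_score")
    n_sites = n_derived = 0
    weighted = 0.0
    for rs, d in sites:
        if d < 1 or not (min_score <= rs <= max_score):
            continue
        n_sites += 1
        n_derived += d
        weighted += rs * d
    return LoadEstimate(
        sample=sample,
        n_sites_used=n_sites,
        n_derived_alleles=n_derived,
        sum_weighted=weighted,
        min_score=min_score,
        max_score=max_score,
    )


def sample_loads(
    variants: Sequence[VariantRecord],
    scores: Mapping[tuple[str, int], float],
    ancestral: Sequence[AncestralCall],
    samples: Sequence[str],
    min_score: float,
    max_score: float,
) -> dict[str, LoadEstimate]:
    """Per-sample relative loads from a merged VCF, score track and polarization."""
    anc_by_site = {(a.chrom, a.pos): a for a in ancestral}
    per_sample_sites: dict[str, list[tuple[float, int]]] = {s: [] for s in samples}
    for v in variants:
        key = (v.chrom, v.pos)
        anc = anc_by_site.get(key)
        rs = scores.get(key)
        if anc is None or rs is None:
            continue
        for s in samples:
            d = count_derived(v, s, anc)
            if d is not None and d >= 1:
                per_sample_sites[s].append((rs, d))
    return {
        s: relative_load(per_sample_sites[s], min_score, max_score, sample=s)
        for s in samples
    }


def gerp_percentile(
    bins: Sequence[tuple[float, float, int]], percentile: float
) -> float:
    """Score threshold at a percentile of a binned genome-wide histogram.

    ``bins`` are contiguous (low, high, count) triples in ascending order;
    the threshold is linearly interpolated within the bin where the
    cumulative count crosses percentile% of the total.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    total = sum(c for _, _, c in bins)
    if total == 0:
        raise ValueError("histogram is empty")
    for i in range(len(bins) - 1):
        if bins[i][1] != bins[i + 1][0]:
            raise ValueError("histogram bins must be contiguous")
    target = percentile / 100.0 * total
    cum = 0
    for low, high, count in bins:
        if cum + count >= target and count > 0:
            return low + (target - cum) / count * (high - low)
        cum += count
    return bins[-1][1]
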