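"""CpG-site identification for damage-aware filtering of historical samples.

Methylated CpG sites escape UDG repair, so post-mortem C→T deamination
persists there in historical/ancient libraries. Three strategies identify
CpG-affected positions, each yielding an exclusion mask:

* ``reference`` — CG dinucleotides in the reference assembly;
* ``genotypes`` — CG dinucleotides implied by the genotyped alleles of
  selected samples substituted into the reference context;
* ``combined`` — the union of both.

"CpG sites" are counted as *positions*: both bases of each dinucleotide are
masked, so the reference-strategy count is always even (CG dinucleotides
cannot overlap). Lowercase (soft-masked) bases match their uppercase
equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import GenomeIntervalSet, ReferenceSequence, VariantRecord


@dataclass(frozen=True)
class CpGMask:
    strategy: str
    intervals: GenomeIntervalSet

    @property
    def n_sites(self) -> int:
        """Number of masked positions (bases covered by the intervals)."""
        return self.intervals.total_bases


def cpg_from_reference(refs: Sequence[ReferenceSequence]) -> CpGMask:
    """Mask both positions of every CG dinucleotide in the reference."""
    raw = []
    for ref in refs:
        bases = ref.bases.upper()
        raw.extend(
            (ref.name, i, i + 2)
            for i in range(len(bases) - 1)
            if bases[i] == "C" and bases[i + 1] == "G"
        )
    return CpGMask("reference", GenomeIntervalSet(raw))


def _allele_sets(
    refs: Sequence[ReferenceSequence],
    variants: Iterable[VariantRecord],
    samples: Sequence[str] | None,
) -> tuple[dict[str, str], dict[tuple[str, int], dict[str, set[str]]], list[str]]:
    """Per-sample SNV allele sets keyed by (chrom, 0-based pos)."""
    seqs = {r.name: r.bases.upper() for r in refs}
    per_site: dict[tuple[str, int], dict[str, set[str]]] = {}
    sample_list: list[str] = list(samples) if samples is not None else []
    for v in variants:
        if v.chrom not in seqs:
            raise KeyError(f"variant chromosome {v.chrom!r} absent from reference")
        if not v.is_snv:
            continue  # indel alleles make the dinucleotide context ill-defined
        alleles = (v.ref_allele.upper(),) + tuple(a.upper() for a in v.alt_alleles)
        use = sample_list if samples is not None else list(v.calls)
        for s in use:
            if s not in sample_list:
                sample_list.append(s)
            call = v.calls.get(s)
            if call is None or call.genotype is None:
                continue  # missing call: sample contributes the reference base
            carried = {alleles[a] for a in call.genotype}
            per_site.setdefault((v.chrom, v.pos0), {}).setdefault(s, set()).update(
                carried
            )
    return seqs, per_site, sample_list


def cpg_from_genotypes(
    refs: Sequence[ReferenceSequence],
    variants: Sequence[VariantRecord],
    samples: Sequence[str] | None = None,
) -> CpGMask:
    """Mask position pairs that form CpG in any selected sample's genotype.

    For each sample, the bases it can carry at position i are its genotyped
    SNV alleles where a variant exists, else the reference base. A pair
    (i, i+1) is masked if any sample can carry C at i and G at i+1 —
    adjacent variants are substituted jointly, and a heterozygote masks if
    *any* carried allele creates the CpG (conservative exclusion).
    """
    seqs, per_site, sample_list = _allele_sets(refs, variants, samples)

    def bases_at(chrom: str, i: int, sample: str) -> set[str]:
        site = per_site.get((chrom, i))
        if site and sample in site:
            return site[sample]
        return {seqs[chrom][i]}

    # candidate pairs: reference CGs plus pairs touching any variant position
    candidates: set[tuple[str, int]] = set()
    for chrom, bases in seqs.items():
        candidates.update(
            (chrom, i)
            for i in range(len(bases) - 1)
            if bases[i] == "C" and bases[i + 1] == "G"
        )
    for chrom, i in per_site:
        if i + 1 < len(seqs[chrom]):
            candidates.add((chrom, i))
        if i - 1 >= 0:
            candidates.add((chrom, i - 1))

    raw = []
    for chrom, i in candidates:
        for s in sample_list or [None]:
            if s is None:  # no samples given and no variants: reference context
                left, right = {seqs[chrom][i]}, {seqs[chrom][i + 1]}
            else:
                left, right = bases_at(chrom, i, s), bases_at(chrom, i + 1, s)
            if "C" in left and "G" in right:
                raw.append((chrom, i, i + 2))
                break
    return CpGMask("genotypes", GenomeIntervalSet(raw))


def cpg_combined(
    refs: Sequence[ReferenceSequence],
    variants: Sequence[VariantRecord],
    samples: Sequence[str] | None = None,
) -> CpGMask:
    """Union of the reference- and genotype-based masks."""
    ref_mask = cpg_from_reference(refs)
    gt_mask = cpg_from_genotypes(refs, variants, samples)
    return CpGMask("combined", ref_mask.intervals.union(gt_mask.intervals))
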