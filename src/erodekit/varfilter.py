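"""The hard-filter cascade applied to per-sample variant calls.

Stages, in cascade order (each per-sample until the merge):

1. CpG-mask exclusion
2. site quality: QUAL >= 30 and MQ >= 30 ("at least 30" is inclusive)
3. indel proximity: drop SNVs within 5 bp of an indel's reference span
   (SnpGap semantics), then drop the indels themselves
4. depth window: min_depth <= DP <= max_depth (real-valued thresholds)
5. allelic imbalance: drop heterozygotes whose allele-support fraction is
   strictly below 20% or strictly above 80% (homozygotes pass untouched)
6. repeat exclusion
7. merge across samples, then drop sites that are not biallelic on the
   union of observed alleles, and sites with strictly more than 10%
   missing genotypes

Every stage records (in, removed, out) in a FilterTrace so counts are
conserved and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .depthqc import DepthThresholds
from .formats import GenomeIntervalSet, SampleCall, VariantRecord


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 30.0
    min_mq: float = 30.0
    indel_gap_bp: int = 5
    imbalance_low: float = 0.20
    imbalance_high: float = 0.80
    max_missing_frac: float = 0.10
    exclude: GenomeIntervalSet = field(default_factory=GenomeIntervalSet)

    def __post_init__(self) -> None:
        if not (0 <= self.imbalance_low < self.imbalance_high <= 1):
            raise ValueError(
                f"imbalance bounds must satisfy 0 <= low < high <= 1, got "
                f"({self.imbalance_low}, {self.imbalance_high})"
            )
        if not (0 <= self.max_missing_frac <= 1):
            raise ValueError("max_missing_frac must be in [0, 1]")


@dataclass
class FilterTrace:
    """Per-stage (sites in, removed, out) bookkeeping; in = removed + out."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append((stage, n_in, n_in - n_out, n_out))

    def check(self) -> None:
        for stage, n_in, n_removed, n_out in self.stages:
            if n_in != n_removed + n_out:
                raise AssertionError(f"trace broken at stage {stage}")


# ---------------------------------------------------------------------------
# Per-site predicates
# ---------------------------------------------------------------------------


def filter_site_quality(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Keep iff QUAL >= min_qual and MQ >= min_mq; absent values fail."""
    if v.site_qual is None or v.site_qual < cfg.min_qual:
        return False
    if v.map_qual is None or v.map_qual < cfg.min_mq:
        return False
    return True


def filter_depth(v: VariantRecord, thresholds: DepthThresholds, sample: str) -> bool:
    call = v.calls.get(sample)
    return call is not None and thresholds.passes(call.dp)


def filter_allelic_imbalance(v: VariantRecord, cfg: FilterConfig, sample: str) -> bool:
    """Drop heterozygotes with allele-support fraction outside (low, high).

    The fraction uses the AD of the two called alleles only; exact 0.20 and
    0.80 are kept ("less than"/"more than" are strict). Homozygous calls
    pass untouched; a het with missing/zero AD is dropped.
    """
    call = v.calls.get(sample)
    if call is None or call.genotype is None:
        return False
    if not call.is_het:
        return True
    if call.ad is None:
        return False
    a1, a2 = call.genotype
    n1, n2 = call.ad[a1], call.ad[a2]
    if n1 + n2 == 0:
        return False
    f = n1 / (n1 + n2)
    return cfg.imbalance_low <= f <= cfg.imbalance_high


def filter_near_indels(
    variants: Sequence[VariantRecord], gap: int = 5
) -> list[VariantRecord]:
    """Drop SNVs within ``gap`` bp of an indel's reference span, then indels.

    An indel's affected span is [pos, pos + len(REF) - 1] (1-based); a
    non-indel variant is dropped when its distance to any span is <= gap.
    Input must be sorted by (chrom, pos).
    """
    order = [(v.chrom, v.pos) for v in variants]
    if order != sorted(order):
        raise ValueError("variants must be sorted by (chrom, pos)")
    zones: dict[str, list[tuple[int, int]]] = {}
    for v in variants:
        if v.is_indel:
            span_end = v.pos + len(v.ref_allele) - 1
            zones.setdefault(v.chrom, []).append((v.pos - gap, span_end + gap))
    kept = []
    for v in variants:
        if v.is_indel:
            continue
        if any(lo <= v.pos <= hi for lo, hi in zones.get(v.chrom, [])):
            continue
        kept.append(v)
    return kept


def exclude_intervals(
    variants: Sequence[VariantRecord], exclude: GenomeIntervalSet
) -> list[VariantRecord]:
    """Drop variants whose 0-based position falls in the exclusion set."""
    return [v for v in variants if not exclude.contains(v.chrom, v.pos0)]


# ---------------------------------------------------------------------------
# Per-sample cascade
# ---------------------------------------------------------------------------


def filter_sample_vcf(
    variants: Sequence[VariantRecord],
    sample: str,
    cfg: FilterConfig,
    thresholds: DepthThresholds,
    cpg_mask: GenomeIntervalSet | None = None,
    repeats: GenomeIntervalSet | None = None,
    trace: FilterTrace | None = None,
) -> list[VariantRecord]:
    """Run the full per-sample cascade in order; returns surviving records."""
    if trace is None:
        trace = FilterTrace()
    cur = list(variants)

    if cpg_mask is not None:
        n_in = len(cur)
        cur = exclude_intervals(cur, cpg_mask)
        trace.record("cpg_exclusion", n_in, len(cur))

    n_in = len(cur)
    cur = [v for v in cur if filter_site_quality(v, cfg)]
    trace.record("site_quality", n_in, len(cur))

    n_in = len(cur)
    cur = filter_near_indels(cur, cfg.indel_gap_bp)
    trace.record("indel_proximity_and_removal", n_in, len(cur))

    n_in = len(cur)
    cur = [v for v in cur if filter_depth(v, thresholds, sample)]
    trace.record("depth_window", n_in, len(cur))

    n_in = len(cur)
    cur = [v for v in cur if filter_allelic_imbalance(v, cfg, sample)]
    trace.record("allelic_imbalance", n_in, len(cur))

    if repeats is not None:
        n_in = len(cur)
        cur = exclude_intervals(cur, repeats)
        trace.record("repeat_exclusion", n_in, len(cur))

    trace.check()
    return cur


# ---------------------------------------------------------------------------
# Merge and post-merge filters
# ---------------------------------------------------------------------------


def merge_and_filter(
    per_sample: Mapping[str, Sequence[VariantRecord]],
    cfg: FilterConfig | None = None,
    trace: FilterTrace | None = None,
) -> list[VariantRecord]:
    """Merge per-sample VCFs and apply biallelic and missingness filters.

    The merged site set is the union of sample sites; a sample without a
    surviving record at a site is missing there. Sites with more than two
    alleles on the union of observed alleles are dropped (per-sample files
    may each look biallelic while jointly triallelic), then sites whose
    missing-genotype fraction strictly exceeds ``max_missing_frac``.
    """
    if cfg is None:
        cfg = FilterConfig()
    if trace is None:
        trace = FilterTrace()
    samples = list(per_sample)
    by_site: dict[tuple[str, int], dict[str, VariantRecord]] = {}
    ref_at: dict[tuple[str, int], str] = {}
    for s, variants in per_sample.items():
        for v in variants:
            key = (v.chrom, v.pos)
            prev_ref = ref_at.setdefault(key, v.ref_allele)
            if prev_ref != v.ref_allele:
                raise ValueError(
                    f"REF mismatch at {v.chrom}:{v.pos}: {prev_ref} vs {v.ref_allele}"
                )
            by_site.setdefault(key, {})[s] = v

    merged: list[VariantRecord] = []
    n_in = len(by_site)
    n_multi = 0
    n_missing = 0
    for key in sorted(by_site):
        chrom, pos = key
        recs = by_site[key]
        ref = ref_at[key]
        # union of ALT alleles listed across samples (bcftools-merge view)
        alts = sorted({a for v in recs.values() for a in v.alt_alleles if a != ref})
        if len(alts) > 1:
            n_multi += 1
            continue
        allele_index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        calls: dict[str, SampleCall] = {}
        n_miss = 0
        for s in samples:
            v = recs.get(s)
            call = v.calls.get(s) if v is not None else None
            if call is None or call.genotype is None:
                calls[s] = SampleCall(genotype=None)
                n_miss += 1
                continue
            site_alleles = (v.ref_allele,) + v.alt_alleles
            gt = tuple(allele_index[site_alleles[a]] for a in call.genotype)
            ad = None
            if call.ad is not None:
                ad = tuple(
                    call.ad[site_alleles.index(b)] if b in site_alleles else 0
                    for b in [ref] + alts
                )
            calls[s] = SampleCall(genotype=gt, dp=call.dp, ad=ad)
        if n_miss / len(samples) > cfg.max_missing_frac:
            n_missing += 1
            continue
        any_rec = next(iter(recs.values()))
        merged.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_alleles=tuple(alts),
                site_qual=any_rec.site_qual,
                map_qual=any_rec.map_qual,
                calls=calls,
            )
        )
    trace.record("biallelic", n_in, n_in - n_multi)
    trace.record("missingness", n_in - n_multi, n_in - n_multi - n_missing)
    trace.check()
    return merged


def split_by_era(
    merged: Sequence[VariantRecord], era_map: Mapping[str, str]
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition sample columns into historical and modern VCFs.

    Both outputs keep the identical site set, even where a split has no
    called genotype at a site.
    """
    samples = {s for v in merged for s in v.calls}
    unassigned = samples - set(era_map)
    if unassigned:
        raise ValueError(f"samples without an era assignment: {sorted(unassigned)}")
    bad = {s: e for s, e in era_map.items() if e not in ("historical", "modern")}
    if bad:
        raise ValueError(f"invalid era labels: {bad}")
    hist_samples = [s for s in era_map if era_map[s] == "historical"]
    mod_samples = [s for s in era_map if era_map[s] == "modern"]
    if not hist_samples or not mod_samples:
        import warnings

        warnings.warn("one era has no samples; emitting an empty-sample VCF")

    def take(v: VariantRecord, keep: list[str]) -> VariantRecord:
        return replace(v, calls={s: c for s, c in v.calls.items() if s in keep})

    historical = [take(v, hist_samples) for v in merged]
    modern = [take(v, mod_samples) for v in merged]
    return historical, modern


def passing_sites_bed(merged: Sequence[VariantRecord]) -> GenomeIntervalSet:
    """1-bp intervals of all surviving sites, merged/normalized."""
    return GenomeIntervalSet((v.chrom, v.pos0, v.pos0 + 1) for v in merged)
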