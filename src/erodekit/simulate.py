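"""Seeded synthetic-data generators with truth bookkeeping.

Every analysis stage gets a generator that emits standard-format inputs
together with the ground truth planted in them (duplicate clusters, CpG
positions, generating theta/eps, planted ROH, per-sample true loads), so
the whole toolkit is testable without any external dataset. All
generators are deterministic functions of (seed, parameters); one global
seed fans out to independent per-generator streams.

What these fixtures emulate — and what they do not: reads are uniformly
placed with exact-copy duplicates (no optical duplicates, no damage
patterns), pileups follow the estimator's own generative model (no
reference bias or mapping error), genotypes are iid per SNP outside
planted ROH (no linkage disequilibrium). Passing tests therefore
demonstrate algorithmic correctness, not robustness to every artefact of
real sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats import (
    AlignmentRecord,
    GenomeIntervalSet,
    ReferenceSequence,
    SampleCall,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent child stream for one generator under a global seed."""
    import zlib

    key = zlib.crc32(label.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class TruthBundle:
    """Generated objects plus the truth planted in them."""

    seed: int
    params: dict = field(default_factory=dict)
    objects: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------


def simulate_reference(
    length: int,
    gc_frac: float = 0.4,
    cpg_enrichment: float = 1.0,
    seed: int = 0,
    name: str = "chr1",
) -> TruthBundle:
    """Random reference with tunable GC content and CpG dinucleotide rate.

    Bases are drawn sequentially; after a C, the probability of a G is
    multiplied by ``cpg_enrichment`` (0 suppresses CpG entirely, 1 leaves
    the iid baseline, >1 enriches) and renormalized. The truth table holds
    the CpG-position BED computed by a direct scan during generation.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    if not (0 < gc_frac < 1) or cpg_enrichment < 0:
        raise ValueError("invalid gc_frac or cpg_enrichment")
    rng = _stream(seed, "reference")
    base_p = np.array(
        [(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2]
    )
    after_c = base_p.copy()
    after_c[2] *= cpg_enrichment
    after_c = after_c / after_c.sum()
    out = np.empty(length, dtype="<U1")
    prev_c = False
    for i in range(length):
        p = after_c if prev_c else base_p
        b = _BASES[rng.choice(4, p=p)]
        out[i] = b
        prev_c = b == "C"
    bases = "".join(out)
    cpg = GenomeIntervalSet(
        (name, i, i + 2)
        for i in range(length - 1)
        if bases[i] == "C" and bases[i + 1] == "G"
    )
    ref = ReferenceSequence(name, bases)
    return TruthBundle(
        seed=seed,
        params={"length": length, "gc_frac": gc_frac, "cpg_enrichment": cpg_enrichment},
        objects={"reference": ref},
        truth={"cpg_bed": cpg},
    )


# ---------------------------------------------------------------------------
# Alignments with planted duplicates
# ---------------------------------------------------------------------------


def simulate_alignments(
    ref: ReferenceSequence,
    mean_depth: float = 10.0,
    dup_rate: float = 0.2,
    read_len_range: tuple[int, int] = (30, 70),
    seed: int = 0,
) -> TruthBundle:
    """Merged-read alignments with exact-coordinate PCR duplicates planted.

    Original reads are drawn with pairwise-distinct (start, end, strand)
    keys (rejection sampling), so the planted duplicate count equals
    exactly the number of reads a start+end deduplicator must remove.
    ``dup_rate`` is the fraction of the final read set that is duplicate
    copies.
    """
    if not (0 <= dup_rate < 1):
        raise ValueError("dup_rate must be in [0, 1)")
    rng = _stream(seed, "alignments")
    lo, hi = read_len_range
    mean_len = (lo + hi) / 2
    n_total = max(1, int(round(mean_depth * ref.length / mean_len)))
    n_dup = int(round(dup_rate * n_total))
    n_orig = n_total - n_dup

    originals: list[AlignmentRecord] = []
    seen: set[tuple[int, int, str]] = set()
    i = 0
    while len(originals) < n_orig:
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(1, ref.length - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        key = (start, start + length, strand)
        if key in seen:
            continue
        seen.add(key)
        quals = tuple(int(q) for q in rng.integers(20, 41, size=length))
        originals.append(
            AlignmentRecord(
                query_name=f"read{i:06d}",
                ref_name=ref.name,
                start=start,
                end=start + length,
                strand=strand,
                mapq=int(rng.integers(30, 61)),
                base_qualities=quals,
            )
        )
        i += 1

    records = list(originals)
    clusters: dict[tuple[int, int, str], list[str]] = {
        (r.start, r.end, r.strand): [r.query_name] for r in originals
    }
    for j in range(n_dup):
        src = originals[int(rng.integers(0, n_orig))]
        name = f"dup{j:06d}"
        quals = tuple(
            int(q) for q in rng.integers(20, 41, size=src.end - src.start)
        )
        records.append(
            AlignmentRecord(
                query_name=name,
                ref_name=src.ref_name,
                start=src.start,
                end=src.end,
                strand=src.strand,
                mapq=int(rng.integers(30, 61)),
                base_qualities=quals,
            )
        )
        clusters[(src.start, src.end, src.strand)].append(name)
    order = rng.permutation(len(records))
    records = [records[k] for k in order]
    return TruthBundle(
        seed=seed,
        params={
            "mean_depth": mean_depth,
            "dup_rate": dup_rate,
            "read_len_range": read_len_range,
        },
        objects={"alignments": records, "reference": ref},
        truth={"n_duplicates": n_dup, "clusters": clusters},
    )


# ---------------------------------------------------------------------------
# Pileup quartets under the theta/eps mixture model
# ---------------------------------------------------------------------------


def simulate_pileup(
    theta: float,
    eps: float,
    depth: int,
    n_sites: int,
    seed: int = 0,
    chrom: str = "chr1",
) -> TruthBundle:
    """Site base-count quartets from the heterozygosity generative model.

    Each site is heterozygous with probability theta/(1+theta); read bases
    are multinomial with the mixture model's per-component probabilities
    at fixed ``depth``.
    """
    rng = _stream(seed, "pileup")
    pi = theta / (1.0 + theta)
    het = rng.random(n_sites) < pi
    rows = []
    for i in range(n_sites):
        if het[i]:
            a1, a2 = rng.choice(4, size=2, replace=False)
            p = np.full(4, eps / 3.0)
            p[a1] = p[a2] = (1.0 - eps) / 2.0 + eps / 6.0
        else:
            a1 = rng.integers(0, 4)
            p = np.full(4, eps / 3.0)
            p[a1] = 1.0 - eps
        quartet = rng.multinomial(depth, p / p.sum())
        rows.append((chrom, i + 1, tuple(int(x) for x in quartet)))
    return TruthBundle(
        seed=seed,
        params={"theta": theta, "eps": eps, "depth": depth, "n_sites": n_sites},
        objects={"rows": rows},
        truth={"theta": theta, "eps": eps, "n_het_sites": int(het.sum())},
    )


# ---------------------------------------------------------------------------
# Genotypes with planted ROH
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_samples: int = 3,
    chrom_bp: int = 10_000_000,
    snp_spacing: int = 10_000,
    het_rate: float = 0.3,
    missing_rate: float = 0.02,
    planted_roh: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    chrom: str = "chr1",
) -> TruthBundle:
    """Multi-sample SNP genotypes with homozygous blocks planted.

    SNPs sit every ``snp_spacing`` bp. Inside planted (start, end) 1-based
    blocks the het probability is zero for every sample (missingness still
    applies); outside it is ``het_rate``.
    """
    ivs = sorted(planted_roh)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError("planted ROH intervals overlap")
    for s, e in ivs:
        if not (1 <= s < e <= chrom_bp):
            raise ValueError(f"planted interval ({s}, {e}) outside chromosome")
    rng = _stream(seed, "genotypes")
    positions = list(range(snp_spacing, chrom_bp + 1, snp_spacing))
    samples = [f"s{i}" for i in range(n_samples)]
    variants = []
    for pos in positions:
        in_roh = any(s <= pos <= e for s, e in ivs)
        calls = {}
        for samp in samples:
            if rng.random() < missing_rate:
                calls[samp] = SampleCall(genotype=None)
            elif not in_roh and rng.random() < het_rate:
                calls[samp] = SampleCall(genotype=(0, 1), dp=20, ad=(10, 10))
            else:
                gt = (0, 0) if rng.random() < 0.7 else (1, 1)
                ad = (20, 0) if gt == (0, 0) else (0, 20)
                calls[samp] = SampleCall(genotype=gt, dp=20, ad=ad)
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref_allele="A",
                alt_alleles=("G",),
                site_qual=60.0,
                map_qual=60.0,
                calls=calls,
            )
        )
    truth_bed = GenomeIntervalSet((chrom, s - 1, e) for s, e in ivs)
    return TruthBundle(
        seed=seed,
        params={
            "n_samples": n_samples,
            "chrom_bp": chrom_bp,
            "snp_spacing": snp_spacing,
            "het_rate": het_rate,
            "missing_rate": missing_rate,
        },
        objects={"variants": variants, "samples": samples},
        truth={"roh_bed": truth_bed},
    )


# ---------------------------------------------------------------------------
# GERP sites with known loads
# ---------------------------------------------------------------------------


def simulate_gerp_sites(
    n_sites: int,
    derived_probs: dict[str, tuple[float, float]],
    score_shape: float = 0.5,
    score_scale: float = 2.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> TruthBundle:
    """Per-site RS scores and derived counts with the true load recorded.

    ``derived_probs`` maps sample -> (P(het), P(hom derived)) or
    (P(het), P(hom derived), rs_bias); a positive ``rs_bias`` multiplies
    both probabilities by (1 + rs_bias * RS), concentrating that sample's
    derived alleles at conserved sites (higher expected load). Scores are
    gamma-distributed (mostly small, occasionally large, like genome-wide
    RS histograms). The truth loads are accumulated by direct summation
    during generation over all sites (window [0, inf)).
    """
    rng = _stream(seed, "gerp")
    scores = rng.gamma(score_shape, score_scale, size=n_sites)
    sites: dict[str, list[tuple[float, int]]] = {s: [] for s in derived_probs}
    truth_num = {s: 0.0 for s in derived_probs}
    truth_den = {s: 0 for s in derived_probs}
    for i in range(n_sites):
        rs = float(scores[i])
        for s, probs in derived_probs.items():
            p_het, p_hom = probs[0], probs[1]
            bias = probs[2] if len(probs) > 2 else 0.0
            scale = 1.0 + bias * rs
            p_het = min(p_het * scale, 0.6)
            p_hom = min(p_hom * scale, 0.3)
            u = rng.random()
            d = 1 if u < p_het else (2 if u < p_het + p_hom else 0)
            sites[s].append((rs, d))
            if d:
                truth_num[s] += rs * d
                truth_den[s] += d
    truth_loads = {
        s: (truth_num[s] / truth_den[s] if truth_den[s] else float("nan"))
        for s in derived_probs
    }
    return TruthBundle(
        seed=seed,
        params={"n_sites": n_sites, "derived_probs": derived_probs},
        objects={"sites": sites, "scores": scores},
        truth={"loads": truth_loads},
    )
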