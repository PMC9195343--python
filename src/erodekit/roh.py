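"""Sliding-window runs-of-homozygosity caller and the F_ROH coefficient.

The caller follows plink --homozyg semantics: a window of ``window_snps``
consecutive SNPs is called homozygous when it contains at most
``window_max_het`` heterozygous and at most ``window_max_missing`` missing
calls. Each SNP's hit rate is the fraction of windows containing it that
are homozygous; SNPs with a hit rate of at least ``hit_rate_threshold``
are eligible. Maximal runs of eligible SNPs (split at physical gaps above
``max_gap_kb``) become ROH when they satisfy the minimum SNP count, the
minimum physical length, the SNP-density bound, and the per-segment
heterozygote cap.

Long ROH (>= 2 Mb by default) arise from recent close inbreeding; the
fraction of the genome in such ROH is the inbreeding coefficient F_ROH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

HOM, HET, MISSING = 0, 1, 2


@dataclass(frozen=True)
class RohParams:
    min_snps_per_roh: int = 25  # homozyg-snp
    min_kb: float = 100.0  # homozyg-kb
    window_snps: int = 250  # homozyg-window-snp
    window_max_het: int = 3  # homozyg-window-het
    window_max_missing: int = 15  # homozyg-window-missing
    max_het_per_roh: int = 750  # homozyg-het
    hit_rate_threshold: float = 0.05  # homozyg-window-threshold
    max_gap_kb: float = 1000.0  # homozyg-gap
    min_density_kb_per_snp: float = 50.0  # homozyg-density

    def __post_init__(self) -> None:
        if not (0 < self.hit_rate_threshold <= 1):
            raise ValueError("hit_rate_threshold must be in (0, 1]")
        for name in (
            "min_snps_per_roh",
            "window_snps",
            "window_max_het",
            "window_max_missing",
            "max_het_per_roh",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: str
    start_pos: int  # 1-based position of the first SNP in the run
    end_pos: int  # 1-based position of the last SNP in the run
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class RohSummary:
    sample: str
    f_roh: float
    total_roh_bp: int
    genome_bp: int
    length_cutoff_bp: int = 2_000_000


def _check_sorted(positions: Sequence[int]) -> None:
    if any(positions[i] >= positions[i + 1] for i in range(len(positions) - 1)):
        raise ValueError("SNP positions must be strictly increasing")


def snp_hit_rates(
    genotypes: Sequence[int], positions: Sequence[int], params: RohParams
) -> np.ndarray:
    """Per-SNP eligibility flags from the sliding-window vote.

    ``genotypes`` are per-SNP codes (0 hom, 1 het, 2 missing) on one
    chromosome, sorted by ``positions``. Chromosomes with fewer SNPs than
    the window size use a single window spanning all SNPs rather than
    being skipped.
    """
    _check_sorted(positions)
    g = np.asarray(genotypes)
    n = len(g)
    if n == 0:
        return np.zeros(0, dtype=bool)
    w = min(params.window_snps, n)
    het = np.concatenate([[0], np.cumsum(g == HET)])
    mis = np.concatenate([[0], np.cumsum(g == MISSING)])
    n_windows = n - w + 1
    het_in = het[w:] - het[:-w][:n_windows]
    mis_in = mis[w:] - mis[:-w][:n_windows]
    win_hom = (het_in <= params.window_max_het) & (
        mis_in <= params.window_max_missing
    )
    # SNP i lies in windows starting at max(0, i-w+1) .. min(i, n_windows-1)
    hom_cum = np.concatenate([[0], np.cumsum(win_hom)])
    idx = np.arange(n)
    first = np.maximum(0, idx - w + 1)
    last = np.minimum(idx, n_windows - 1)
    n_hom = hom_cum[last + 1] - hom_cum[first]
    n_tot = last - first + 1
    return (n_hom / n_tot) >= params.hit_rate_threshold


def call_roh(
    genotypes: Sequence[int],
    positions: Sequence[int],
    params: RohParams,
    sample: str = "sample",
    chrom: str = "chrom",
) -> list[RohSegment]:
    """Call ROH segments on one chromosome for one sample.

    Maximal runs of eligible SNPs, split at inter-SNP gaps above
    ``max_gap_kb``, are accepted when they meet the SNP-count, length,
    density and heterozygote criteria. Segment coordinates span the first
    to the last SNP of the run.
    """
    eligible = snp_hit_rates(genotypes, positions, params)
    g = np.asarray(genotypes)
    pos = np.asarray(positions)
    segments: list[RohSegment] = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if not run_idx:
            return
        n_snps = len(run_idx)
        start, end = int(pos[run_idx[0]]), int(pos[run_idx[-1]])
        length = end - start + 1
        n_het = int(np.sum(g[run_idx] == HET))
        if (
            n_snps >= params.min_snps_per_roh
            and length >= params.min_kb * 1000
            and length / n_snps <= params.min_density_kb_per_snp * 1000
            and n_het <= params.max_het_per_roh
        ):
            segments.append(RohSegment(sample, chrom, start, end, n_snps, n_het))

    for i in range(len(g)):
        if not eligible[i]:
            flush(run)
            run = []
            continue
        if run and pos[i] - pos[run[-1]] > params.max_gap_kb * 1000:
            flush(run)
            run = []
        run.append(i)
    flush(run)
    return segments


def f_roh(
    segments: Sequence[RohSegment],
    genome_bp: int,
    cutoff_bp: int = 2_000_000,
    sample: str = "sample",
) -> RohSummary:
    """Fraction of the genome in ROH at least ``cutoff_bp`` long."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    total = sum(s.length_bp for s in segments if s.length_bp >= cutoff_bp)
    return RohSummary(
        sample=sample,
        f_roh=total / genome_bp,
        total_roh_bp=total,
        genome_bp=genome_bp,
        length_cutoff_bp=cutoff_bp,
    )


def genotype_codes(
    variants, sample: str, chrom: str
) -> tuple[list[int], list[int]]:
    """Extract (codes, positions) for one sample on one chromosome from
    VariantRecords, in position order."""
    codes, positions = [], []
    for v in sorted(
        (v for v in variants if v.chrom == chrom), key=lambda v: v.pos
    ):
        call = v.calls.get(sample)
        if call is None or call.genotype is None:
            codes.append(MISSING)
        elif call.is_het:
            codes.append(HET)
        else:
            codes.append(HOM)
        positions.append(v.pos)
    return codes, positions
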