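"""Depth profiles, thresholds, seeded subsampling, and contamination ratios.

The depth rule used throughout: per-sample minimum and maximum depth
thresholds are one third and ten times the genome-wide average depth, with
an absolute (non-negotiable) minimum of three reads per site. Thresholds
are kept real-valued and compared directly — no rounding — so a site with
DP=3 passes the minimum whenever the average is at most 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import AlignmentRecord

ABSOLUTE_MIN_DEPTH = 3


@dataclass(frozen=True)
class DepthProfile:
    """Depth histogram over all sites in scope (depth 0 bin included)."""

    histogram: dict[int, int]
    n_sites_total: int

    def __post_init__(self) -> None:
        counted = sum(self.histogram.values())
        if counted != self.n_sites_total:
            raise ValueError(
                f"histogram counts {counted} != n_sites_total {self.n_sites_total}"
            )

    @property
    def n_sites_covered(self) -> int:
        return sum(c for d, c in self.histogram.items() if d >= 1)


@dataclass(frozen=True)
class DepthThresholds:
    min_depth: float
    max_depth: float
    abs_min: int = ABSOLUTE_MIN_DEPTH

    def __post_init__(self) -> None:
        if self.min_depth < self.abs_min:
            raise ValueError("min_depth below absolute minimum")
        if self.max_depth <= self.min_depth:
            raise ValueError("max_depth must exceed min_depth")

    def passes(self, dp: int | None) -> bool:
        return dp is not None and self.min_depth <= dp <= self.max_depth


def depth_profile(
    records: Iterable[AlignmentRecord], ref_lengths: Mapping[str, int]
) -> DepthProfile:
    """Per-site depth histogram from alignment spans (no per-base masking)."""
    cov = {name: np.zeros(length + 1, dtype=np.int64) for name, length in ref_lengths.items()}
    for rec in records:
        if rec.ref_name not in cov:
            raise KeyError(f"alignment on unknown reference {rec.ref_name}")
        arr = cov[rec.ref_name]
        arr[rec.start] += 1
        arr[min(rec.end, len(arr) - 1)] -= 1
    hist: dict[int, int] = {}
    for name, length in ref_lengths.items():
        depths = np.cumsum(cov[name][:length])
        vals, counts = np.unique(depths, return_counts=True)
        for d, c in zip(vals.tolist(), counts.tolist()):
            hist[d] = hist.get(d, 0) + c
    return DepthProfile(hist, sum(ref_lengths.values()))


def average_depth(profile: DepthProfile, include_zero: bool = True) -> float:
    """Genome-wide average depth, including or excluding zero-coverage sites."""
    if profile.n_sites_total == 0:
        raise ValueError("empty depth profile")
    total = sum(d * c for d, c in profile.histogram.items())
    if include_zero:
        return total / profile.n_sites_total
    if profile.n_sites_covered == 0:
        raise ValueError("average over covered sites undefined: no site has coverage")
    return total / profile.n_sites_covered


def depth_thresholds(avg: float) -> DepthThresholds:
    """min = max(3, avg/3), max = 10*avg; applied as min <= DP <= max."""
    if avg <= 0:
        raise ValueError(f"average depth must be positive, got {avg}")
    return DepthThresholds(max(float(ABSOLUTE_MIN_DEPTH), avg / 3.0), 10.0 * avg)


def subsample_alignments(
    records: Sequence[AlignmentRecord],
    current_avg: float,
    target_avg: float,
    seed: int,
) -> list[AlignmentRecord]:
    """Per-read Bernoulli subsampling to a target genome-wide depth.

    Each read is kept independently with probability target/current
    (streaming samtools-style); a fixed seed reproduces the output exactly.
    ``target >= current`` is a no-op.
    """
    if target_avg <= 0:
        raise ValueError("target depth must be positive")
    if target_avg >= current_avg:
        import warnings

        warnings.warn("target depth >= current depth; returning input unchanged")
        return list(records)
    p = target_avg / current_avg
    rng = np.random.default_rng(seed)
    keep = rng.random(len(records)) < p
    return [rec for rec, k in zip(records, keep) if k]


UNDEFINED_RATIO = float("nan")


def contamination_table(
    read_counts: Mapping[str, int] | Sequence[Mapping[str, int]],
    target_name: str,
) -> pd.DataFrame:
    """Ratios of reads mapped to contaminant mitogenomes vs. the target's.

    ``read_counts`` is one mitogenome->count map per library (a single map is
    treated as one library). Returns one row per (library, mitogenome) plus,
    when several libraries are given, mean/sd summary rows per mitogenome.
    A zero target count yields NaN ratios rather than an error.
    """
    libs = [read_counts] if isinstance(read_counts, Mapping) else list(read_counts)
    rows = []
    for i, counts in enumerate(libs):
        if target_name not in counts:
            raise KeyError(f"target {target_name!r} absent from library {i}")
        denom = counts[target_name]
        for mito, n in sorted(counts.items()):
            if mito == target_name:
                continue
            ratio = UNDEFINED_RATIO if denom == 0 else n / denom
            rows.append(
                {"library": str(i), "mitogenome": mito, "ratio": ratio}
            )
    df = pd.DataFrame(rows, columns=["library", "mitogenome", "ratio"])
    if len(libs) > 1 and not df.empty:
        summary = (
            df.groupby("mitogenome")["ratio"]
            .agg(["mean", "std"])
            .reset_index()
        )
        for _, r in summary.iterrows():
            rows.append(
                {"library": "mean", "mitogenome": r["mitogenome"], "ratio": r["mean"]}
            )
            rows.append(
                {"library": "sd", "mitogenome": r["mitogenome"], "ratio": r["std"]}
            )
        df = pd.DataFrame(rows, columns=["library", "mitogenome", "ratio"])
    return df
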