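"""Joint maximum-likelihood estimation of per-site heterozygosity and error.

Model
-----
Each retained site carries a quartet of base counts (n_A, n_C, n_G, n_T).
A site is heterozygous with prior probability pi = theta / (1 + theta),
where theta = 4*Ne*mu is the population mutation parameter; under the
infinite-sites model theta approximates the expected per-site
heterozygosity of a diploid individual (Ne and mu are not separately
identifiable — only their product is estimated).

With per-read error rate eps and the quartet sorted n1 >= n2 >= n3 >= n4:

* homozygous component: the most frequent base is the true base; reads are
  multinomial with probabilities (1 - eps, eps/3, eps/3, eps/3);
* heterozygous component: the two most frequent bases are the allele pair;
  each allele base has probability (1 - eps)/2 + eps/6, the other two
  bases eps/3.

The site log-likelihood is log[(1 - pi) L_hom + pi L_het] (multinomial
coefficient included; it is common to both components). Sites are
aggregated by sorted quartet, so cost scales with the number of distinct
quartets rather than the number of sites. The likelihood depends on the
sorted quartet only, making it invariant to base relabelling.

The joint MLE (theta_hat, eps_hat) is found by Nelder-Mead on
log-transformed parameters within theta, eps in [1e-8, 0.2]; the 95%
confidence interval on theta comes from the profile likelihood at a drop
of 1.92 log-units (chi-square(1)/2). Estimation is deterministic given the
count table. In the zero-error limit the MLE solves
h_hat = theta/(1 + theta) with h_hat the observed heterozygous-site
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.special import gammaln, logsumexp, xlogy

MIN_SITE_DEPTH = 3  # absolute minimum depth of three reads per site

THETA_BOUNDS = (1e-8, 0.2)
EPS_BOUNDS = (1e-8, 0.2)
_CI_DROP = 1.92  # chi2(1, 0.95) / 2


@dataclass(frozen=True)
class ThetaEstimate:
    theta_hat: float
    eps_hat: float
    ci_low: float
    ci_high: float
    n_sites: int
    log_likelihood: float
    partition: str = "all"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.theta_hat <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


class SiteCountTable:
    """Per-site base-count quartets, aggregated by sorted quartet.

    Only sites with depth >= 3 are retained; an optional maximum-depth
    bound mirrors the pipeline's depth window. The aggregation map sends
    each sorted quartet (n1 >= n2 >= n3 >= n4) to its site multiplicity.
    """

    def __init__(
        self,
        rows: Iterable[tuple[str, int, tuple[int, int, int, int]]] = (),
        max_depth: float | None = None,
    ):
        counts: dict[tuple[int, int, int, int], int] = {}
        n = 0
        for chrom, pos, quartet in rows:
            depth = sum(quartet)
            if depth < MIN_SITE_DEPTH:
                continue
            if max_depth is not None and depth > max_depth:
                continue
            key = tuple(sorted(quartet, reverse=True))
            counts[key] = counts.get(key, 0) + 1
            n += 1
        self.multiplicity: dict[tuple[int, int, int, int], int] = counts
        self.n_sites: int = n

    @classmethod
    def from_multiplicity(
        cls, multiplicity: dict[tuple[int, int, int, int], int]
    ) -> "SiteCountTable":
        t = cls()
        t.multiplicity = {
            tuple(sorted(q, reverse=True)): m for q, m in multiplicity.items()
        }
        t.n_sites = sum(multiplicity.values())
        return t

    @classmethod
    def from_tsv(cls, path: str, max_depth: float | None = None) -> "SiteCountTable":
        """Read a chrom / pos / nA / nC / nG / nT tab-separated table."""
        df = pd.read_csv(
            path, sep="\t", names=["chrom", "pos", "nA", "nC", "nG", "nT"], comment="#"
        )
        rows = (
            (r.chrom, int(r.pos), (int(r.nA), int(r.nC), int(r.nG), int(r.nT)))
            for r in df.itertuples()
        )
        return cls(rows, max_depth=max_depth)

    @property
    def het_fraction(self) -> float:
        """Fraction of sites showing two or more distinct bases."""
        het = sum(m for q, m in self.multiplicity.items() if q[1] > 0)
        return het / self.n_sites if self.n_sites else 0.0


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _log_multinom_coef(q: Sequence[int]) -> float:
    n = sum(q)
    return gammaln(n + 1) - sum(gammaln(k + 1) for k in q)


def site_log_likelihood(
    quartet: Sequence[int], theta: float, eps: float
) -> float:
    """Log-likelihood of one base-count quartet under the mixture model."""
    if theta < 0 or not (0 <= eps < 0.75):
        raise ValueError(f"parameters out of bounds: theta={theta}, eps={eps}")
    if sum(quartet) < 1:
        raise ValueError("quartet depth must be >= 1")
    q = sorted(quartet, reverse=True)
    return float(_site_loglik_vec(np.array([q]), theta, eps)[0])


def _site_loglik_vec(q: np.ndarray, theta: float, eps: float) -> np.ndarray:
    """Vectorized site log-likelihoods for sorted quartets (rows n1>=..>=n4)."""
    pi = theta / (1.0 + theta)
    n1, n2, rest = q[:, 0], q[:, 1], q[:, 2] + q[:, 3]
    coef = gammaln(q.sum(axis=1) + 1) - gammaln(q + 1).sum(axis=1)
    # xlogy gives 0*log(0) = 0, k*log(0) = -inf for k > 0 (zero-error limit)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_hom = n1 * np.log(1.0 - eps) + xlogy(n2 + rest, eps / 3.0)
        p_allele = (1.0 - eps) / 2.0 + eps / 6.0
        log_het = (n1 + n2) * np.log(p_allele) + xlogy(rest, eps / 3.0)
    # log[(1-pi) e^log_hom + pi e^log_het], robust for pi in {0, 1} and -inf terms
    terms = np.stack([log_hom, log_het], axis=1)
    with np.errstate(divide="ignore"):
        weights = np.log(np.array([1.0 - pi, pi]))
    return coef + logsumexp(terms + weights, axis=1)


def total_log_likelihood(table: SiteCountTable, theta: float, eps: float) -> float:
    q = np.array(list(table.multiplicity.keys()), dtype=float)
    m = np.array(list(table.multiplicity.values()), dtype=float)
    ll = _site_loglik_vec(q, theta, eps)
    if np.any(np.isneginf(ll) & (m > 0)):
        return -math.inf
    return float(np.dot(m, ll))


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _profile_eps(table: SiteCountTable, theta: float) -> float:
    """Max over eps of the log-likelihood at fixed theta."""
    res = minimize_scalar(
        lambda le: -total_log_likelihood(table, theta, math.exp(le)),
        bounds=(math.log(EPS_BOUNDS[0]), math.log(EPS_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return -res.fun


def estimate_theta(
    table: SiteCountTable,
    partition: str = "all",
    fix_eps: float | None = None,
) -> ThetaEstimate:
    """Joint MLE of (theta, eps) with a 95% profile-likelihood CI on theta.

    ``fix_eps`` pins the error rate (``fix_eps=0`` gives the zero-error
    estimator whose MLE solves h_hat = theta/(1+theta) exactly).
    """
    if table.n_sites == 0:
        raise ValueError("empty site-count table")
    if table.n_sites < 1000:
        import warnings

        warnings.warn(
            f"only {table.n_sites} sites; theta estimates will be noisy"
        )

    lo, hi = (math.log(b) for b in THETA_BOUNDS)

    if fix_eps is not None:
        res = minimize_scalar(
            lambda lt: -total_log_likelihood(table, math.exp(lt), fix_eps),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta_hat, eps_hat, ll_max = math.exp(res.x), fix_eps, -res.fun

        def profile(theta: float) -> float:
            return total_log_likelihood(table, theta, fix_eps)

    else:
        x0 = np.array(
            [math.log(max(table.het_fraction, 1e-6)), math.log(0.01)]
        )
        res = minimize(
            lambda x: -total_log_likelihood(
                table,
                math.exp(np.clip(x[0], lo, hi)),
                math.exp(np.clip(x[1], math.log(EPS_BOUNDS[0]), math.log(EPS_BOUNDS[1]))),
            ),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        if not res.success and res.status != 2:  # 2 = maxiter, still usable
            raise RuntimeError(f"theta optimization failed: {res.message}")
        theta_hat = math.exp(np.clip(res.x[0], lo, hi))
        eps_hat = math.exp(
            np.clip(res.x[1], math.log(EPS_BOUNDS[0]), math.log(EPS_BOUNDS[1]))
        )
        ll_max = -res.fun

        def profile(theta: float) -> float:
            return _profile_eps(table, theta)

    ci_low, ci_high = _profile_ci(profile, theta_hat, ll_max)
    return ThetaEstimate(
        theta_hat=theta_hat,
        eps_hat=eps_hat,
        ci_low=min(ci_low, theta_hat),
        ci_high=max(ci_high, theta_hat),
        n_sites=table.n_sites,
        log_likelihood=ll_max,
        partition=partition,
    )


def _profile_ci(profile, theta_hat: float, ll_max: float) -> tuple[float, float]:
    target = ll_max - _CI_DROP

    def g(log_theta: float) -> float:
        return profile(math.exp(log_theta)) - target

    lo_bound, hi_bound = (math.log(b) for b in THETA_BOUNDS)
    lt_hat = math.log(theta_hat)

    def solve(a: float, b: float, fallback: float) -> float:
        ga, gb = g(a), g(b)
        if ga == gb or ga * gb > 0:
            return fallback
        return math.exp(brentq(g, a, b, xtol=1e-10))

    low = (
        math.exp(lo_bound)
        if g(lo_bound) >= 0
        else solve(lo_bound, lt_hat, theta_hat)
    )
    high = (
        math.exp(hi_bound)
        if g(hi_bound) >= 0
        else solve(lt_hat, hi_bound, theta_hat)
    )
    return low, high


def estimate_by_partition(
    rows: Sequence[tuple[str, int, tuple[int, int, int, int]]],
    sex_chromosomes: Sequence[str] = (),
    max_depth: float | None = None,
    fix_eps: float | None = None,
) -> dict[str, ThetaEstimate]:
    """Estimate theta separately for autosomes and sex chromosomes.

    Scaffolds named in ``sex_chromosomes`` form the sex-chromosome
    partition; everything else is autosomal. Empty partitions are omitted.
    """
    sex = set(sex_chromosomes)
    parts = {
        "autosomes": [r for r in rows if r[0] not in sex],
        "sex_chromosomes": [r for r in rows if r[0] in sex],
    }
    out = {}
    for name, part_rows in parts.items():
        table = SiteCountTable(part_rows, max_depth=max_depth)
        if table.n_sites:
            out[name] = estimate_theta(table, partition=name, fix_eps=fix_eps)
    return out
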