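"""Occupancy distributions, delay probabilities and trade-off curves.

The planning logic: audit daily ward occupancy ``N`` in the unconstrained
model, then for a candidate bed count ``c`` estimate the probability an
arriving patient finds the ward full as the truncated ratio

    p(delay) = P(N = c) / P(N <= c),

the Erlang loss (Erlang B) formula applied to the empirical occupancy
distribution.  When occupancy is exactly Poisson — as it is for a stationary
unconstrained ward — this coincides with the classical Erlang B blocking
probability at offered load equal to the mean occupancy, which this module
also provides analytically as an independent oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .engine import OccupancyAudit


@dataclass
class OccupancyPMF:
    """Empirical daily-occupancy distribution of one ward.

    ``p[k]`` is the probability of observing ``k`` occupied beds; ``n_days``
    is the number of audited ward-days behind the estimate.
    """

    p: np.ndarray
    n_days: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size == 0:
            raise ValueError("empty PMF")
        total = self.p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}, not 1")

    @property
    def probabilities(self) -> dict[int, float]:
        return {k: float(v) for k, v in enumerate(self.p) if v > 0}

    def mean(self) -> float:
        return float(np.arange(self.p.size) @ self.p)

    def cdf(self, k: int) -> float:
        if k < 0:
            return 0.0
        return float(self.p[: k + 1].sum())


@dataclass
class DelayEstimate:
    beds: int
    p_delay: float
    one_in_n: float  # positive integer, or math.inf when p_delay == 0
    ci_low: float
    ci_high: float


def occupancy_pmf(audits: list[OccupancyAudit] | OccupancyAudit) -> OccupancyPMF:
    """Pool all post-warm-up ward-days across replications into one PMF."""
    if isinstance(audits, OccupancyAudit):
        audits = [audits]
    if not audits:
        raise ValueError("no audits supplied")
    counts = np.concatenate([a.counts for a in audits])
    if counts.size == 0:
        raise ValueError("audits contain no days")
    freq = np.bincount(counts)
    return OccupancyPMF(p=freq / counts.size, n_days=int(counts.size))


def per_rep_pmfs(audits: list[OccupancyAudit]) -> list[OccupancyPMF]:
    return [occupancy_pmf(a) for a in audits]


def prob_delay(pmf: OccupancyPMF, beds: int) -> float:
    """Truncated-ratio delay probability P(N = beds) / P(N <= beds)."""
    if beds < 0:
        raise ValueError("beds must be non-negative")
    denom = pmf.cdf(beds)
    if denom <= 0.0:
        warnings.warn(
            f"P(N <= {beds}) is zero in the empirical PMF; reporting p(delay)=1",
            stacklevel=2,
        )
        return 1.0
    num = float(pmf.p[beds]) if beds < pmf.p.size else 0.0
    return num / denom


def erlang_b(offered_load: float, beds: int) -> float:
    """Erlang B blocking probability via the stable recursion
    ``B(0)=1, B(k) = a B(k-1) / (k + a B(k-1))``."""
    if offered_load <= 0:
        raise ValueError("offered_load must be positive")
    if beds < 0:
        raise ValueError("beds must be non-negative")
    b = 1.0
    for k in range(1, beds + 1):
        b = offered_load * b / (k + offered_load * b)
    return b


def poisson_pmf(mean: float, tail: float = 1e-15) -> OccupancyPMF:
    """Exact (to machine truncation) Poisson occupancy PMF, as produced by a
    stationary unconstrained ward with offered load ``mean``."""
    upper = int(stats.poisson.isf(tail, mean)) + 2
    p = stats.poisson.pmf(np.arange(upper + 1), mean)
    return OccupancyPMF(p=p / p.sum(), n_days=0)


def one_in_n(p: float) -> float:
    """'1 in every n patients' summary: nearest integer to 1/p.

    Applied to the *unrounded* probability.  ``p == 0`` maps to ``math.inf``
    (no delays); values outside (0, 1] are rejected.
    """
    if p == 0:
        return math.inf
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    return int(math.floor(1.0 / p + 0.5))


def invert_offered_load(
    target_p: float, beds: int, tol: float = 1e-12
) -> float:
    """Offered load at which Erlang B blocking on ``beds`` equals ``target_p``."""
    if not (0.0 < target_p < 1.0):
        raise ValueError("target_p must lie in (0, 1)")
    if beds == 0:
        raise ValueError("blocking on zero beds is 1 for every load; target unbracketable")
    lo, hi = 1e-12, 1.0
    while erlang_b(hi, beds) < target_p:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("target blocking probability is unbracketable")
    root = optimize.brentq(
        lambda a: erlang_b(a, beds) - target_p, lo, hi, xtol=tol, rtol=8.9e-16
    )
    return float(root)


def tradeoff_curve(
    audits: list[OccupancyAudit], bed_range
) -> list[DelayEstimate]:
    """One :class:`DelayEstimate` per bed count.

    The point estimate uses the pooled PMF; the 95% interval is the 2.5th and
    97.5th percentile of per-replication delay probabilities (widened, if
    necessary, to contain the pooled point estimate).  The curve should be
    non-increasing in beds; an empirical violation (possible for strongly
    multi-modal occupancy) triggers a warning rather than an error.
    """
    beds = list(bed_range)
    if not beds:
        raise ValueError("empty bed range")
    pooled = occupancy_pmf(audits)
    reps = per_rep_pmfs(audits) if len(audits) > 1 else []
    out = []
    prev = None
    for c in beds:
        point = prob_delay(pooled, c)
        if reps:
            per_rep = np.array([prob_delay(r, c) for r in reps])
            lo, hi = np.percentile(per_rep, [2.5, 97.5])
        else:
            lo = hi = point
        est = DelayEstimate(
            beds=int(c),
            p_delay=point,
            one_in_n=one_in_n(point),
            ci_low=float(min(lo, point)),
            ci_high=float(max(hi, point)),
        )
        if prev is not None and est.p_delay > prev + 1e-12:
            warnings.warn(
                f"p(delay) increased from {prev:.4g} to {est.p_delay:.4g} at "
                f"{c} beds; empirical PMF is not unimodal-tailed",
                stacklevel=2,
            )
        prev = est.p_delay
        out.append(est)
    return out


def poisson_gof_pvalue(
    counts: np.ndarray, mean: float, spacing: int = 14, min_expected: float = 5.0
) -> float:
    """Chi-square goodness of fit of audited occupancy against Poisson(mean).

    Daily occupancy is serially correlated on the length-of-stay timescale, so
    the test subsamples every ``spacing``-th day to obtain approximately
    independent draws before binning (tails merged until every expected count
    is at least ``min_expected``).
    """
    sample = np.asarray(counts)[::spacing]
    n = sample.size
    if n < 20:
        raise ValueError("too few subsampled days for a chi-square test")
    upper = int(stats.poisson.isf(1e-12, mean)) + 1
    probs = stats.poisson.pmf(np.arange(upper + 1), mean)
    probs[-1] = 1.0 - probs[:-1].sum()
    observed = np.bincount(np.minimum(sample, upper), minlength=upper + 1).astype(float)
    expected = probs * n
    # Merge adjacent low-expectation cells from both tails inward.
    obs_b, exp_b = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_b.append(acc_o)
            exp_b.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if exp_b:
            obs_b[-1] += acc_o
            exp_b[-1] += acc_e
        else:
            obs_b, exp_b = [acc_o], [acc_e]
    if len(exp_b) < 2:
        raise ValueError("not enough occupancy spread for a chi-square test")
    stat, p = stats.chisquare(obs_b, f_exp=np.array(exp_b) * (n / sum(exp_b)))
    return float(p)
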