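"""Integer event-count distributions for care-pathway parameters.

Annual per-patient event counts (injections per year, follow-up assessments
per year) are small positive integers — observed between 1 and 14 per year —
and are modelled as a log-normal variate rounded to the nearest integer and
truncated to a bounded support.  A distribution is specified by the
*natural-scale* mean and standard deviation of that rounded, truncated
variate, matching how service averages are quoted (e.g. "mean 1.4, SD 0.37"
follow-ups per patient-year).

Because the variate is integer-valued, not every (mean, sd) pair is
attainable: an integer variate with mean 1.4 cannot have sd below
sqrt(0.6*0.4^2 + 0.4*0.6^2) ~= 0.49.  The calibrator therefore matches the
mean exactly (the quantity every downstream average depends on) and gets as
close as the support allows in sd; see ``CountDistribution.lognormal``.

Sampling is by inverse CDF so that, under common random numbers, a
distribution with a larger mean (same coefficient of variation) yields
pointwise larger draws — the property paired scenario comparisons rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

#: Observed range of per-patient annual event counts.
DEFAULT_SUPPORT = (1, 14)

#: Coefficient of variation used when only a mean is quoted for a count
#: distribution; taken from the one fully specified pair (mean 1.4, SD 0.37).
DEFAULT_COUNT_CV = 0.37 / 1.4

_PARAMETRIC_MIN_N = 30


def _cell_edges(lo: int, hi: int) -> np.ndarray:
    ks = np.arange(lo, hi + 1)
    return np.concatenate(([-np.inf], np.log(ks[:-1] + 0.5), [np.inf]))


def _discretised_probs(mu: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    """P(round(clip(X, lo, hi)) = k) for X ~ LogNormal(mu, sigma)."""
    cdf = stats.norm.cdf(_cell_edges(lo, hi), loc=mu, scale=sigma)
    p = np.diff(cdf)
    return p / p.sum()


def _discretised_moments(mu: float, sigma: float, lo: int, hi: int):
    ks = np.arange(lo, hi + 1)
    p = _discretised_probs(mu, sigma, lo, hi)
    m = float((ks * p).sum())
    sd = float(np.sqrt(((ks - m) ** 2 * p).sum()))
    return m, sd


def _solve_lognormal(mean: float, sd: float, lo: int, hi: int):
    """Underlying (mu, sigma) whose rounded, truncated variate has the
    requested natural-scale mean (matched exactly) and sd (best attainable)."""
    s2 = math.log1p((sd / mean) ** 2) if sd > 0 else 1e-4
    x0 = [math.log(mean) - s2 / 2.0, max(math.sqrt(s2), 1e-2)]

    def resid(x):
        m, s = _discretised_moments(x[0], abs(x[1]), lo, hi)
        # weight ratio makes the mean residual dominate: the mean is matched
        # to solver precision, the sd only as far as the integer support allows
        return [1e4 * (m - mean), s - sd]

    sol = optimize.least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return float(sol.x[0]), float(abs(sol.x[1]))


@dataclass(frozen=True)
class CountDistribution:
    """Distribution of an integer events-per-patient-year count.

    ``mean``/``sd`` are the natural-scale moments of the integer variate.
    ``family`` is ``"lognormal"`` (rounded, truncated log-normal) or
    ``"empirical"`` (arbitrary probabilities over the support, used for small
    or degenerate samples).
    """

    family: str
    mean: float
    sd: float
    support: tuple[int, int] = DEFAULT_SUPPORT
    values: tuple[int, ...] = field(default=(), repr=False)
    probs: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self):
        if self.family not in ("lognormal", "empirical"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("mean must be > 0 and sd >= 0")
        lo, hi = self.support
        if not (0 < lo <= hi):
            raise ValueError(f"bad support {self.support}")
        if not all(lo <= v <= hi for v in self.values):
            raise ValueError("empirical values outside support")

    # -- constructors -------------------------------------------------------

    @classmethod
    def lognormal(
        cls,
        mean: float,
        sd: float | None = None,
        support: tuple[int, int] = DEFAULT_SUPPORT,
    ) -> "CountDistribution":
        """Rounded, truncated log-normal with the given natural-scale mean.

        When ``sd`` is omitted it defaults to ``mean * DEFAULT_COUNT_CV``.
        The achieved integer-variate moments are stored back on the object.
        """
        if sd is None:
            sd = mean * DEFAULT_COUNT_CV
        lo, hi = support
        mu, sigma = _solve_lognormal(mean, sd, lo, hi)
        probs = _discretised_probs(mu, sigma, lo, hi)
        got_mean, got_sd = _discretised_moments(mu, sigma, lo, hi)
        return cls(
            family="lognormal",
            mean=got_mean,
            sd=got_sd,
            support=support,
            values=tuple(range(lo, hi + 1)),
            probs=tuple(float(p) for p in probs),
        )

    @classmethod
    def empirical(
        cls, values: Sequence[int], probs: Sequence[float] | None = None
    ) -> "CountDistribution":
        values = tuple(int(v) for v in values)
        if probs is None:
            probs = np.full(len(values), 1.0 / len(values))
        probs = np.asarray(probs, float)
        probs = probs / probs.sum()
        ks = np.asarray(values, float)
        m = float((ks * probs).sum())
        sd = float(np.sqrt((((ks - m) ** 2) * probs).sum()))
        return cls(
            family="empirical",
            mean=m,
            sd=sd,
            support=(min(values), max(values)),
            values=values,
            probs=tuple(float(p) for p in probs),
        )

    @classmethod
    def constant(cls, value: int) -> "CountDistribution":
        return cls.empirical([int(value)], [1.0])

    # -- sampling -----------------------------------------------------------

    def _cum(self) -> np.ndarray:
        c = np.cumsum(self.probs)
        c[-1] = 1.0
        return c

    def ppf(self, u) -> np.ndarray:
        """Inverse CDF over the integer support (monotone in the mean)."""
        idx = np.searchsorted(self._cum(), np.asarray(u), side="left")
        return np.asarray(self.values)[np.clip(idx, 0, len(self.values) - 1)]

    def sample(self, rng: np.random.Generator, size=None):
        out = self.ppf(rng.random(size if size is not None else 1))
        return out if size is not None else int(out[0])

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mean": self.mean,
            "sd": self.sd,
            "support": list(self.support),
            "values": list(self.values),
            "probs": list(self.probs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CountDistribution":
        return cls(
            family=d["family"],
            mean=d["mean"],
            sd=d["sd"],
            support=tuple(d["support"]),
            values=tuple(d["values"]),
            probs=tuple(d["probs"]),
        )


def fit_count_distribution(
    counts: Sequence[int], support: tuple[int, int] = DEFAULT_SUPPORT
) -> CountDistribution:
    """Maximum-likelihood fit of the rounded truncated log-normal to counts.

    The likelihood is the discretised one (each integer count contributes the
    probability of its rounding cell), which is the correct MLE for
    integer-recorded data and leaves the natural-scale mean unbiased.  Falls
    back to the empirical family below 30 observations or when all counts are
    equal (the log-normal scale parameter degenerates).

    Counts must be positive integers; an empty sample is an error.
    """
    x = np.asarray(counts)
    if x.size == 0:
        raise ValueError("cannot fit a distribution to an empty sample")
    if np.any(x <= 0):
        raise ValueError("counts must be positive (>= 1 event per year)")
    x = x.astype(int)

    vals, cnt = np.unique(x, return_counts=True)
    if x.size < _PARAMETRIC_MIN_N or len(vals) == 1:
        return CountDistribution.empirical(vals, cnt / cnt.sum())

    lo, hi = support
    lx = np.log(x)
    x0 = [float(lx.mean()), max(float(lx.std()), 0.05)]
    ks = np.arange(lo, hi + 1)
    pos = np.searchsorted(ks, np.clip(vals, lo, hi))

    def nll(th):
        p = _discretised_probs(th[0], abs(th[1]), lo, hi)
        return -float((cnt * np.log(np.clip(p[pos], 1e-300, None))).sum())

    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-10, maxiter=4000),
    )
    mu, sigma = float(res.x[0]), float(abs(res.x[1]))
    probs = _discretised_probs(mu, sigma, lo, hi)
    m, sd = _discretised_moments(mu, sigma, lo, hi)
    return CountDistribution(
        family="lognormal",
        mean=m,
        sd=sd,
        support=support,
        values=tuple(range(lo, hi + 1)),
        probs=tuple(float(p) for p in probs),
    )


def lognormal_log_moments(counts: Sequence[int]) -> tuple[float, float]:
    """Closed-form log-scale MLE (mean and sd of log counts)."""
    lx = np.log(np.asarray(counts, float))
    return float(lx.mean()), float(lx.std())
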