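"""Convert boxplot summaries (median and quartiles) into mean/dispersion
estimates, and cell concentrations into growth rates.

Experiments often report response medians with interquartile ranges rather
than means with standard errors.  The estimators here are the
quantile-based ones of Luo, Wan, Liu & Tong (mean) and Wan et al.
(dispersion): the mean is a sample-size-weighted blend of the mid-quartile
point and the median, and the dispersion is the interquartile range scaled
by the expected IQR of a standard normal at the given sample size,

    eta(n) = 2 * Phi^{-1}((0.75 n - 0.125) / (n + 0.25)).

The dispersion estimator targets the standard deviation of the underlying
sample.  Because upstream tables treat the resulting S as a standard
error, two modes are provided: ``paper_literal`` returns S unchanged for
use as an SE, and ``corrected`` divides by sqrt(n) to convert the SD
estimate into a proper standard error of the mean.
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel, model_validator
from scipy.stats import norm

__all__ = [
    "QuartileSummary",
    "GrowthObservation",
    "estimate_mean",
    "eta",
    "estimate_dispersion",
    "growth_rate",
]

DispersionMode = Literal["paper_literal", "corrected"]


class QuartileSummary(BaseModel):
    """A boxplot summary: first quartile, median, third quartile, n."""

    q1: float
    median: float
    q3: float
    n: int

    @model_validator(mode="after")
    def _check(self) -> "QuartileSummary":
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"quartiles out of order: q1={self.q1}, median={self.median}, q3={self.q3}"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")
        return self


class GrowthObservation(BaseModel):
    """Initial/final cell concentrations over an elapsed time in days."""

    n0: float
    nt: float
    t: float

    @model_validator(mode="after")
    def _check(self) -> "GrowthObservation":
        if self.n0 <= 0 or self.nt <= 0:
            raise ValueError("cell concentrations must be positive")
        if self.t <= 0:
            raise ValueError("elapsed time must be positive")
        return self


def estimate_mean(qs: QuartileSummary) -> float:
    """Mean estimate from (q1, median, q3, n).

    Weighted blend ``(0.7 + 0.39/n) * (q1+q3)/2 + (0.3 - 0.39/n) * median``;
    the two weights sum to one for every n, so a degenerate summary with
    q1 = median = q3 = c returns exactly c.
    """
    w = 0.7 + 0.39 / qs.n
    return w * (qs.q1 + qs.q3) / 2.0 + (1.0 - w) * qs.median


def eta(n: int) -> float:
    """Expected IQR of a standard normal sample of size n.

    ``2 * Phi^{-1}((0.75 n - 0.125) / (n + 0.25))``, increasing in n toward
    the asymptote 2 * Phi^{-1}(0.75) ≈ 1.349; zero at n = 1 (the quantile
    probability is exactly one half).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = (0.75 * n - 0.125) / (n + 0.25)
    if not (0.0 < p < 1.0):
        raise ValueError(f"quantile probability {p} outside (0, 1) for n={n}")
    return 2.0 * norm.ppf(p)


def estimate_dispersion(qs: QuartileSummary, mode: DispersionMode = "paper_literal") -> float:
    """Dispersion estimate S = (q3 - q1) / eta(n).

    In ``paper_literal`` mode S is returned as-is (used directly as the
    record's standard error downstream); in ``corrected`` mode S is treated
    as a standard-deviation estimate and divided by sqrt(n) to give a
    standard error of the mean.

    A degenerate summary (q1 = q3) gives 0 for any n.  At n = 1 the
    normal-IQR scale eta(1) is 0, so a non-zero IQR is contradictory and
    rejected.
    """
    if qs.q3 == qs.q1:
        return 0.0
    if qs.n == 1:
        raise ValueError("a single observation cannot have a non-zero IQR")
    s = (qs.q3 - qs.q1) / eta(qs.n)
    if mode == "corrected":
        s /= math.sqrt(qs.n)
    elif mode != "paper_literal":
        raise ValueError(f"unknown dispersion mode {mode!r}")
    return s


def growth_rate(obs: GrowthObservation) -> float:
    """Specific growth rate μ = ln(Nt/N0) / t, per day."""
    return math.log(obs.nt / obs.n0) / obs.t
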