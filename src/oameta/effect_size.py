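"""Signed log response ratios and their sampling variances.

The effect size is the log response ratio LnRR = ln(mean_E) - ln(mean_C)
between an elevated-CO2 treatment arm (E) and the ambient control arm (C).
For responses where an increase is harmful (e.g. shell dissolution) the
sign is inverted, so a positive LnRR always denotes benefit to the
organism and a negative LnRR harm.

The sampling variance follows the inverse-variance weighting convention

    v = S_E^2 / (n_E * mean_E^2) + S_C^2 / (n_C * mean_C^2)

evaluated either with the reported standard errors as the S terms
(``paper_literal``) or with standard deviations (``hedges``, S = SE*sqrt(n)),
the latter being the delta-method variance of the log ratio from the
effect-size literature.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel

__all__ = [
    "EffectSize",
    "log_response_ratio",
    "effect_variance",
    "lnrr_from_arms",
    "variance_from_arms",
]

VarianceMode = Literal["paper_literal", "hedges"]
Direction = Literal["higher_is_better", "higher_is_worse"]


class EffectSize(BaseModel):
    """One pooled-analysis row: signed LnRR, variance, weight, labels."""

    lnrr: float
    v: float
    weight: Optional[float]  # None when v == 0 (excluded from weighted pooling)
    category: str
    trophic_level: str
    group: str
    response_name: str
    community_flag: str
    study_id: str
    experiment_id: str
    species: str


def log_response_ratio(
    mean_treatment: float,
    mean_control: float,
    direction: Direction = "higher_is_better",
) -> float:
    """Signed LnRR; positive always means the organism benefits."""
    if mean_treatment <= 0 or mean_control <= 0:
        raise ValueError(
            f"log response ratio requires positive means, got "
            f"treatment={mean_treatment}, control={mean_control}"
        )
    lnrr = math.log(mean_treatment) - math.log(mean_control)
    if direction == "higher_is_worse":
        lnrr = -lnrr
    elif direction != "higher_is_better":
        raise ValueError(f"unknown direction {direction!r}")
    return lnrr


def effect_variance(
    mean_treatment: float,
    s_treatment: float,
    n_treatment: int,
    mean_control: float,
    s_control: float,
    n_control: int,
    mode: VarianceMode = "paper_literal",
) -> float:
    """Sampling variance of the log response ratio.

    ``paper_literal`` plugs the reported dispersion (a standard error) into
    S directly; ``hedges`` converts SE to SD first (SD = SE*sqrt(n)), which
    makes v the usual delta-method variance SD^2/(n*mean^2) per arm.
    """
    if n_treatment < 1 or n_control < 1:
        raise ValueError("sample sizes must be >= 1")
    if mean_treatment <= 0 or mean_control <= 0:
        raise ValueError("means must be positive")
    if s_treatment < 0 or s_control < 0:
        raise ValueError("dispersions must be non-negative")
    if mode == "hedges":
        s_treatment = s_treatment * math.sqrt(n_treatment)
        s_control = s_control * math.sqrt(n_control)
    elif mode != "paper_literal":
        raise ValueError(f"unknown variance mode {mode!r}")
    return s_treatment**2 / (n_treatment * mean_treatment**2) + s_control**2 / (
        n_control * mean_control**2
    )


def lnrr_from_arms(treatment, control, direction: Direction = "higher_is_better") -> float:
    """LnRR from two resolved treatment arms (arms must carry mean)."""
    return log_response_ratio(treatment.mean, control.mean, direction)


def variance_from_arms(treatment, control, mode: VarianceMode = "paper_literal") -> float:
    """Effect variance from two resolved arms (arms must carry mean/se/n)."""
    return effect_variance(
        treatment.mean, treatment.se, treatment.n,
        control.mean, control.se, control.n,
        mode=mode,
    )
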