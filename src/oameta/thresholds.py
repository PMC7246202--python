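"""Aggregate effect sizes across grouping levels and derive categorical
verdicts and CO2 threshold ("tipping point") levels.

Four grouping levels of increasing taxonomic resolution are supported:

1. trophic level (prokaryote / autotroph / heterotroph), all responses;
2. taxon group (bacteria / phytoplankton / macroalgae / invertebrate /
   fish), all responses;
3. taxon group x biological response;
4. phytoplankton only, biological response x single-species vs community.

Each non-empty (labels x CO2 category) cell gets a random-effects fit;
its verdict is read off the 95% CI (positive / negative / no_effect), and
a threshold for a group is the lower bound of the lowest category whose
verdict is negative with no higher category turning positive again.
Alternating verdicts, or cells all based on few effects, yield
"uncertain".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .ingest import CATEGORY_DISPLAY, DEFAULT_CATEGORIES
from .rema import REMLFit, fit

__all__ = [
    "GroupSummary",
    "ResponseClassification",
    "LEVEL_KEYS",
    "summarize_groups",
    "classify",
    "detect_threshold",
    "classification_grid",
    "threshold_table",
    "DEFAULT_LOW_K_CUTOFF",
]

DEFAULT_LOW_K_CUTOFF = 3

LEVEL_KEYS: Dict[int, Tuple[str, ...]] = {
    1: ("trophic_level",),
    2: ("group",),
    3: ("group", "response_name"),
    4: ("group", "response_name", "community_flag"),
}

# Elevated categories in ascending order of lower bound (the sub-ambient
# pre-industrial band is reported but takes no part in threshold logic).
ELEVATED_ORDER = ["c500_800", "c801_1000", "c1001_1500", "c1501_2000", "gt2000"]
CATEGORY_ORDER = ["preindustrial"] + ELEVATED_ORDER


@dataclass(frozen=True)
class GroupSummary:
    grouping_level: int
    group_labels: Tuple[str, ...]
    category: str
    fit: REMLFit

    @property
    def n_effects(self) -> int:
        return self.fit.k


@dataclass(frozen=True)
class ResponseClassification:
    group_labels: Tuple[str, ...]
    category: str
    verdict: str  # positive | negative | no_effect | no_data
    low_confidence: bool


def summarize_groups(
    effects: pd.DataFrame,
    level: int,
    weights: str = "inverse_variance",
) -> List[GroupSummary]:
    """One random-effects fit per non-empty (labels x category) cell.

    ``effects`` is the effect-size table with columns lnrr, v, category
    and the grouping labels.  Level 4 restricts to phytoplankton, the only
    taxon with both single-species and community studies.
    """
    if level not in LEVEL_KEYS:
        raise ValueError(f"unknown grouping level {level}; expected 1-4")
    keys = LEVEL_KEYS[level]
    df = effects
    if level == 4:
        df = df[df["group"] == "phytoplankton"]
    out: List[GroupSummary] = []
    grouped = df.groupby(list(keys) + ["category"], sort=True)
    for key, cell in grouped:
        *labels, category = key if isinstance(key, tuple) else (key,)
        pairs = list(zip(cell["lnrr"], cell["v"]))
        out.append(
            GroupSummary(
                grouping_level=level,
                group_labels=tuple(labels),
                category=str(category),
                fit=fit(pairs, weights=weights),
            )
        )
    return out


def classify(
    summary: Optional[GroupSummary],
    low_k_cutoff: int = DEFAULT_LOW_K_CUTOFF,
    group_labels: Tuple[str, ...] = (),
    category: str = "",
) -> ResponseClassification:
    """Verdict from the CI position; ``None`` means an empty cell.

    positive <=> ci_low > 0; negative <=> ci_high < 0; otherwise
    no_effect.  Cells pooling fewer than ``low_k_cutoff`` effects are
    flagged low-confidence (the "few data points" asterisk convention of
    published classification tables).
    """
    if summary is None:
        return ResponseClassification(group_labels, category, "no_data", False)
    f = summary.fit
    if f.ci_low > 0:
        verdict = "positive"
    elif f.ci_high < 0:
        verdict = "negative"
    else:
        verdict = "no_effect"
    return ResponseClassification(
        summary.group_labels,
        summary.category,
        verdict,
        low_confidence=f.k < low_k_cutoff,
    )


def detect_threshold(
    classifications: Sequence[ResponseClassification],
) -> dict:
    """CO2 threshold from one group's verdicts across ordered categories.

    Returns a dict with keys ``status`` ("threshold" | "no_effect" |
    "uncertain"), ``threshold_uatm`` (lower bound of the first
    sustained-negative category, or None), ``display`` (the category's
    display name) and ``reason``.

    The threshold is the lowest elevated category whose verdict is
    negative and that stays negative (or has no data) at every higher
    category.  No negative category at all -> "no_effect"; verdicts that
    alternate (negative then later non-negative with data), or negatives
    supported only by low-confidence cells -> "uncertain".
    """
    by_cat = {c.category: c for c in classifications}
    ordered = [by_cat.get(cat) for cat in ELEVATED_ORDER]
    verdicts = [c.verdict if c is not None else "no_data" for c in ordered]

    neg_idx = [i for i, v in enumerate(verdicts) if v == "negative"]
    if not neg_idx:
        if all(v == "no_data" for v in verdicts):
            return {
                "status": "uncertain",
                "threshold_uatm": None,
                "display": None,
                "reason": "no data in any elevated category",
            }
        return {
            "status": "no_effect",
            "threshold_uatm": None,
            "display": None,
            "reason": "no elevated category shows a significant negative effect",
        }

    informative = [c for c in ordered if c is not None and c.verdict != "no_data"]
    if informative and all(c.low_confidence for c in informative):
        return {
            "status": "uncertain",
            "threshold_uatm": None,
            "display": None,
            "reason": "all informative cells are low-confidence (few effects)",
        }

    first = neg_idx[0]
    sustained = all(v in ("negative", "no_data") for v in verdicts[first:])
    if not sustained:
        return {
            "status": "uncertain",
            "threshold_uatm": None,
            "display": None,
            "reason": "verdicts alternate across categories",
        }
    cat_label = ELEVATED_ORDER[first]
    lower = next(c.lower for c in DEFAULT_CATEGORIES if c.label == cat_label)
    return {
        "status": "threshold",
        "threshold_uatm": lower,
        "display": CATEGORY_DISPLAY[cat_label],
        "reason": "first sustained significantly-negative category",
    }


def classification_grid(
    summaries: Sequence[GroupSummary],
    low_k_cutoff: int = DEFAULT_LOW_K_CUTOFF,
) -> pd.DataFrame:
    """Table-style grid: one row per (group labels x category) with the
    verdict and low-confidence flag."""
    rows = []
    for s in summaries:
        c = classify(s, low_k_cutoff)
        rows.append(
            {
                "group_labels": "|".join(s.group_labels),
                "category": s.category,
                "verdict": c.verdict,
                "low_confidence": c.low_confidence,
                "k": s.fit.k,
                "pooled": s.fit.pooled,
                "ci_low": s.fit.ci_low,
                "ci_high": s.fit.ci_high,
                "tau2": s.fit.tau2,
                "q": s.fit.q,
                "q_df": s.fit.q_df,
                "q_p": s.fit.q_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_labels",
            "category",
            "verdict",
            "low_confidence",
            "k",
            "pooled",
            "ci_low",
            "ci_high",
            "tau2",
            "q",
            "q_df",
            "q_p",
        ],
    )


def threshold_table(
    summaries: Sequence[GroupSummary],
    low_k_cutoff: int = DEFAULT_LOW_K_CUTOFF,
) -> pd.DataFrame:
    """One threshold row per distinct group-label tuple."""
    by_group: Dict[Tuple[str, ...], List[ResponseClassification]] = {}
    for s in summaries:
        by_group.setdefault(s.group_labels, []).append(classify(s, low_k_cutoff))
    rows = []
    for labels in sorted(by_group):
        res = detect_threshold(by_group[labels])
        rows.append(
            {
                "group_labels": "|".join(labels),
                "status": res["status"],
                "threshold_uatm": res["threshold_uatm"],
                "display": res["display"],
                "reason": res["reason"],
            }
        )
    return pd.DataFrame(
        rows, columns=["group_labels", "status", "threshold_uatm", "display", "reason"]
    )
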