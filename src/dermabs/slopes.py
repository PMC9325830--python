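"""Regulatory classification of fitted log–log slopes.

The slope of the log10(absorbed) ~ log10(applied) regression carries a
regulatory reading: a slope of 1 means absorption is directly
dose-proportional (a single relative absorption value covers all doses);
a slope of 0 means the absorbed amount does not respond to dose at all
(the premise behind concentration-based pro-rata extrapolation); slopes
in between are less-than-dose-proportional; slopes above 1 mean smaller
doses give disproportionately less systemic exposure.  A negative slope
(absorption rising as dose falls) is biologically implausible and is
treated as uncertain.

Rather than testing a single hypothesis, each slope's 80% confidence
interval is held against all of these hypotheses at once; with a
two-sided 80% interval each one-sided exclusion holds at the 95% level.
The classification is a partition: exactly one category applies to any
interval.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .loglog import LogLogFit, slope_ci

__all__ = [
    "SlopeCategory",
    "SlopeClassification",
    "compatible_with",
    "classify_slope",
    "classify_fit",
    "interpret_slope",
    "classification_summary",
    "classifications_to_frame",
]


class SlopeCategory(str, enum.Enum):
    ZERO = "0"
    BETWEEN_0_1 = "0-1"
    ONE = "1"
    ABOVE_1 = ">1"
    UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class SlopeClassification:
    category: SlopeCategory
    ci: tuple[float, float]
    ci_level: float = 0.80
    stratum: str = ""
    slope: float = math.nan
    note: str = ""


def compatible_with(fit: LogLogFit, value: float, level: float = 0.95) -> bool:
    """Is ``value`` inside the level-CI of the fitted slope?

    Closed interval: a value exactly on the boundary counts as
    compatible.
    """
    lo, hi = slope_ci(fit, level)
    return lo <= value <= hi


def classify_slope(
    ci80: tuple[float, float],
    ci_level: float = 0.80,
    stratum: str = "",
    slope: float = math.nan,
) -> SlopeClassification:
    """Assign a slope CI to exactly one regulatory category.

    Rules, applied in order (closed intervals; a boundary counts as
    contained):

    1. entirely below 0 -> UNCERTAIN (implausible inverse relationship)
    2. contains both 0 and 1 -> UNCERTAIN (too wide to conclude)
    3. contains 1 (not 0) -> ONE
    4. contains 0 (not 1) -> ZERO
    5. entirely above 1 -> ABOVE_1 (with a proximity note when the lower
       bound is within 0.1 of 1)
    6. otherwise entirely inside (0, 1) -> BETWEEN_0_1
    """
    lo, hi = ci80
    if lo > hi:
        raise ValueError(f"malformed interval: lo ({lo}) > hi ({hi})")
    has0 = lo <= 0 <= hi
    has1 = lo <= 1 <= hi
    note = ""
    if hi < 0:
        cat = SlopeCategory.UNCERTAIN
        note = "negative slope: biologically implausible"
    elif has0 and has1:
        cat = SlopeCategory.UNCERTAIN
        note = "interval too wide to exclude either 0 or 1"
    elif has1:
        cat = SlopeCategory.ONE
    elif has0:
        cat = SlopeCategory.ZERO
    elif lo > 1:
        cat = SlopeCategory.ABOVE_1
        if lo <= 1.1:
            note = "greater than but very close to 1"
    else:
        cat = SlopeCategory.BETWEEN_0_1
    return SlopeClassification(
        category=cat, ci=(lo, hi), ci_level=ci_level, stratum=stratum,
        slope=slope, note=note,
    )


def classify_fit(fit: LogLogFit, ci_level: float = 0.80) -> SlopeClassification:
    """Classify a fitted model via its slope CI."""
    ci = slope_ci(fit, ci_level)
    return classify_slope(ci, ci_level=ci_level, stratum=fit.stratum,
                          slope=fit.slope)


#: Readings of the three slope regimes, one row per interpretive aspect.
_INTERPRETATIONS: dict[SlopeCategory, dict[str, str]] = {
    SlopeCategory.ABOVE_1: {
        "absolute_penetration": "Decreases with decreasing doses "
                                "(overly dose-proportional)",
        "relative_penetration": "Decreases with decreasing dose "
                                "(< dose-proportional)",
        "small_dose_limit": "Intersection with abscissa, i.e. 0% absorption: "
                            "very small doses are not absorbed",
        "adme": "Reduce exposure/toxicity at lower applied doses",
        "predicted_internal_exposure": "Smaller doses result in less systemic "
                                       "exposure than higher doses",
        "plausibility": "Plausible",
    },
    SlopeCategory.ONE: {
        "absolute_penetration": "Constant and independent of dose "
                                "(EFSA pro-rata approach); directly "
                                "dose-proportional",
        "relative_penetration": "Constant and independent of applied dose "
                                "(dose-proportional)",
        "small_dose_limit": "Constant",
        "adme": "Do not affect exposure/toxicity",
        "predicted_internal_exposure": "All applied doses result in same "
                                       "systemic exposure",
        "plausibility": "Plausible",
    },
    SlopeCategory.ZERO: {
        "absolute_penetration": "Constant and independent of dose "
                                "(EFSA pro-rata approach)",
        "relative_penetration": "Increases with decreasing dose "
                                "(> dose-proportional)",
        "small_dose_limit": "Constant",
        "adme": "Increase exposure/toxicity at lower applied dose",
        "predicted_internal_exposure": "All applied doses result in same "
                                       "systemic exposure",
        "plausibility": "Implausible",
    },
    SlopeCategory.BETWEEN_0_1: {
        "absolute_penetration": "Increases with decreasing doses less than "
                                "dose-proportionally",
        "relative_penetration": "Increases with decreasing dose "
                                "(> dose-proportional)",
        "small_dose_limit": "Intersection with identity line, i.e. 100% "
                            "absorption: very small doses are completely "
                            "absorbed",
        "adme": "Increase exposure/toxicity at lower applied dose",
        "predicted_internal_exposure": "Lower applied doses result in higher "
                                       "systemic exposure",
        "plausibility": "Implausible",
    },
    SlopeCategory.UNCERTAIN: {
        "absolute_penetration": "No conclusion",
        "relative_penetration": "No conclusion",
        "small_dose_limit": "No conclusion",
        "adme": "No conclusion",
        "predicted_internal_exposure": "No conclusion",
        "plausibility": "Uncertain",
    },
}


def interpret_slope(category: SlopeCategory) -> dict[str, str]:
    """Interpretive ledger for a slope regime.

    Keys: ``absolute_penetration``, ``relative_penetration``,
    ``small_dose_limit``, ``adme``, ``predicted_internal_exposure``,
    ``plausibility``.
    """
    return dict(_INTERPRETATIONS[SlopeCategory(category)])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def classification_summary(classifications) -> pd.DataFrame:
    """Counts and integer percentages per category.

    Percentages are computed against the total and rounded half-up, so
    they may not sum exactly to 100.
    """
    classifications = list(classifications)
    if not classifications:
        raise ValueError("no classifications supplied")
    total = len(classifications)
    rows = []
    for cat in SlopeCategory:
        n = sum(1 for c in classifications if c.category is cat)
        rows.append(
            {"category": cat.value, "n": n,
             "pct": _round_half_up(100.0 * n / total)}
        )
    return pd.DataFrame(rows).set_index("category")


def classifications_to_frame(classifications) -> pd.DataFrame:
    """Flat export: one row per classified stratum."""
    return pd.DataFrame(
        [
            {
                "stratum": c.stratum,
                "slope": c.slope,
                "ci_lo": c.ci[0],
                "ci_hi": c.ci[1],
                "ci_level": c.ci_level,
                "category": c.category.value,
                "note": c.note,
            }
            for c in classifications
        ]
    )
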