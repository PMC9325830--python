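"""Average dermal absorption estimators and the pro-rata comparator.

When absolute absorbed dose is taken to be directly proportional to
applied dose (log–log slope of 1), the intercept of the slope-1 line no
longer needs a regression: it is simply

    intercept = mean(log10(absorbed) - log10(applied)),

and back-transforming gives a single average relative dermal absorption
value usable at any exposure dose,

    DA_ave [%] = 10**intercept * 100,

which is algebraically the geometric mean of the per-dose-group relative
absorption percentages.  The free-slope analogue, DA_rel|model, back-
transforms the intercept of the fitted model instead.  Both are exposed
as scikit-learn-style estimators with ``predict`` mapping applied dose
to estimated internal (absorbed) dose.

The module also provides the concentration-based pro-rata rule used in
European guidance (scaling a tested relative absorption value inversely
with concentration) as a comparator, capped at 100%.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .loglog import LogLogFit, ModelForm, fit_loglog
from .study_data import (
    Endpoint,
    StudyTable,
    endpoint_series,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DAMethod",
    "DAEstimate",
    "AverageDermalAbsorption",
    "intercept_slope1",
    "da_ave",
    "da_rel_model",
    "predict_internal_dose",
    "worked_table",
    "pro_rata",
    "SlopeAboveOneWarning",
]


class SlopeAboveOneWarning(UserWarning):
    """The companion free-slope fit exceeds 1; a generic slope-1 average
    may under-predict risk at high doses and warrants case-by-case
    review."""


class DAMethod(str, enum.Enum):
    SLOPE1_AVERAGE = "slope1_average"
    FITTED_MODEL = "fitted_model"


@dataclass(frozen=True)
class DAEstimate:
    """A relative dermal absorption value with its provenance."""

    value_pct: float
    method: DAMethod
    intercept: float  # log10 units
    endpoint: Endpoint = Endpoint.RF
    n_groups: int = 1
    stratum: str = ""

    def __post_init__(self) -> None:
        if not self.value_pct > 0:
            raise ValueError(f"value_pct must be > 0, got {self.value_pct}")


def _check_pairs(pairs) -> np.ndarray:
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one (applied, absorbed) pair is required")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (applied, absorbed)")
    bad = np.where(~(arr > 0).all(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"non-positive applied or absorbed dose in pair(s) "
            f"{bad.tolist()}: log10 is undefined"
        )
    return arr


def intercept_slope1(pairs) -> float:
    """Slope-1 intercept: mean of log10(absorbed) − log10(applied)."""
    arr = _check_pairs(pairs)
    return float(np.mean(np.log10(arr[:, 1]) - np.log10(arr[:, 0])))


class AverageDermalAbsorption(RegressorMixin, BaseEstimator):
    """Slope-1 average dermal absorption estimator.

    ``fit`` takes applied doses and absolute absorbed doses (both
    µg/cm²); ``predict`` maps applied dose to estimated internal dose
    using the single averaged value.

    Parameters
    ----------
    endpoint : Endpoint or str
        Label of the absorption endpoint the absorbed doses represent.
    check_slope : bool, default True
        When possible (>= 3 groups), also fit the free-slope model and
        emit :class:`SlopeAboveOneWarning` if its slope exceeds 1, in
        which case a generic slope-1 average is not conservative.

    Attributes
    ----------
    intercept_ : float
        mean(log10 absorbed − log10 applied), log10 units.
    da_ave_pct_ : float
        ``10**intercept_ * 100`` — the average relative dermal
        absorption in percent; equal to the geometric mean of the
        per-group relative absorption values.
    slope_check_ : LogLogFit or None
        The companion free-slope fit, when computed.
    """

    def __init__(self, endpoint: Endpoint | str = Endpoint.RF,
                 check_slope: bool = True):
        self.endpoint = endpoint
        self.check_slope = check_slope

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        y = np.asarray(y, dtype=float)
        pairs = np.column_stack([X, y])
        self.intercept_ = intercept_slope1(pairs)
        self.da_ave_pct_ = 10.0 ** self.intercept_ * 100.0
        self.n_groups_ = int(X.size)
        self.slope_check_ = None
        if self.check_slope and X.size >= 3 and np.ptp(np.log10(X)) > 0:
            fit = fit_loglog(pairs, endpoint=self.endpoint)
            self.slope_check_ = fit
            if fit.slope > 1:
                warnings.warn(
                    f"fitted slope {fit.slope:.3g} exceeds 1; a slope-1 "
                    "average may under-predict absorption at high doses — "
                    "consider a case-by-case assessment",
                    SlopeAboveOneWarning,
                    stacklevel=2,
                )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        return X * self.da_ave_pct_ / 100.0

    def to_estimate(self, stratum: str = "") -> DAEstimate:
        return DAEstimate(
            value_pct=self.da_ave_pct_,
            method=DAMethod.SLOPE1_AVERAGE,
            intercept=self.intercept_,
            endpoint=Endpoint(self.endpoint),
            n_groups=self.n_groups_,
            stratum=stratum,
        )


def da_ave(pairs, endpoint: Endpoint | str = Endpoint.RF,
           stratum: str = "", check_slope: bool = True) -> DAEstimate:
    """Average dermal absorption (slope-1 geometric mean) from pairs."""
    arr = _check_pairs(pairs)
    est = AverageDermalAbsorption(endpoint=endpoint, check_slope=check_slope)
    est.fit(arr[:, 0], arr[:, 1])
    return est.to_estimate(stratum=stratum)


def da_rel_model(fit: LogLogFit) -> DAEstimate:
    """Model-based relative dermal absorption: 10^intercept × 100.

    Requires the absolute-absorbed-vs-dose model form; the intercept of
    the concentration model is not a relative absorption value.
    """
    if ModelForm(fit.model_form) is not ModelForm.ABSOLUTE_VS_DOSE:
        raise ValueError(
            "da_rel_model needs a fit of absolute absorbed dose on applied "
            f"dose, got model_form={fit.model_form!r}"
        )
    return DAEstimate(
        value_pct=10.0 ** fit.intercept * 100.0,
        method=DAMethod.FITTED_MODEL,
        intercept=fit.intercept,
        endpoint=Endpoint(fit.endpoint),
        n_groups=fit.n,
        stratum=fit.stratum,
    )


def predict_internal_dose(applied: float, da: DAEstimate) -> float:
    """Estimated internal dose (µg/cm²): applied × DA% / 100."""
    if not applied > 0:
        raise ValueError(f"applied dose must be > 0, got {applied!r}")
    return applied * da.value_pct / 100.0


def pro_rata(da_tested_pct: float, conc_tested: float,
             conc_target: float) -> float:
    """Concentration-based pro-rata extrapolation (comparator).

    Scales a tested relative absorption value inversely with
    concentration: a tested 1% at 1 g/L becomes 10% at 0.1 g/L. Capped
    at 100%, since a relative absorption above the applied dose is
    physically meaningless. Intended for extrapolating *below* the
    tested concentration; scaling upwards triggers a warning.
    """
    if min(da_tested_pct, conc_tested, conc_target) <= 0:
        raise ValueError("da_tested_pct, conc_tested and conc_target must all "
                         "be > 0")
    if conc_target > conc_tested:
        warnings.warn(
            "pro-rata is meant for extrapolation below the tested "
            "concentration; scaling down the DA value instead",
            UserWarning, stacklevel=2,
        )
    return min(100.0, da_tested_pct * conc_tested / conc_target)


#: Column order of the worked report.
WORKED_COLUMNS = [
    "product_id",
    "applied_dose",
    "da_pct",
    "absorbed_dose",
    "log10_applied",
    "log10_absorbed",
    "log10_difference",
    "mean_difference",
    "da_ave_pct",
    "predicted_absorbed",
]


def worked_table(study: StudyTable, endpoint: Endpoint | str = Endpoint.RF,
                 check_slope: bool = False) -> pd.DataFrame:
    """Per-group slope-1 worked calculation, one block per product.

    For each dose group: applied dose, relative DA%, absolute absorbed
    dose, the two decadic logs and their difference; per product: the
    mean log difference, DA_ave and the internal dose each group's
    applied dose predicts under DA_ave. A ``sum`` row per product totals
    applied, absorbed and predicted doses. All arithmetic is full
    precision; round only for display.
    """
    endpoint = Endpoint(endpoint)
    blocks = []
    for pid in study.product_ids:
        sub = study.filter(product_id=pid)
        pairs = np.asarray(endpoint_series(sub, endpoint), dtype=float)
        pairs = pairs[(pairs > 0).all(axis=1)]
        if pairs.size == 0:
            logger.warning("product %s: no usable dose group; skipped", pid)
            continue
        est = da_ave(pairs, endpoint=endpoint, stratum=pid,
                     check_slope=check_slope)
        applied, absorbed = pairs[:, 0], pairs[:, 1]
        block = pd.DataFrame(
            {
                "product_id": pid,
                "applied_dose": applied,
                "da_pct": 100.0 * absorbed / applied,
                "absorbed_dose": absorbed,
                "log10_applied": np.log10(applied),
                "log10_absorbed": np.log10(absorbed),
                "log10_difference": np.log10(absorbed) - np.log10(applied),
                "mean_difference": est.intercept,
                "da_ave_pct": est.value_pct,
                "predicted_absorbed": applied * est.value_pct / 100.0,
            }
        )
        total = pd.DataFrame(
            {
                "product_id": [f"{pid} (sum)"],
                "applied_dose": [applied.sum()],
                "da_pct": [np.nan],
                "absorbed_dose": [absorbed.sum()],
                "log10_applied": [np.nan],
                "log10_absorbed": [np.nan],
                "log10_difference": [np.nan],
                "mean_difference": [np.nan],
                "da_ave_pct": [np.nan],
                "predicted_absorbed": [block["predicted_absorbed"].sum()],
            }
        )
        blocks.append(pd.concat([block, total], ignore_index=True))
    if not blocks:
        raise ValueError("no product with a usable dose group")
    return pd.concat(blocks, ignore_index=True)[WORKED_COLUMNS]


def render_worked_table(report: pd.DataFrame, path=None,
                        fmt: str = "csv") -> str:
    """Render the worked report rounded to 2 dp as CSV or Markdown."""
    disp = report.copy()
    num = disp.select_dtypes("number").columns
    disp[num] = disp[num].round(2)
    if fmt == "markdown":
        text = disp.to_markdown(index=False)
    else:
        text = disp.to_csv(index=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
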