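"""Log–log linear models of dermal absorption data.

The central model is an ordinary least-squares fit on decadic-log scale,

    log10(absorbed dose) = slope * log10(applied dose) + intercept,

with absorbed and applied dose both in µg/cm².  A slope of 1 means the
absolute absorbed amount is directly proportional to the applied dose, so
relative absorption is constant; a slope of 0 means the absorbed amount
does not respond to dose at all.  The competing model form used in
European regulatory practice regresses relative absorption (% of applied)
on the concentration of the test preparation instead:

    log10(relative DA %) = slope * log10(concentration) + intercept.

Both forms are available, as is a mixed-effects variant with a random
intercept per product for multi-product databases, reported with
Nakagawa marginal/conditional R².

Note an algebraic fact that matters when comparing the two forms by AIC:
if every record's applied dose is exactly proportional to its
concentration (one fixed application volume), the concentration form is a
reparameterisation of the dose form — subtracting the predictor from the
response leaves OLS residuals unchanged — so their RSS and AIC are
identical. The forms can only be distinguished when dose and
concentration decouple (varying application volumes across studies).
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .study_data import Endpoint, StudyTable, endpoint_series, with_endpoint

logger = logging.getLogger(__name__)

__all__ = [
    "ModelForm",
    "LogLogFit",
    "MixedFit",
    "LogLogRegressor",
    "MixedLogLogRegressor",
    "fit_loglog",
    "slope_ci",
    "model_aic",
    "fit_mixed",
    "compare_model_forms",
    "stratified_fits",
    "fits_to_frame",
    "InsufficientDataError",
    "SingularDesignError",
]

#: number of estimated parameters in the Gaussian OLS likelihood
#: (slope, intercept, residual variance)
_K_OLS = 3


class InsufficientDataError(ValueError):
    """Fewer usable observations than the operation requires."""


class SingularDesignError(ValueError):
    """All predictor values identical: the slope is unidentifiable."""


class ModelForm(str, enum.Enum):
    ABSOLUTE_VS_DOSE = "absolute_vs_dose"
    RELATIVE_VS_CONCENTRATION = "relative_vs_concentration"


@dataclass(frozen=True)
class LogLogFit:
    """A fitted log10–log10 simple linear regression."""

    slope: float
    intercept: float  # log10 units
    se_slope: float
    se_intercept: float
    r2: float
    aic: float
    n: int
    residual_sd: float
    rss: float
    model_form: ModelForm = ModelForm.ABSOLUTE_VS_DOSE
    endpoint: Endpoint = Endpoint.RF
    stratum: str = ""

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        return slope_ci(self, level)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_form"] = self.model_form.value
        d["endpoint"] = self.endpoint.value
        return d


@dataclass(frozen=True)
class MixedFit:
    """A random-intercept-by-product mixed model on log10 scale.

    Variance components follow the Nakagawa decomposition: ``var_fixed``
    is the variance of the fixed-effect predictions, ``var_random`` the
    product random-intercept variance, ``var_resid`` the residual
    variance, and

        r2_marginal    = var_fixed / total
        r2_conditional = (var_fixed + var_random) / total.
    """

    slope: float
    intercept: float
    se_slope: float
    var_fixed: float
    var_random: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    aic: float  # ML-based, comparable across model forms
    n_products: int
    n_obs: int
    model_form: ModelForm = ModelForm.ABSOLUTE_VS_DOSE
    endpoint: Endpoint = Endpoint.RF


def _as_1d_positive(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-d (or a single column), got shape "
                         f"{arr.shape}")
    return arr


def _log_filter(x: np.ndarray, y: np.ndarray, stratum: str = ""):
    """Drop pairs that cannot enter a log-scale fit (x or y <= 0)."""
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning(
            "%s: %d record(s) with non-positive dose or absorption excluded "
            "from the log-scale fit", stratum or "fit", n_drop,
        )
    return x[ok], y[ok]


def _gaussian_aic(n: int, rss: float, k: int = _K_OLS) -> float:
    """Full Gaussian maximum-likelihood AIC, −2ℓ̂ + 2k.

    Returns ``-inf`` for a perfect fit (RSS = 0 up to float round-off):
    the Gaussian likelihood is unbounded there, and the sentinel makes
    the perfect fit win any AIC comparison, which is the intended
    reading. Round-off on exact power-law data leaves an RSS of order
    1e-30, hence the numerical-zero threshold.
    """
    if rss <= 1e-27 * n:
        return -math.inf
    return n * math.log(2 * math.pi * rss / n) + n + 2 * k


class LogLogRegressor(RegressorMixin, BaseEstimator):
    """OLS of log10(y) on log10(x), scikit-learn style.

    Parameters
    ----------
    model_form : ModelForm or str
        Which regression this fit represents: absolute absorbed dose on
        applied dose, or relative absorption on concentration. Metadata
        only; the arithmetic is the same.
    endpoint : Endpoint or str
        Absorption endpoint label (RF or POT). Metadata only.
    stratum : str
        Free-text label for stratified fits.

    Attributes
    ----------
    slope_, intercept_ : float
        Estimates on log10 scale. ``10**intercept_ * 100`` is the
        relative absorption (%) the model predicts at x = 1.
    se_slope_, se_intercept_, r2_, aic_, residual_sd_, rss_, n_ :
        the usual OLS summaries; ``aic_`` uses the full Gaussian
        likelihood with k = 3.

    Examples
    --------
    >>> import numpy as np
    >>> x = np.array([1.0, 10.0, 100.0])
    >>> reg = LogLogRegressor().fit(x, 10 * x ** 0.5)
    >>> round(reg.slope_, 6), round(reg.intercept_, 6)
    (0.5, 1.0)
    """

    def __init__(
        self,
        model_form: ModelForm | str = ModelForm.ABSOLUTE_VS_DOSE,
        endpoint: Endpoint | str = Endpoint.RF,
        stratum: str = "",
    ):
        self.model_form = model_form
        self.endpoint = endpoint
        self.stratum = stratum

    def fit(self, X, y):
        x = _as_1d_positive(X, "X")
        yv = _as_1d_positive(y, "y")
        if x.shape != yv.shape:
            raise ValueError("X and y must have the same length")
        x, yv = _log_filter(x, yv, str(self.stratum))
        if x.size < 2:
            raise InsufficientDataError(
                f"need >= 2 pairs with positive dose and absorption, "
                f"got {x.size}"
            )
        lx, ly = np.log10(x), np.log10(yv)
        if np.ptp(lx) == 0:
            raise SingularDesignError(
                "all predictor values identical; slope unidentifiable"
            )
        res = stats.linregress(lx, ly)
        fitted = res.intercept + res.slope * lx
        rss = float(np.sum((ly - fitted) ** 2))
        tss = float(np.sum((ly - ly.mean()) ** 2))
        n = int(lx.size)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        # SEs from RSS directly: robust where linregress yields NaN
        # (constant y, exact fits)
        sxx = float(np.sum((lx - lx.mean()) ** 2))
        s2 = rss / (n - 2) if n > 2 else 0.0
        self.se_slope_ = math.sqrt(s2 / sxx)
        self.se_intercept_ = math.sqrt(s2 * (1.0 / n + lx.mean() ** 2 / sxx))
        self.r2_ = 1.0 if tss == 0 else 1.0 - rss / tss
        self.rss_ = rss
        self.n_ = n
        self.df_ = n - 2
        self.residual_sd_ = math.sqrt(rss / (n - 2)) if n > 2 else 0.0
        self.aic_ = _gaussian_aic(n, rss)
        return self

    def predict(self, X):
        """Predicted y on the natural (µg/cm² or %) scale."""
        x = _as_1d_positive(X, "X")
        return 10 ** (self.intercept_ + self.slope_ * np.log10(x))

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided Wald t-interval for the slope."""
        if not 0 < level < 1:
            raise ValueError(f"level must be in (0, 1), got {level}")
        if self.df_ < 1:
            raise InsufficientDataError(
                "confidence interval needs n >= 3 (df = n - 2 >= 1)"
            )
        tq = stats.t.ppf(1 - (1 - level) / 2, self.df_)
        half = tq * self.se_slope_
        return (self.slope_ - half, self.slope_ + half)

    def to_fit(self) -> LogLogFit:
        return LogLogFit(
            slope=self.slope_,
            intercept=self.intercept_,
            se_slope=self.se_slope_,
            se_intercept=self.se_intercept_,
            r2=self.r2_,
            aic=self.aic_,
            n=self.n_,
            residual_sd=self.residual_sd_,
            rss=self.rss_,
            model_form=ModelForm(self.model_form),
            endpoint=Endpoint(self.endpoint),
            stratum=str(self.stratum),
        )


def fit_loglog(
    pairs,
    model_form: ModelForm | str = ModelForm.ABSOLUTE_VS_DOSE,
    endpoint: Endpoint | str = Endpoint.RF,
    stratum: str = "",
) -> LogLogFit:
    """Fit the log10–log10 line to (x, y) pairs and return the summary."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no pairs supplied")
    reg = LogLogRegressor(model_form=model_form, endpoint=endpoint,
                          stratum=stratum)
    reg.fit(arr[:, 0], arr[:, 1])
    return reg.to_fit()


def slope_ci(fit: LogLogFit, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for a fitted slope."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    df = fit.n - 2
    if df < 1:
        raise InsufficientDataError(
            "confidence interval needs n >= 3 (df = n - 2 >= 1)"
        )
    tq = stats.t.ppf(1 - (1 - level) / 2, df)
    return (fit.slope - tq * fit.se_slope, fit.slope + tq * fit.se_slope)


def model_aic(fit: LogLogFit) -> float:
    """Gaussian ML AIC of a fit (−inf sentinel when RSS = 0)."""
    return _gaussian_aic(fit.n, fit.rss)


def _form_pairs(table: StudyTable, model_form: ModelForm, endpoint: Endpoint):
    """(x, y) pairs for a model form; skips unusable records with a warning."""
    if model_form is ModelForm.ABSOLUTE_VS_DOSE:
        return endpoint_series(table, endpoint)
    pairs = []
    for i, rec in enumerate(table):
        da = with_endpoint(rec, endpoint)
        if da is None or rec.concentration is None:
            logger.warning(
                "record %d (product %s): missing concentration or "
                "compartments; skipped for concentration model",
                i, rec.product_id,
            )
            continue
        pairs.append((rec.concentration, da))
    return pairs


class MixedLogLogRegressor(BaseEstimator):
    """Random-intercept-per-product mixed model on log10 scale.

    Fits ``log10(y) ~ log10(x) + (1 | group)`` by REML (variance
    components) with an additional ML fit for a cross-model-comparable
    AIC. R² follows Nakagawa: the fixed-effect prediction variance over
    the total of fixed, random-intercept and residual variances
    (marginal), adding the random variance to the numerator
    (conditional).
    """

    def __init__(
        self,
        model_form: ModelForm | str = ModelForm.ABSOLUTE_VS_DOSE,
        endpoint: Endpoint | str = Endpoint.RF,
    ):
        self.model_form = model_form
        self.endpoint = endpoint

    def fit(self, X, y, groups=None):
        import statsmodels.formula.api as smf

        if groups is None:
            raise ValueError("groups (product labels) are required")
        x = _as_1d_positive(X, "X")
        yv = _as_1d_positive(y, "y")
        g = np.asarray(groups)
        ok = (x > 0) & (yv > 0) & np.isfinite(x) & np.isfinite(yv)
        x, yv, g = x[ok], yv[ok], g[ok]
        uniq, counts = np.unique(g, return_counts=True)
        if uniq.size < 2:
            raise InsufficientDataError(
                "mixed model needs >= 2 products; use fit_loglog for a "
                "single product"
            )
        df = pd.DataFrame({"lx": np.log10(x), "ly": np.log10(yv), "g": g})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reml = smf.mixedlm("ly ~ lx", df, groups=df["g"]).fit(reml=True)
            ml = smf.mixedlm("ly ~ lx", df, groups=df["g"]).fit(reml=False)
        self.slope_ = float(reml.fe_params["lx"])
        self.intercept_ = float(reml.fe_params["Intercept"])
        self.se_slope_ = float(reml.bse_fe["lx"])
        fixed_pred = self.intercept_ + self.slope_ * df["lx"].to_numpy()
        # Nakagawa components: var() of fixed predictions (ddof=1, the R
        # convention), REML random-intercept and residual variances
        self.var_fixed_ = float(np.var(fixed_pred, ddof=1))
        self.var_random_ = float(reml.cov_re.iloc[0, 0])
        self.var_resid_ = float(reml.scale)
        total = self.var_fixed_ + self.var_random_ + self.var_resid_
        self.r2_marginal_ = self.var_fixed_ / total
        self.r2_conditional_ = (self.var_fixed_ + self.var_random_) / total
        self.aic_ = float(-2 * ml.llf + 2 * 4)  # slope, intercept, tau2, sigma2
        self.n_products_ = int(uniq.size)
        self.n_obs_ = int(df.shape[0])
        return self

    def to_fit(self) -> MixedFit:
        return MixedFit(
            slope=self.slope_,
            intercept=self.intercept_,
            se_slope=self.se_slope_,
            var_fixed=self.var_fixed_,
            var_random=self.var_random_,
            var_resid=self.var_resid_,
            r2_marginal=self.r2_marginal_,
            r2_conditional=self.r2_conditional_,
            aic=self.aic_,
            n_products=self.n_products_,
            n_obs=self.n_obs_,
            model_form=ModelForm(self.model_form),
            endpoint=Endpoint(self.endpoint),
        )


def fit_mixed(
    table: StudyTable,
    model_form: ModelForm | str = ModelForm.ABSOLUTE_VS_DOSE,
    endpoint: Endpoint | str = Endpoint.RF,
) -> MixedFit:
    """Fit the product-random-intercept mixed model to a study table."""
    model_form = ModelForm(model_form)
    endpoint = Endpoint(endpoint)
    xs, ys, gs = [], [], []
    for rec in table:
        da = with_endpoint(rec, endpoint)
        if da is None or da <= 0:
            continue
        if model_form is ModelForm.ABSOLUTE_VS_DOSE:
            xs.append(rec.applied_dose)
            ys.append(rec.applied_dose * da / 100.0)
        else:
            if rec.concentration is None:
                continue
            xs.append(rec.concentration)
            ys.append(da)
        gs.append(rec.product_id)
    reg = MixedLogLogRegressor(model_form=model_form, endpoint=endpoint)
    reg.fit(np.asarray(xs), np.asarray(ys), groups=np.asarray(gs))
    return reg.to_fit()


def compare_model_forms(
    table: StudyTable, endpoint: Endpoint | str = Endpoint.RF
) -> dict:
    """Fit both model forms on the same records and tabulate slope/R²/AIC.

    Returns a dict with one entry per model form plus a ``caveat`` note:
    the two AICs belong to models with *different responses* (log10
    absolute absorbed vs log10 relative DA%), so the comparison is the
    conventional naive one, not a like-for-like likelihood comparison.
    When dose is exactly proportional to concentration the two AICs are
    equal by construction.
    """
    endpoint = Endpoint(endpoint)
    out: dict = {
        "caveat": (
            "AICs compare models with different response variables "
            "(naive cross-response comparison)"
        )
    }
    usable = [
        rec for rec in table
        if (da := with_endpoint(rec, endpoint)) is not None and da > 0
    ]
    sub = StudyTable(records=usable, provenance=table.provenance)
    have_conc = [r for r in usable if r.concentration is not None]
    if len(have_conc) >= 2:
        both = StudyTable(records=have_conc, provenance=table.provenance)
        for form in ModelForm:
            fit = fit_loglog(
                _form_pairs(both, form, endpoint), model_form=form,
                endpoint=endpoint, stratum="pooled",
            )
            out[form.value] = {"slope": fit.slope, "r2": fit.r2,
                               "aic": fit.aic, "n": fit.n, "fit": fit}
    else:
        logger.warning(
            "concentration missing on (nearly) all records; reporting the "
            "dose-form fit only"
        )
        form = ModelForm.ABSOLUTE_VS_DOSE
        fit = fit_loglog(
            _form_pairs(sub, form, endpoint), model_form=form,
            endpoint=endpoint, stratum="pooled",
        )
        out[form.value] = {"slope": fit.slope, "r2": fit.r2,
                           "aic": fit.aic, "n": fit.n, "fit": fit}
    return out


def stratified_fits(
    table: StudyTable,
    by,
    model_form: ModelForm | str = ModelForm.ABSOLUTE_VS_DOSE,
    endpoint: Endpoint | str = Endpoint.RF,
) -> list[LogLogFit]:
    """One log–log fit per stratum of the table.

    ``by`` is an iterable of record attribute names (e.g.
    ``["preparation"]`` or ``["product_id"]``). Strata with fewer than
    two usable records are skipped with a warning.
    """
    if len(table) == 0:
        raise InsufficientDataError("empty table")
    model_form = ModelForm(model_form)
    endpoint = Endpoint(endpoint)
    by = list(by)
    strata: dict[tuple, list] = {}
    for rec in table:
        key = tuple(
            v.value if isinstance(v, enum.Enum) else v
            for v in (getattr(rec, b) for b in by)
        )
        strata.setdefault(key, []).append(rec)
    fits = []
    for key, recs in strata.items():
        label = "/".join(str(k) for k in key)
        sub = StudyTable(records=recs, provenance=table.provenance)
        try:
            fits.append(
                fit_loglog(_form_pairs(sub, model_form, endpoint),
                           model_form=model_form, endpoint=endpoint,
                           stratum=label)
            )
        except (InsufficientDataError, SingularDesignError) as exc:
            logger.warning("stratum %s skipped: %s", label, exc)
    return fits


def fits_to_frame(fits, ci_level: float = 0.95) -> pd.DataFrame:
    """Flat one-row-per-fit table (for CSV/JSON export)."""
    rows = []
    for f in fits:
        try:
            lo, hi = slope_ci(f, ci_level)
        except InsufficientDataError:
            lo = hi = float("nan")
        rows.append(
            {
                "stratum": f.stratum,
                "model_form": f.model_form.value,
                "endpoint": f.endpoint.value,
                "slope": f.slope,
                "se_slope": f.se_slope,
                "ci_lo": lo,
                "ci_hi": hi,
                "intercept": f.intercept,
                "r2": f.r2,
                "aic": f.aic,
                "n": f.n,
            }
        )
    return pd.DataFrame(rows)
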