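"""Synthetic dermal absorption study generator.

Emulates the structure of regulatory in vitro study collections: each
product is tested at several in-use dilution concentrations; the applied
dose is coupled to the concentration through a fixed application volume
(10 µL/cm² is the conventional droplet-exposure volume, and with
concentration in g a.i./L, 1 g/L = 1 µg/µL, so dose in µg/cm² = volume ×
concentration); absorption follows the log–log line

    log10(absorbed) = intercept + u_product + slope · log10(dose) + ε,

with a Normal product random intercept ``u ~ N(0, tau²)`` and lognormal
residual noise ``ε ~ N(0, sigma²)`` on the decadic-log scale.  Relative
recovery is clipped to (0, 100] by rejection-resampling the residual, so
the log-scale noise stays approximately Gaussian.

Two dose–concentration regimes are available: the exact fixed-volume
coupling (Pearson r of the log values is 1 by construction), and
decoupled regimes via per-record volume jitter or a lognormal volume
spread, which mimic databases pooling studies with different application
volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .study_data import (
    DoseGroupRecord,
    Preparation,
    StudyTable,
    TestSystem,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "generate_study",
    "generate_database",
    "dose_concentration_correlation",
]

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study generator.

    Defaults mirror a typical multiple-concentration in vitro study:
    three in-use dilution concentrations spanning two orders of
    magnitude, a 10 µL/cm² application volume, dose-proportional
    absorption (slope 1) around a few-percent relative absorption level,
    and moderate lognormal noise.
    """

    n_products: int = 1
    concentrations_g_L: tuple[float, ...] = (0.5, 5.0, 50.0)
    application_volume_uL_cm2: float = 10.0
    true_slope: float = 1.0
    true_intercept: float = -1.5  # log10 units; 10**-1.5*100 ≈ 3.2 % DA
    sigma_resid: float = 0.2  # log10 residual sd
    tau_product: float = 0.0  # product random-intercept sd
    seed: int = 0
    formulation_code: str = "SC"
    preparation: Preparation = Preparation.DILUTION
    test_system: TestSystem = TestSystem.IN_VITRO_HUMAN
    product_prefix: str = "P"
    volume_jitter: float = 0.0  # uniform ±fraction on the volume, per record
    volume_sd_log10: float = 0.0  # lognormal volume spread, per record

    def __post_init__(self) -> None:
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")
        if len(self.concentrations_g_L) < 3:
            raise ValueError(
                "at least 3 concentrations per product are required "
                "(multiple-concentration study design)"
            )
        if any(c <= 0 for c in self.concentrations_g_L):
            raise ValueError("concentrations must be positive")
        if self.application_volume_uL_cm2 <= 0:
            raise ValueError("application volume must be positive")
        if self.sigma_resid < 0 or self.tau_product < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.volume_jitter < 1:
            raise ValueError("volume_jitter must be in [0, 1)")


def _draw_record(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    product_id: str,
    u_p: float,
    conc: float,
) -> tuple[DoseGroupRecord, int]:
    """One dose-group record; returns (record, resample count)."""
    vol = cfg.application_volume_uL_cm2
    if cfg.volume_jitter > 0:
        vol *= 1 + rng.uniform(-cfg.volume_jitter, cfg.volume_jitter)
    if cfg.volume_sd_log10 > 0:
        vol *= 10 ** rng.normal(0.0, cfg.volume_sd_log10)
    dose = vol * conc  # µg/cm²: (µL/cm²)·(g/L) with 1 g/L = 1 µg/µL
    mean_log = cfg.true_intercept + u_p + cfg.true_slope * np.log10(dose)
    resamples = 0
    for _ in range(_MAX_RESAMPLE):
        log_abs = mean_log + rng.normal(0.0, cfg.sigma_resid)
        rf_pct = 100.0 * 10**log_abs / dose
        if rf_pct <= 100.0:
            break
        resamples += 1
    else:
        raise RuntimeError(
            f"could not draw rf_pct <= 100 for {product_id} at "
            f"{conc} g/L; parameters place absorption above the applied dose"
        )
    rec = DoseGroupRecord(
        product_id=product_id,
        active_id=f"{product_id}_ai",
        formulation_code=cfg.formulation_code,
        test_system=cfg.test_system,
        preparation=cfg.preparation,
        applied_dose=float(dose),
        concentration=float(conc),
        observation_time=24.0,
        rf_pct=float(rf_pct),
    )
    return rec, resamples


def generate_study(config: GeneratorConfig) -> StudyTable:
    """Generate a multiple-concentration study table.

    Every product is tested at every configured concentration.
    Reproducible for a fixed seed. Records whose drawn relative recovery
    would exceed 100 % are re-drawn; the number of rejections is logged.
    """
    rng = np.random.default_rng(config.seed)
    records: list[DoseGroupRecord] = []
    n_resampled = 0
    for p in range(config.n_products):
        pid = f"{config.product_prefix}{p + 1}_{config.formulation_code}"
        u_p = rng.normal(0.0, config.tau_product) if config.tau_product else 0.0
        for conc in config.concentrations_g_L:
            rec, k = _draw_record(rng, config, pid, u_p, conc)
            records.append(rec)
            n_resampled += k
    if n_resampled:
        logger.warning(
            "rejection-resampled %d draw(s) with relative recovery > 100%%",
            n_resampled,
        )
    return StudyTable(
        records=records,
        provenance=f"synthetic (seed={config.seed})",
    )


def generate_database(configs) -> StudyTable:
    """EFSA-database-like table: one dose group per product (study).

    Takes an iterable of :class:`GeneratorConfig` (e.g. one per
    formulation type or preparation stratum); for each config every
    product contributes a single record at one randomly chosen
    concentration from the config's list — mirroring a database where
    most studies report one dose group each.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("at least one GeneratorConfig is required")
    records: list[DoseGroupRecord] = []
    for ci, cfg in enumerate(configs):
        rng = np.random.default_rng(cfg.seed)
        for p in range(cfg.n_products):
            pid = (
                f"{cfg.product_prefix}{p + 1}_{cfg.formulation_code}"
                f"_{cfg.preparation.value[:4]}"
            )
            u_p = rng.normal(0.0, cfg.tau_product) if cfg.tau_product else 0.0
            conc = float(rng.choice(np.asarray(cfg.concentrations_g_L)))
            rec, _ = _draw_record(rng, cfg, pid, u_p, conc)
            records.append(rec)
    return StudyTable(records=records, provenance="synthetic database")


def dose_concentration_correlation(table: StudyTable) -> float:
    """Pearson correlation of log10 applied dose and log10 concentration."""
    pairs = [
        (r.applied_dose, r.concentration)
        for r in table
        if r.concentration is not None
    ]
    if len(pairs) < 2:
        raise ValueError("need >= 2 records with both dose and concentration")
    arr = np.log10(np.asarray(pairs, dtype=float))
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError(
            "correlation undefined: dose or concentration is constant"
        )
    return float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])


def vary(config: GeneratorConfig, **changes) -> GeneratorConfig:
    """Copy of a config with fields replaced."""
    return replace(config, **changes)
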