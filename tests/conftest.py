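"""Shared fixtures: the worked-example study data and an independent
normal-equations OLS oracle used to cross-check the fitting routines."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dermabs import DoseGroupRecord, Preparation, StudyTable

# Three published worked examples: per-dose-group (applied dose µg/cm²,
# receptor-fluid recovery % of applied). The 16.45 µg/cm² dose of the CS
# product is reconstructed from the printed column sum (132.96) as the
# source cell is garbled.
WORKED_EXAMPLES = {
    "FMC_P2_CS": {
        "groups": [(62.37, 5.2), (31.43, 8.93), (22.71, 12.54), (16.45, 13.96)],
        "slope": 0.227,
        "mean_diff": -1.02,
        "da_ave": 9.50,
        "predicted": [5.92, 2.98, 2.16, 1.56],
        "sums": (132.96, 11.19, 12.62),
        "formulation": "CS",
    },
    "BAY_P6_WG": {
        "groups": [(29.7, 1.32), (14.8, 1.8), (8.8, 1.3)],
        "slope": 0.987,
        "mean_diff": -1.84,
        "da_ave": 1.46,
        "predicted": [0.43, 0.22, 0.13],
        "sums": (53.3, 0.77, 0.78),
        "formulation": "WG",
    },
    "SYN_P10_SC": {
        "groups": [(49.8, 2.54), (26.2, 3.0), (16.5, 1.29)],
        "slope": 1.56,
        "mean_diff": -1.67,
        "da_ave": 2.14,
        "predicted": [1.07, 0.56, 0.35],
        "sums": (92.5, 2.27, 1.98),
        "formulation": "SC",
    },
}


def worked_pairs(name: str) -> list[tuple[float, float]]:
    """(applied, absolute absorbed) pairs of a worked example."""
    return [
        (a, a * p / 100.0) for a, p in WORKED_EXAMPLES[name]["groups"]
    ]


@pytest.fixture(scope="session")
def worked_table_fixture() -> StudyTable:
    """The three worked-example products as one validated StudyTable."""
    records = []
    for pid, spec in WORKED_EXAMPLES.items():
        for applied, rf in spec["groups"]:
            records.append(
                DoseGroupRecord(
                    product_id=pid,
                    formulation_code=spec["formulation"],
                    preparation=Preparation.DILUTION,
                    applied_dose=applied,
                    rf_pct=rf,
                )
            )
    return StudyTable(records=records, provenance="published worked examples")


def ols_oracle(x, y):
    """Brute-force simple-OLS via the normal equations.

    Independent of the package's fitting path: plain sums, no library
    regression call. Returns slope, intercept, their standard errors and
    the residual sum of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    rss = float((resid * resid).sum())
    if n > 2:
        s2 = rss / (n - 2)
        sxx_c = sxx - sx * sx / n
        se_slope = math.sqrt(s2 / sxx_c)
        se_intercept = math.sqrt(s2 * (1.0 / n + (sx / n) ** 2 / sxx_c))
    else:
        se_slope = se_intercept = 0.0
    return slope, intercept, se_slope, se_intercept, rss


def gaussian_loglik(y, fitted):
    """Full Gaussian log-likelihood at the ML variance estimate."""
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = y.size
    sigma2 = float(((y - fitted) ** 2).sum()) / n
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
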