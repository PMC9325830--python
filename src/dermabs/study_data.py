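"""Data model, CSV I/O and endpoint arithmetic for dermal absorption studies.

A dermal absorption study (OECD TG 428 in vitro, or an in vivo rat study)
applies a test preparation at one or more doses to skin and, after the
observation period, recovers the radiolabel from a set of compartments.
This module holds one row per *dose group mean*: the applied dose in
µg/cm² together with the percentage of that dose recovered in the
receptor fluid (``rf_pct``), in the skin including stratum corneum
(``skin_pct``) and in the first two tape strips (``ts12_pct``), which by
convention are surface material and not absorbed.

Two absorption endpoints are derived from those compartments:

``RF``
    receptor-fluid recovery only (the systemic compartment for in vivo
    studies) — the minimal absorption endpoint.
``POT``
    the "potentially absorbed dose": receptor fluid plus skin residue
    minus tape strips 1–2.

Units are fixed: applied doses in µg/cm², concentrations in g a.i./L of
the test preparation, recoveries in percent of the applied dose. Zero
recoveries are valid data here; how they are handled on log scale is the
modelling modules' concern.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TestSystem",
    "Preparation",
    "Endpoint",
    "DoseGroupRecord",
    "StudyTable",
    "StudyDataError",
    "SchemaError",
    "ValidationError",
    "read_study_table",
    "write_study_table",
    "relative_to_absolute",
    "potentially_absorbed_pct",
    "endpoint_series",
]

#: CSV column names, in canonical order.
CSV_COLUMNS = [
    "product_id",
    "active_id",
    "formulation_code",
    "test_system",
    "preparation",
    "applied_dose_ug_cm2",
    "concentration_g_L",
    "observation_time_h",
    "rf_pct",
    "skin_pct",
    "ts12_pct",
]

REQUIRED_COLUMNS = ["product_id", "preparation", "applied_dose_ug_cm2"]
RECOVERY_COLUMNS = ["rf_pct", "skin_pct", "ts12_pct"]


class StudyDataError(ValueError):
    """Base class for study-data problems."""


class SchemaError(StudyDataError):
    """The CSV header does not provide the required columns."""


class ValidationError(StudyDataError):
    """A row violates a domain invariant; the message names the row."""


class TestSystem(str, enum.Enum):
    IN_VITRO_HUMAN = "in_vitro_human"
    IN_VITRO_RAT = "in_vitro_rat"
    IN_VIVO_RAT = "in_vivo_rat"


class Preparation(str, enum.Enum):
    CONCENTRATE = "concentrate"
    DILUTION = "dilution"


class Endpoint(str, enum.Enum):
    """Absorption endpoint: receptor fluid only, or potentially absorbed."""

    RF = "RF"
    POT = "POT"


@dataclass(frozen=True)
class DoseGroupRecord:
    """Mean results of one tested dose group of one study.

    For in vivo studies ``rf_pct`` carries the systemic dose; what the
    supplier counted as systemic (excreta, carcass, blood) is their
    definition, not enforced here.
    """

    product_id: str
    applied_dose: float  # µg/cm²
    preparation: Preparation
    rf_pct: float | None = None  # % of applied dose
    skin_pct: float | None = None
    ts12_pct: float | None = None
    concentration: float | None = None  # g a.i./L
    observation_time: float | None = None  # hours
    active_id: str = ""
    formulation_code: str = ""
    test_system: TestSystem = TestSystem.IN_VITRO_HUMAN

    def __post_init__(self) -> None:
        object.__setattr__(self, "preparation", Preparation(self.preparation))
        object.__setattr__(self, "test_system", TestSystem(self.test_system))
        if not (self.applied_dose > 0) or not math.isfinite(self.applied_dose):
            raise ValidationError(
                f"applied_dose must be a positive finite number, got "
                f"{self.applied_dose!r} (product {self.product_id!r})"
            )
        for name in ("rf_pct", "skin_pct", "ts12_pct"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(
                    f"{name} must be >= 0, got {v!r} (product {self.product_id!r})"
                )
        for name in ("concentration", "observation_time"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(
                    f"{name} must be > 0, got {v!r} (product {self.product_id!r})"
                )
        if (
            self.ts12_pct is not None
            and self.skin_pct is not None
            and self.ts12_pct > self.skin_pct
        ):
            raise ValidationError(
                f"ts12_pct ({self.ts12_pct}) exceeds skin_pct ({self.skin_pct}) "
                f"for product {self.product_id!r}: tape strips 1-2 are part of "
                f"the skin recovery and cannot exceed it"
            )

    @property
    def key(self) -> tuple:
        return (
            self.product_id,
            self.preparation.value,
            self.test_system.value,
            self.applied_dose,
            self.observation_time,
        )


@dataclass
class StudyTable:
    """Validated, ordered collection of dose-group records.

    Duplicate (product, preparation, test system, applied dose,
    observation time) keys are rejected: a dose group mean is unique
    within a study.
    """

    records: list[DoseGroupRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple, int] = {}
        for i, rec in enumerate(self.records):
            if rec.key in seen:
                raise ValidationError(
                    f"duplicate dose-group key {rec.key} at records "
                    f"{seen[rec.key]} and {i}"
                )
            seen[rec.key] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def product_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.product_id not in out:
                out.append(r.product_id)
        return out

    def filter(self, **fields) -> "StudyTable":
        """Sub-table of records whose attributes equal the given values."""
        recs = [
            r
            for r in self.records
            if all(getattr(r, k) == v for k, v in fields.items())
        ]
        return StudyTable(records=recs, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame with the canonical CSV columns."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "product_id": r.product_id,
                    "active_id": r.active_id,
                    "formulation_code": r.formulation_code,
                    "test_system": r.test_system.value,
                    "preparation": r.preparation.value,
                    "applied_dose_ug_cm2": r.applied_dose,
                    "concentration_g_L": r.concentration,
                    "observation_time_h": r.observation_time,
                    "rf_pct": r.rf_pct,
                    "skin_pct": r.skin_pct,
                    "ts12_pct": r.ts12_pct,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "StudyTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if not any(c in df.columns for c in RECOVERY_COLUMNS):
            raise SchemaError(
                "at least one recovery column is required "
                f"({', '.join(RECOVERY_COLUMNS)})"
            )
        records = []
        for idx, row in df.iterrows():
            try:
                records.append(
                    DoseGroupRecord(
                        product_id=str(row["product_id"]),
                        active_id=_opt_str(row.get("active_id")),
                        formulation_code=_opt_str(row.get("formulation_code")),
                        test_system=_opt_str(row.get("test_system"))
                        or TestSystem.IN_VITRO_HUMAN,
                        preparation=str(row["preparation"]),
                        applied_dose=_num(row["applied_dose_ug_cm2"], idx,
                                          "applied_dose_ug_cm2"),
                        concentration=_opt_num(row.get("concentration_g_L"),
                                               idx, "concentration_g_L"),
                        observation_time=_opt_num(row.get("observation_time_h"),
                                                  idx, "observation_time_h"),
                        rf_pct=_opt_num(row.get("rf_pct"), idx, "rf_pct"),
                        skin_pct=_opt_num(row.get("skin_pct"), idx, "skin_pct"),
                        ts12_pct=_opt_num(row.get("ts12_pct"), idx, "ts12_pct"),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}") from exc
        return cls(records=records, provenance=provenance)


def _opt_str(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v)


def _num(v, row: int, col: str) -> float:
    try:
        # unicode minus appears in copy-pasted tables
        if isinstance(v, str):
            v = v.replace("−", "-").strip()
        return float(v)
    except (TypeError, ValueError) as exc:
        raise StudyDataError(
            f"row {row}: non-numeric value {v!r} in column {col!r}"
        ) from exc


def _opt_num(v, row: int, col: str) -> float | None:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return _num(v, row, col)


def read_study_table(path, provenance: str | None = None) -> StudyTable:
    """Read and validate a study-results CSV.

    The file is comma-separated with a single header row; decimal dots;
    UTF-8. Both the ASCII hyphen-minus and the unicode minus sign are
    accepted in numeric cells. Rows violating invariants raise
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return StudyTable.from_frame(df, provenance=provenance or str(path))


def write_study_table(table: StudyTable, path) -> None:
    """Write a table using the canonical CSV schema."""
    table.to_frame().to_csv(path, index=False)


def relative_to_absolute(applied_dose: float, da_rel_pct: float) -> float:
    """Absolute absorbed dose (µg/cm²) from applied dose and relative DA%.

    ``applied × DA% / 100``: a 62.37 µg/cm² dose with 5.2 % receptor-fluid
    recovery corresponds to 3.24 µg/cm² absorbed.
    """
    if not applied_dose > 0:
        raise ValidationError(f"applied_dose must be > 0, got {applied_dose!r}")
    if da_rel_pct < 0:
        raise ValidationError(f"da_rel_pct must be >= 0, got {da_rel_pct!r}")
    return applied_dose * da_rel_pct / 100.0


def potentially_absorbed_pct(
    rf_pct: float, skin_pct: float, ts12_pct: float
) -> float:
    """Potentially absorbed dose in % of applied: RF + skin − tape strips 1–2."""
    if min(rf_pct, skin_pct, ts12_pct) < 0:
        raise ValidationError("recoveries must be >= 0")
    if ts12_pct > skin_pct:
        raise ValidationError(
            f"ts12_pct ({ts12_pct}) > skin_pct ({skin_pct}): tape strips "
            "cannot remove more than the skin holds"
        )
    return rf_pct + skin_pct - ts12_pct


def _record_da_pct(rec: DoseGroupRecord, endpoint: Endpoint) -> float | None:
    endpoint = Endpoint(endpoint)
    if endpoint is Endpoint.RF:
        return rec.rf_pct
    if rec.rf_pct is None or rec.skin_pct is None:
        return None
    return potentially_absorbed_pct(
        rec.rf_pct, rec.skin_pct, rec.ts12_pct or 0.0
    )


def endpoint_series(
    table: StudyTable, endpoint: Endpoint | str = Endpoint.RF
) -> list[tuple[float, float]]:
    """(applied dose, absolute absorbed dose) pairs for one endpoint.

    Records missing the compartments the endpoint needs are skipped with
    a logged warning; if no record supports the endpoint an error is
    raised rather than returning an empty series.
    """
    endpoint = Endpoint(endpoint)
    pairs: list[tuple[float, float]] = []
    for i, rec in enumerate(table):
        da = _record_da_pct(rec, endpoint)
        if da is None:
            logger.warning(
                "record %d (product %s): missing compartments for endpoint "
                "%s; skipped", i, rec.product_id, endpoint.value,
            )
            continue
        pairs.append((rec.applied_dose, relative_to_absolute(rec.applied_dose, da)))
    if not pairs:
        raise StudyDataError(
            f"no record provides the compartments needed for endpoint "
            f"{endpoint.value}"
        )
    return pairs


def with_endpoint(rec: DoseGroupRecord, endpoint: Endpoint) -> float | None:
    """Relative DA% of a record under an endpoint (None if unavailable)."""
    return _record_da_pct(rec, endpoint)


def replace_record(rec: DoseGroupRecord, **changes) -> DoseGroupRecord:
    return replace(rec, **changes)
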