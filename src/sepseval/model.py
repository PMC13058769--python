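"""Core EHR data model: concept vocabulary, tabular I/O, cohort filters.

The package works on three delimited tables:

* **events** — one row per timestamped clinical observation or action
  (``encounter_id,patient_id,time,kind,concept,value,antibiotic_name``);
* **encounters** — one row per hospital encounter with type, unit timeline
  and demographics;
* **predictions** — one row per emitted model score
  (``encounter_id,time,score``), scores on a 0–100 scale.

Timestamps are timezone-naive at minute resolution throughout: lead times
are reported in hours, so sub-minute precision carries no information.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger("sepseval")

# ---------------------------------------------------------------------------
# Controlled vocabulary
# ---------------------------------------------------------------------------

#: Concepts carrying a numeric value.
MEASUREMENT_CONCEPTS: set[str] = {
    "temperature_c",
    "heart_rate",
    "resp_rate",
    "sbp_mmHg",
    "map_mmHg",
    "wbc_k_per_uL",
    "band_pct",
    "lactate_mmol_L",
    "creatinine_mg_dL",
    "bilirubin_mg_dL",
    "platelets_k_per_uL",
    "inr",
    "pao2_fio2",
    "gcs",
}

#: Pure actions — no numeric value.
ACTION_CONCEPTS: set[str] = {
    "blood_culture_order",
    "lactate_order",
    "iv_antibiotic_admin",
    "vasopressor_admin",
    "mech_vent_start",
}

EVENT_KINDS = {"vital", "lab", "med_admin", "order", "procedure"}
ENCOUNTER_TYPES = {"direct_admission", "ed_only", "ed_to_hosp", "ob_to_hosp", "or_to_hosp"}
HOSPITAL_TYPES = {"academic", "community", "critical_access"}
UNITS = {"ED", "ward", "ICU"}
DEFINITIONS = ("sepsis3", "sep1", "ase")

#: Treatment-initiation concepts used by the pre-treatment censoring analysis.
SEPSIS_ACTION_CONCEPTS = {"lactate_order", "blood_culture_order", "iv_antibiotic_admin"}

EVENT_COLUMNS = ["encounter_id", "patient_id", "time", "kind", "concept", "value", "antibiotic_name"]
ENCOUNTER_COLUMNS = [
    "encounter_id",
    "patient_id",
    "arrival_time",
    "discharge_time",
    "encounter_type",
    "hospital_type",
    "unit_intervals",
    "age_years",
    "sex",
    "race",
    "ethnicity",
    "esi",
    "died_in_hospital",
    "context",
]
PREDICTION_COLUMNS = ["encounter_id", "time", "score"]


def known_concepts() -> set[str]:
    """The full concept vocabulary (fixed set plus registered extensions)."""
    return MEASUREMENT_CONCEPTS | ACTION_CONCEPTS


def register_concept(name: str, *, measured: bool) -> None:
    """Extend the concept vocabulary.

    Raw EHR code mapping happens upstream of this package; the registry
    exists so a site can admit additional mapped concepts without editing
    the vocabulary in place.
    """
    if measured:
        MEASUREMENT_CONCEPTS.add(name)
    else:
        ACTION_CONCEPTS.add(name)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """A table is missing required columns or uses unknown codes."""


class RowError(ValueError):
    """A row-level parse failure; the message names offending lines."""


class UndefinedMetricError(ValueError):
    """A metric is undefined on the given input (e.g. single-class labels)."""


class ConfigError(ValueError):
    """An infeasible configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class CohortConfig(BaseModel):
    """Cohort inclusion rules.

    The study population keeps adult encounters with a hospital stay of at
    least ``min_stay_hours`` (default 1 h) that did not begin in one of the
    excluded contexts.
    """

    min_stay_hours: float = 1.0
    excluded_encounter_contexts: set[str] = Field(
        default_factory=lambda: {
            "endoscopy",
            "psychiatric_direct_admission",
            "ed_to_labor_and_delivery",
        }
    )
    prediction_cadence_minutes: int = 15
    #: Events up to this many hours before arrival are admitted to criteria
    #: evaluation; 0 restricts to events at/after arrival.
    pre_arrival_lookback_hours: float = 0.0

    @field_validator("min_stay_hours")
    @classmethod
    def _positive_stay(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("min_stay_hours must be > 0")
        return v

    @field_validator("prediction_cadence_minutes")
    @classmethod
    def _positive_cadence(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("prediction_cadence_minutes must be > 0")
        return v


# ---------------------------------------------------------------------------
# Timestamp handling
# ---------------------------------------------------------------------------


def _parse_times(raw: pd.Series, *, what: str) -> pd.Series:
    """Parse ISO 8601 strings to minute-resolution timestamps.

    Unparseable rows raise :class:`RowError` naming 1-based data line
    numbers (header excluded).
    """
    parsed = pd.to_datetime(raw, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        lines = [int(i) + 2 for i in raw.index[bad][:20]]  # +2: header + 1-based
        raise RowError(f"unparseable {what} timestamps at file lines {lines}")
    if parsed.isna().any():
        lines = [int(i) + 2 for i in raw.index[parsed.isna()][:20]]
        raise RowError(f"missing {what} timestamps at file lines {lines}")
    return parsed.dt.floor("min")


def _require_columns(df: pd.DataFrame, required: Iterable[str], *, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing required columns: {missing}")


# ---------------------------------------------------------------------------
# Events I/O
# ---------------------------------------------------------------------------


def read_events(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an event table from CSV.

    Parameters
    ----------
    path:
        CSV with columns ``encounter_id,patient_id,time,kind,concept,value,
        antibiotic_name`` (``antibiotic_name`` optional unless antibiotic
        administrations are present).
    schema:
        Optional map from canonical column name to the file's column name.

    Returns events sorted by ``(encounter_id, time)``.  Unknown concepts or
    kinds raise :class:`SchemaError` naming the offending codes; value
    presence must match the concept class (present iff measurement).
    """
    df = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if "antibiotic_name" not in df.columns:
        df["antibiotic_name"] = pd.NA
    _require_columns(df, [c for c in EVENT_COLUMNS if c != "antibiotic_name"], table="events")

    unknown = sorted(set(df["concept"]) - known_concepts())
    if unknown:
        raise SchemaError(f"unknown concept codes: {unknown}")
    bad_kinds = sorted(set(df["kind"]) - EVENT_KINDS)
    if bad_kinds:
        raise SchemaError(f"unknown event kinds: {bad_kinds}")

    df["time"] = _parse_times(df["time"], what="event")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    is_meas = df["concept"].isin(MEASUREMENT_CONCEPTS)
    missing_val = is_meas & df["value"].isna()
    if missing_val.any():
        raise RowError(
            f"measurement events without a value at file lines "
            f"{[int(i) + 2 for i in df.index[missing_val][:20]]}"
        )
    stray_val = ~is_meas & df["value"].notna()
    if stray_val.any():
        raise RowError(
            f"action events carrying a value at file lines "
            f"{[int(i) + 2 for i in df.index[stray_val][:20]]}"
        )
    negative = is_meas & (df["value"] < 0)
    if negative.any():
        raise RowError(
            f"negative physiologic values at file lines "
            f"{[int(i) + 2 for i in df.index[negative][:20]]}"
        )
    abx = df["concept"] == "iv_antibiotic_admin"
    if (abx & df["antibiotic_name"].isna()).any():
        raise RowError("iv_antibiotic_admin events require antibiotic_name")
    df["antibiotic_name"] = (
        df["antibiotic_name"].astype(object).where(df["antibiotic_name"].notna(), None)
    )

    df = df.sort_values(["encounter_id", "time"], kind="stable").reset_index(drop=True)
    logger.info("read_events: %d events, %d encounters", len(df), df["encounter_id"].nunique())
    return df[EVENT_COLUMNS]


def write_events(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M")
    out[EVENT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Encounters I/O
# ---------------------------------------------------------------------------


def _intervals_to_json(intervals) -> str:
    return json.dumps(
        [
            [u, pd.Timestamp(s).strftime("%Y-%m-%dT%H:%M"), pd.Timestamp(e).strftime("%Y-%m-%dT%H:%M")]
            for u, s, e in intervals
        ]
    )


def _intervals_from_json(s: str):
    return [(u, pd.Timestamp(a), pd.Timestamp(b)) for u, a, b in json.loads(s)]


def read_encounters(path) -> pd.DataFrame:
    """Read an encounter table; ``unit_intervals`` is a JSON column of
    ``[unit, start, end]`` triples covering the stay."""
    df = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str})
    _require_columns(
        df,
        [c for c in ENCOUNTER_COLUMNS if c not in ("context", "esi")],
        table="encounters",
    )
    for col in ("arrival_time", "discharge_time"):
        df[col] = _parse_times(df[col], what=col)
    if not (df["discharge_time"] > df["arrival_time"]).all():
        raise RowError("discharge_time must be after arrival_time")
    bad_type = sorted(set(df["encounter_type"]) - ENCOUNTER_TYPES)
    if bad_type:
        raise SchemaError(f"unknown encounter types: {bad_type}")
    if (df["age_years"] < 18).any():
        raise RowError("cohort is adult-only: age_years must be >= 18")
    df["unit_intervals"] = df["unit_intervals"].map(_intervals_from_json)
    if "esi" in df.columns:
        df["esi"] = df["esi"].astype("Int64")
    else:
        df["esi"] = pd.array([pd.NA] * len(df), dtype="Int64")
    if "context" not in df.columns:
        df["context"] = pd.NA
    df["died_in_hospital"] = df["died_in_hospital"].astype(bool)
    return df[ENCOUNTER_COLUMNS]


def write_encounters(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["unit_intervals"] = out["unit_intervals"].map(_intervals_to_json)
    for col in ("arrival_time", "discharge_time"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M")
    cols = [c for c in ENCOUNTER_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Predictions I/O
# ---------------------------------------------------------------------------


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str})
    _require_columns(df, PREDICTION_COLUMNS, table="predictions")
    df["time"] = _parse_times(df["time"], what="prediction")
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    if df["score"].isna().any() or (df["score"] < 0).any() or (df["score"] > 100).any():
        raise RowError("prediction scores must be numeric in [0, 100]")
    return df.sort_values(["encounter_id", "time"], kind="stable").reset_index(drop=True)[
        PREDICTION_COLUMNS
    ]


def write_predictions(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M")
    out[PREDICTION_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort filters and report arithmetic
# ---------------------------------------------------------------------------


def apply_inclusion_filters(
    encounters: pd.DataFrame, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study inclusion filters.

    Encounters with a stay shorter than ``min_stay_hours`` or that began in
    an excluded context are removed.  Returns the included table and a tally
    of exclusions by reason; counts always conserve:
    ``len(input) == len(included) + sum(tally.values())``.
    """
    config = config or CohortConfig()
    stay_h = (
        pd.to_datetime(encounters["discharge_time"]) - pd.to_datetime(encounters["arrival_time"])
    ).dt.total_seconds() / 3600.0

    tally: Counter[str] = Counter()
    if "context" in encounters.columns:
        ctx = encounters["context"].isin(config.excluded_encounter_contexts)
    else:
        ctx = pd.Series(False, index=encounters.index)
    short = ~ctx & (stay_h < config.min_stay_hours)
    tally["excluded_context"] = int(ctx.sum())
    tally["short_stay"] = int(short.sum())
    tally = Counter({k: v for k, v in tally.items() if v})

    included = encounters[~ctx & ~short].reset_index(drop=True)
    logger.info(
        "inclusion filters: %d in, %d included, %s excluded",
        len(encounters),
        len(included),
        dict(tally),
    )
    return included, dict(tally)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention
    for reported percentages and NNE)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to 1 decimal."""
    if denominator <= 0:
        raise ConfigError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, 1)


def incidence(case_count: int, cohort_count: int) -> float:
    """Outcome incidence as a percentage with 1 decimal (half-up)."""
    if cohort_count <= 0:
        raise ConfigError("cohort_count must be positive")
    if not 0 <= case_count <= cohort_count:
        raise ConfigError("case_count must be within [0, cohort_count]")
    return percentage(case_count, cohort_count)


def nne_from_precision(precision: float) -> float:
    """Number of encounters needing evaluation per true positive (1/precision)."""
    if precision <= 0:
        raise UndefinedMetricError("NNE undefined at zero precision")
    return 1.0 / precision
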