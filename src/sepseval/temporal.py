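"""Temporal evaluation: encounter- and horizon-level instances, lead times,
and pre-treatment censoring of the prediction stream.

Conventions (all boundaries "strictly before"): encounter-level instances
take the maximum score over predictions strictly before
``min(time_zero, discharge)``; a score emitted at the moment of outcome
recognition is not advance warning, so ties at the exact timestamp are
excluded.  Horizon instances label each pre-time-zero prediction positive
iff time zero falls within the horizon; post-time-zero predictions of case
encounters are excluded by default (configurable to count as positives
instead).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import SEPSIS_ACTION_CONCEPTS, ConfigError, logger

_SUBGROUP_FIELDS = [
    "patient_id",
    "encounter_type",
    "hospital_type",
    "sex",
    "race",
    "ethnicity",
    "esi",
    "age_years",
    "arrival_time",
]


def _labels_for(labels: pd.DataFrame, definition: str | None) -> pd.DataFrame:
    if "definition" in labels.columns and definition is not None:
        labels = labels[labels["definition"] == definition]
    return labels[["encounter_id", "is_case", "time_zero"]]


def build_encounter_instances(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    encounters: pd.DataFrame,
    definition: str | None = None,
) -> pd.DataFrame:
    """One instance per encounter: the highest score before the outcome time
    zero or hospital discharge, with the definition's case label.

    Encounters with no eligible prediction get ``max_score_pre_t0 = NaN``
    and are excluded from metric computation downstream (count logged).
    """
    lab = _labels_for(labels, definition)
    enc = encounters[["encounter_id"] + [c for c in _SUBGROUP_FIELDS if c in encounters.columns]]
    base = enc.merge(encounters[["encounter_id", "discharge_time"]], on="encounter_id")
    base = base.merge(lab, on="encounter_id", how="left", validate="one_to_one")
    if base["is_case"].isna().any():
        raise ConfigError("labels missing for some encounters")
    cutoff = base["time_zero"].fillna(base["discharge_time"])
    cutoff = np.minimum(pd.to_datetime(cutoff), pd.to_datetime(base["discharge_time"]))
    base = base.assign(_cutoff=cutoff.to_numpy())

    p = predictions.merge(base[["encounter_id", "_cutoff"]], on="encounter_id", how="inner")
    p = p[p["time"] < p["_cutoff"]]
    mx = p.groupby("encounter_id")["score"].max().rename("max_score_pre_t0")

    out = base.merge(mx, on="encounter_id", how="left").drop(columns=["_cutoff", "discharge_time"])
    out["label"] = out["is_case"].astype(bool)
    n_missing = int(out["max_score_pre_t0"].isna().sum())
    if n_missing:
        logger.info("encounter instances: %d encounters with no eligible prediction", n_missing)
    return out


def build_horizon_instances(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    encounters: pd.DataFrame,
    horizon_hours: float,
    definition: str | None = None,
    post_t0: str = "exclude",
) -> pd.DataFrame:
    """Prediction-level instances for a fixed early-warning horizon.

    Each prediction of a case encounter made strictly before time zero is
    labeled positive iff ``time_zero − prediction_time ≤ horizon``.
    Non-case encounters contribute all their predictions as negatives.
    ``post_t0``: ``"exclude"`` drops case predictions at/after time zero
    (default), ``"positive"`` keeps them labeled positive.
    """
    if horizon_hours <= 0:
        raise ConfigError("horizon_hours must be positive")
    if post_t0 not in ("exclude", "positive"):
        raise ConfigError("post_t0 must be 'exclude' or 'positive'")
    lab = _labels_for(labels, definition)
    p = predictions.merge(lab, on="encounter_id", how="inner")
    t0 = pd.to_datetime(p["time_zero"])
    gap_h = (t0 - pd.to_datetime(p["time"])).dt.total_seconds() / 3600.0

    is_case = p["is_case"].astype(bool)
    pre_t0 = gap_h > 0
    if post_t0 == "exclude":
        keep = ~is_case | pre_t0
        label = is_case & pre_t0 & (gap_h <= horizon_hours)
    else:
        keep = pd.Series(True, index=p.index)
        label = is_case & (gap_h <= horizon_hours)

    out = p[keep].assign(label=label[keep], horizon_hours=horizon_hours)[
        ["encounter_id", "time", "score", "label", "horizon_hours"]
    ].rename(columns={"time": "prediction_time"})
    out = _attach_units(out, encounters)
    return out.reset_index(drop=True)


def _attach_units(instances: pd.DataFrame, encounters: pd.DataFrame) -> pd.DataFrame:
    """Resolve the unit at each prediction by half-open [start, end) interval
    containment on the encounter's unit timeline."""
    rows = []
    for enc_id, intervals in zip(encounters["encounter_id"], encounters["unit_intervals"]):
        for u, s, e in intervals:
            rows.append((enc_id, u, s, e))
    iv = pd.DataFrame(rows, columns=["encounter_id", "unit", "_start", "_end"])
    m = instances.merge(iv, on="encounter_id", how="left")
    inside = (m["prediction_time"] >= m["_start"]) & (m["prediction_time"] < m["_end"])
    m = m[inside | m["unit"].isna()]
    m = m.drop_duplicates(subset=["encounter_id", "prediction_time"], keep="first")
    out = instances.merge(
        m[["encounter_id", "prediction_time", "unit"]],
        on=["encounter_id", "prediction_time"],
        how="left",
    ).rename(columns={"unit": "unit_at_prediction"})
    return out


def censor_before_actions(
    predictions: pd.DataFrame,
    events: pd.DataFrame,
    action_concepts=("lactate_order", "blood_culture_order", "iv_antibiotic_admin"),
) -> pd.DataFrame:
    """Keep only predictions strictly before the encounter's first
    sepsis-related clinical action (lactate order, blood culture order, or
    IV antibiotic).  Encounters with no such action keep all predictions.
    """
    bad = set(action_concepts) - SEPSIS_ACTION_CONCEPTS
    if not action_concepts or bad:
        raise ConfigError(
            f"action_concepts must be a nonempty subset of {sorted(SEPSIS_ACTION_CONCEPTS)}; got {bad}"
        )
    acts = events[events["concept"].isin(set(action_concepts))]
    first_action = acts.groupby("encounter_id")["time"].min().rename("_first_action")
    p = predictions.merge(first_action, on="encounter_id", how="left")
    keep = p["_first_action"].isna() | (p["time"] < p["_first_action"])
    out = p[keep].drop(columns="_first_action").reset_index(drop=True)
    logger.info(
        "pre-treatment censoring: kept %d/%d predictions", len(out), len(predictions)
    )
    return out


def first_crossing(predictions: pd.DataFrame, threshold: float):
    """Time of the first prediction with score ≥ threshold (one encounter's
    stream, time-sorted); None if the threshold is never reached."""
    if not 0 <= threshold <= 100:
        raise ConfigError("threshold must be within [0, 100]")
    hit = predictions[predictions["score"] >= threshold]
    return None if hit.empty else pd.Timestamp(hit["time"].iloc[0])


def first_crossings(predictions: pd.DataFrame, threshold: float) -> pd.Series:
    """Vectorized first crossing time per encounter."""
    if not 0 <= threshold <= 100:
        raise ConfigError("threshold must be within [0, 100]")
    hit = predictions[predictions["score"] >= threshold]
    return hit.groupby("encounter_id")["time"].min()


def lead_times(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    threshold: float,
    definition: str | None = None,
):
    """Warning time between the first threshold crossing and time zero.

    Returns ``(records, summary)``: one record per case with the crossing
    time and ``lead_hours`` (absent when the stream never crosses before
    time zero); the summary holds the median and IQR over cases with a
    defined lead plus tallies of never-crossing and late-detection
    (crossing at/after time zero) cases.
    """
    lab = _labels_for(labels, definition)
    cases = lab[lab["is_case"].astype(bool)].copy()
    fc = first_crossings(predictions, threshold).rename("first_crossing_time")
    rec = cases.merge(fc, on="encounter_id", how="left")
    t0 = pd.to_datetime(rec["time_zero"])
    crossed = rec["first_crossing_time"].notna()
    early = crossed & (rec["first_crossing_time"] < t0)
    lead = (t0 - pd.to_datetime(rec["first_crossing_time"])).dt.total_seconds() / 3600.0
    rec["lead_hours"] = lead.where(early)
    rec["threshold"] = threshold

    detected = rec.loc[early, "lead_hours"]
    summary = {
        "threshold": threshold,
        "n_cases": int(len(rec)),
        "n_detected_early": int(early.sum()),
        "n_late_detection": int((crossed & ~early).sum()),
        "n_never_crossed": int((~crossed).sum()),
        "median_lead_hours": float(detected.median()) if len(detected) else None,
        "q1_lead_hours": float(detected.quantile(0.25)) if len(detected) else None,
        "q3_lead_hours": float(detected.quantile(0.75)) if len(detected) else None,
    }
    return rec[["encounter_id", "threshold", "first_crossing_time", "lead_hours"]], summary
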