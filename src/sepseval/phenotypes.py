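"""Computable sepsis phenotypes: Sepsis-3, SEP-1 (severe sepsis) and the
CDC Adult Sepsis Event, each with a per-encounter case flag, time zero and
criterion-level provenance.

Time zero is the earliest timestamp at which an encounter satisfies a
definition's qualifying criteria:

* **Sepsis-3** — suspected infection (blood culture and IV antibiotic
  paired within standard windows) with an acute SOFA rise of ≥ 2 points in
  a (−48 h, +24 h) window around the suspicion time; time zero is the
  suspicion time of the earliest qualifying pair.
* **SEP-1** — two or more SIRS criteria concurrent with at least one
  organ-dysfunction criterion inside a rolling window; time zero is the
  earliest moment the conjunction completes.
* **ASE** — blood culture, a qualifying antibiotic-day run (≥ 4 calendar
  days, new start within ± 2 days of the culture, death exception) and
  concurrent organ dysfunction within ± 2 calendar days of the culture;
  time zero defaults to the minimum over the three component times.

Criterion thresholds and windows are reconstructed from the primary
published definitions and are all overridable through
:class:`CriteriaConfig`, since operational implementations differ by site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .model import logger

HOUR = np.timedelta64(60, "m")


class CriteriaConfig(BaseModel):
    """Windows, thresholds and conventions for the three definitions."""

    # suspected infection pairing (Sepsis-3 convention)
    abx_after_culture_hours: float = 72.0
    culture_after_abx_hours: float = 24.0

    # SOFA evaluation around suspicion
    sofa_window_before_hours: float = 48.0
    sofa_window_after_hours: float = 24.0
    sofa_component_lookback_hours: float = 24.0
    sofa_delta: int = 2

    # SIRS / SEP-1 rolling concurrency windows
    sirs_window_hours: float = 6.0
    sep1_window_hours: float = 6.0

    # SIRS thresholds (strict inequalities per the SEP-1 wording)
    sirs_temp_high_c: float = 38.3
    sirs_temp_low_c: float = 36.0
    sirs_hr: float = 90.0
    sirs_rr: float = 20.0
    sirs_wbc_high: float = 12.0
    sirs_wbc_low: float = 4.0
    sirs_band_pct: float = 10.0

    # SEP-1 organ dysfunction (strict inequalities)
    sep1_sbp: float = 90.0
    sep1_map: float = 65.0
    sep1_sbp_drop: float = 40.0
    sep1_lactate: float = 2.0
    sep1_creatinine: float = 2.0
    sep1_bilirubin: float = 2.0
    sep1_platelets: float = 100.0
    sep1_inr: float = 1.5

    # ASE
    ase_culture_window_days: int = 2
    qad_min_days: int = 4
    qad_gap_days: int = 1
    ase_lactate: float = 2.0  # inclusive (>=) per the ASE wording
    ase_creatinine_ratio: float = 2.0
    ase_bilirubin_abs: float = 2.0
    ase_bilirubin_ratio: float = 2.0
    ase_platelets_abs: float = 100.0
    ase_platelet_decline: float = 0.5
    ase_time_zero_mode: str = "min_components"  # or "culture"

    # events earlier than arrival − lookback are ignored
    pre_arrival_lookback_hours: float = 0.0


@dataclass
class SepsisLabel:
    """Case status, time zero and criterion provenance for one definition."""

    encounter_id: str
    definition: str
    is_case: bool
    time_zero: pd.Timestamp | None
    components: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-encounter event view
# ---------------------------------------------------------------------------


class EncounterEvents:
    """Concept-indexed numpy view of one encounter's sorted events."""

    def __init__(self, events: pd.DataFrame):
        self.times = events["time"].to_numpy()
        self.concepts = events["concept"].to_numpy()
        self.values = events["value"].to_numpy(dtype=float)
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def concept_series(self, concept: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) for one concept, time-sorted."""
        if concept not in self._cache:
            m = self.concepts == concept
            self._cache[concept] = (self.times[m], self.values[m])
        return self._cache[concept]

    def times_of(self, concept: str) -> np.ndarray:
        return self.concept_series(concept)[0]


def _as_view(events) -> EncounterEvents:
    return events if isinstance(events, EncounterEvents) else EncounterEvents(events)


def _in_window(times: np.ndarray, lo, hi) -> np.ndarray:
    """Half-open (lo, hi] selection."""
    return (times > lo) & (times <= hi)


def _first_time(times: np.ndarray, mask: np.ndarray):
    idx = np.flatnonzero(mask)
    return times[idx[0]] if idx.size else None


# ---------------------------------------------------------------------------
# SIRS
# ---------------------------------------------------------------------------


def _sirs_criteria(ev: EncounterEvents, cfg: CriteriaConfig) -> dict[str, np.ndarray]:
    """Firing times per SIRS criterion (distinct criteria, not events)."""
    out = {}
    t, v = ev.concept_series("temperature_c")
    out["sirs_temperature"] = t[(v > cfg.sirs_temp_high_c) | (v < cfg.sirs_temp_low_c)]
    t, v = ev.concept_series("heart_rate")
    out["sirs_heart_rate"] = t[v > cfg.sirs_hr]
    t, v = ev.concept_series("resp_rate")
    out["sirs_resp_rate"] = t[v > cfg.sirs_rr]
    tw, vw = ev.concept_series("wbc_k_per_uL")
    tb, vb = ev.concept_series("band_pct")
    out["sirs_wbc"] = np.sort(
        np.concatenate(
            [tw[(vw > cfg.sirs_wbc_high) | (vw < cfg.sirs_wbc_low)], tb[vb > cfg.sirs_band_pct]]
        )
    )
    return out


def sirs_count(events, at_time, window_hours: float | None = None, config: CriteriaConfig | None = None) -> int:
    """Number of distinct SIRS criteria (0–4) satisfied by at least one
    measurement in ``(at_time − window, at_time]``."""
    cfg = config or CriteriaConfig()
    w = np.timedelta64(int((window_hours or cfg.sirs_window_hours) * 60), "m")
    ev = _as_view(events)
    at = np.datetime64(pd.Timestamp(at_time))
    return sum(
        1 for times in _sirs_criteria(ev, cfg).values() if _in_window(times, at - w, at).any()
    )


# ---------------------------------------------------------------------------
# SOFA
# ---------------------------------------------------------------------------

_SOFA_BANDS = {
    # concept -> (direction, [(threshold, points), ...] evaluated in order)
    "platelets_k_per_uL": ("low", [(20, 4), (50, 3), (100, 2), (150, 1)]),
    "bilirubin_mg_dL": ("high", [(12.0, 4), (6.0, 3), (2.0, 2), (1.2, 1)]),
    "creatinine_mg_dL": ("high", [(5.0, 4), (3.5, 3), (2.0, 2), (1.2, 1)]),
    "gcs": ("low", [(6, 4), (10, 3), (13, 2), (15, 1)]),
}


def sofa_score(events, at_time, lookback_hours: float | None = None, config: CriteriaConfig | None = None):
    """Total SOFA (0–24) and the six organ subscores at ``at_time``.

    Each subscore is derived from the worst qualifying value in
    ``(at_time − lookback, at_time]``; missing components score 0 (the
    standard convention for sparse ward data).  Vasopressor administration
    scores the cardiovascular component at 3; mechanical ventilation enables
    the severe respiratory bands.
    """
    cfg = config or CriteriaConfig()
    lb = np.timedelta64(int((lookback_hours or cfg.sofa_component_lookback_hours) * 60), "m")
    ev = _as_view(events)
    at = np.datetime64(pd.Timestamp(at_time))
    lo = at - lb

    sub = {}
    for concept, (direction, bands) in _SOFA_BANDS.items():
        t, v = ev.concept_series(concept)
        vals = v[_in_window(t, lo, at)]
        score = 0
        if vals.size:
            worst = vals.min() if direction == "low" else vals.max()
            for thr, pts in bands:
                hit = worst < thr if direction == "low" else worst >= thr
                if hit:
                    score = pts
                    break
        key = {
            "platelets_k_per_uL": "coagulation",
            "bilirubin_mg_dL": "liver",
            "creatinine_mg_dL": "renal",
            "gcs": "cns",
        }[concept]
        sub[key] = score

    # respiration: PaO2/FiO2, severe bands require ventilatory support
    t, v = ev.concept_series("pao2_fio2")
    vals = v[_in_window(t, lo, at)]
    resp = 0
    if vals.size:
        worst = vals.min()
        vented = _in_window(ev.times_of("mech_vent_start"), lo, at).any()
        if worst < 100 and vented:
            resp = 4
        elif worst < 200 and vented:
            resp = 3
        elif worst < 300:
            resp = 2
        elif worst < 400:
            resp = 1
    sub["respiration"] = resp

    # cardiovascular: MAP < 70 → 1; any vasopressor → 3
    cardio = 0
    t, v = ev.concept_series("map_mmHg")
    vals = v[_in_window(t, lo, at)]
    if vals.size and vals.min() < 70:
        cardio = 1
    if _in_window(ev.times_of("vasopressor_admin"), lo, at).any():
        cardio = 3
    sub["cardiovascular"] = cardio

    return sum(sub.values()), sub


# ---------------------------------------------------------------------------
# Suspected infection and Sepsis-3
# ---------------------------------------------------------------------------


def detect_suspected_infection(events, config: CriteriaConfig | None = None):
    """Culture–antibiotic pairs establishing suspected infection.

    A pair qualifies when the antibiotic starts no more than 72 h after the
    culture, or the culture is drawn no more than 24 h after the antibiotic;
    the suspicion time is the earlier member.  Returned sorted by suspicion
    time.
    """
    cfg = config or CriteriaConfig()
    ev = _as_view(events)
    cultures = ev.times_of("blood_culture_order")
    abx = ev.times_of("iv_antibiotic_admin")
    pairs = []
    w_abx = np.timedelta64(int(cfg.abx_after_culture_hours * 60), "m")
    w_cult = np.timedelta64(int(cfg.culture_after_abx_hours * 60), "m")
    for c in cultures:
        m = (abx >= c) & (abx <= c + w_abx)
        if m.any():
            pairs.append((c, c, abx[m][0]))
    for b in abx:
        m = (cultures >= b) & (cultures <= b + w_cult)
        if m.any():
            pairs.append((b, cultures[m][0], b))
    pairs.sort(key=lambda p: (p[0], p[1]))
    # deduplicate by suspicion time, earliest first
    seen, out = set(), []
    for s, c, b in pairs:
        if s not in seen:
            seen.add(s)
            out.append((pd.Timestamp(s), pd.Timestamp(c), pd.Timestamp(b)))
    return out


def sepsis3_label(events, encounter, config: CriteriaConfig | None = None) -> SepsisLabel:
    """Sepsis-3: suspected infection with an acute SOFA rise ≥ 2.

    The SOFA rise is the maximum score at event times inside
    (suspicion − 48 h, suspicion + 24 h] minus the baseline (minimum score at
    event times in the 48 h before suspicion; 0 if unmeasured).
    """
    cfg = config or CriteriaConfig()
    ev = _as_view(events)
    enc_id = encounter["encounter_id"]
    before = np.timedelta64(int(cfg.sofa_window_before_hours * 60), "m")
    after = np.timedelta64(int(cfg.sofa_window_after_hours * 60), "m")

    for susp, culture, abx in detect_suspected_infection(ev, cfg):
        s = np.datetime64(susp)
        in_win = ev.times[(ev.times > s - before) & (ev.times <= s + after)]
        eval_times = np.unique(np.concatenate([in_win, [s]]))
        scores = np.array([sofa_score(ev, t, config=cfg)[0] for t in eval_times])
        max_sofa = int(scores.max()) if scores.size else 0
        pre = scores[eval_times <= s]
        baseline = int(pre.min()) if pre.size else 0
        if max_sofa - baseline >= cfg.sofa_delta:
            return SepsisLabel(
                enc_id,
                "sepsis3",
                True,
                susp,
                {
                    "culture": str(culture),
                    "antibiotic": str(abx),
                    "suspicion": str(susp),
                    "sofa_baseline": baseline,
                    "sofa_max": max_sofa,
                },
            )
    return SepsisLabel(enc_id, "sepsis3", False, None)


# ---------------------------------------------------------------------------
# SEP-1
# ---------------------------------------------------------------------------


def _sep1_od_criteria(ev: EncounterEvents, cfg: CriteriaConfig) -> dict[str, np.ndarray]:
    """Firing times per SEP-1 organ-dysfunction criterion (strict thresholds)."""
    out = {}
    t, v = ev.concept_series("sbp_mmHg")
    out["sbp_low"] = t[v < cfg.sep1_sbp]
    # drop > 40 mmHg from the running pre-measurement maximum
    if t.size:
        run_max = np.maximum.accumulate(v)
        prior_max = np.concatenate([[-np.inf], run_max[:-1]])
        out["sbp_drop"] = t[prior_max - v > cfg.sep1_sbp_drop]
    else:
        out["sbp_drop"] = t
    t, v = ev.concept_series("map_mmHg")
    out["map_low"] = t[v < cfg.sep1_map]
    t, v = ev.concept_series("lactate_mmol_L")
    out["lactate_high"] = t[v > cfg.sep1_lactate]
    t, v = ev.concept_series("creatinine_mg_dL")
    out["creatinine_high"] = t[v > cfg.sep1_creatinine]
    t, v = ev.concept_series("bilirubin_mg_dL")
    out["bilirubin_high"] = t[v > cfg.sep1_bilirubin]
    t, v = ev.concept_series("platelets_k_per_uL")
    out["platelets_low"] = t[v < cfg.sep1_platelets]
    t, v = ev.concept_series("inr")
    out["inr_high"] = t[v > cfg.sep1_inr]
    return out


def sep1_organ_dysfunction(events, at_time, window_hours: float | None = None, config: CriteriaConfig | None = None) -> set[str]:
    """SEP-1 organ-dysfunction criteria fired in ``(at_time − window, at_time]``."""
    cfg = config or CriteriaConfig()
    w = np.timedelta64(int((window_hours or cfg.sep1_window_hours) * 60), "m")
    ev = _as_view(events)
    at = np.datetime64(pd.Timestamp(at_time))
    return {
        name
        for name, times in _sep1_od_criteria(ev, cfg).items()
        if _in_window(times, at - w, at).any()
    }


def sep1_label(events, encounter, config: CriteriaConfig | None = None) -> SepsisLabel:
    """SEP-1 severe sepsis: ≥ 2 SIRS criteria concurrent with ≥ 1
    organ-dysfunction criterion inside the rolling window; time zero is the
    earliest event time completing the conjunction."""
    cfg = config or CriteriaConfig()
    ev = _as_view(events)
    enc_id = encounter["encounter_id"]
    w = np.timedelta64(int(cfg.sep1_window_hours * 60), "m")

    sirs = _sirs_criteria(ev, cfg)
    od = _sep1_od_criteria(ev, cfg)
    candidates = np.unique(np.concatenate(list(sirs.values()) + list(od.values())))
    for t in candidates:
        fired_sirs = [n for n, times in sirs.items() if _in_window(times, t - w, t).any()]
        if len(fired_sirs) < 2:
            continue
        fired_od = [n for n, times in od.items() if _in_window(times, t - w, t).any()]
        if fired_od:
            comp = {"sirs": fired_sirs, "organ_dysfunction": fired_od, "window_end": str(pd.Timestamp(t))}
            return SepsisLabel(enc_id, "sep1", True, pd.Timestamp(t), comp)
    return SepsisLabel(enc_id, "sep1", False, None)


# ---------------------------------------------------------------------------
# ASE
# ---------------------------------------------------------------------------


def qualifying_antibiotic_days(events, culture_time, encounter, config: CriteriaConfig | None = None):
    """CDC ASE qualifying-antibiotic-day rule.

    A run qualifies when a *new* IV antibiotic (no administration in the
    prior 2 calendar days) starts within ± 2 calendar days of the culture and
    continues ≥ 4 consecutive calendar days (single-day gaps bridged), or
    until in-hospital death if that comes first.  Returns
    ``(qualifies, qad_start_timestamp_or_None)``.
    """
    cfg = config or CriteriaConfig()
    ev = _as_view(events)
    abx_t = ev.times_of("iv_antibiotic_admin")
    if abx_t.size == 0:
        return False, None
    days = abx_t.astype("datetime64[D]")
    uniq_days = np.unique(days)
    day_set = set(uniq_days.astype("int64").tolist())
    culture_day = np.datetime64(pd.Timestamp(culture_time), "D").astype("int64")

    died = bool(encounter.get("died_in_hospital", False))
    death_day = (
        np.datetime64(pd.Timestamp(encounter["discharge_time"]), "D").astype("int64")
        if died
        else None
    )

    for d in uniq_days.astype("int64"):
        if abs(d - culture_day) > cfg.ase_culture_window_days:
            continue
        if (d - 1) in day_set or (d - 2) in day_set:
            continue  # not a new start
        # extend the run, bridging gaps of <= qad_gap_days
        last = d
        for nxt in sorted(x for x in day_set if x > d):
            if nxt - last <= cfg.qad_gap_days + 1:
                last = nxt
            else:
                break
        span = last - d + 1
        qualifies = span >= cfg.qad_min_days or (died and last >= death_day - 1)
        if qualifies:
            start_mask = days.astype("int64") == d
            return True, pd.Timestamp(abx_t[start_mask][0])
    return False, None


def ase_organ_dysfunction(events, culture_time, window_days: int | None = None, config: CriteriaConfig | None = None):
    """ASE organ-dysfunction criteria within ± window calendar days of the
    culture; baselines are the best values before the window (lowest
    creatinine/bilirubin, highest platelets).  Returns criterion → earliest
    firing time."""
    cfg = config or CriteriaConfig()
    wd = cfg.ase_culture_window_days if window_days is None else window_days
    ev = _as_view(events)
    cday = np.datetime64(pd.Timestamp(culture_time), "D")
    lo = (cday - np.timedelta64(wd, "D")).astype("datetime64[m]")
    hi = (cday + np.timedelta64(wd + 1, "D")).astype("datetime64[m]")

    def win(times):
        return (times >= lo) & (times < hi)

    fired: dict[str, pd.Timestamp] = {}
    for concept, name in (("vasopressor_admin", "vasopressor"), ("mech_vent_start", "mechanical_ventilation")):
        t = ev.times_of(concept)
        ft = _first_time(t, win(t))
        if ft is not None:
            fired[name] = pd.Timestamp(ft)

    t, v = ev.concept_series("lactate_mmol_L")
    ft = _first_time(t, win(t) & (v >= cfg.ase_lactate))
    if ft is not None:
        fired["lactate"] = pd.Timestamp(ft)

    t, v = ev.concept_series("creatinine_mg_dL")
    base = v[t < lo]
    if base.size:
        ft = _first_time(t, win(t) & (v >= cfg.ase_creatinine_ratio * base.min()))
        if ft is not None:
            fired["creatinine_doubling"] = pd.Timestamp(ft)

    t, v = ev.concept_series("bilirubin_mg_dL")
    base = v[t < lo]
    if base.size:
        ft = _first_time(
            t, win(t) & (v >= cfg.ase_bilirubin_abs) & (v >= cfg.ase_bilirubin_ratio * base.min())
        )
        if ft is not None:
            fired["bilirubin_rise"] = pd.Timestamp(ft)

    t, v = ev.concept_series("platelets_k_per_uL")
    base = v[t < lo]
    if base.size and base.max() >= cfg.ase_platelets_abs:
        ft = _first_time(
            t,
            win(t)
            & (v < cfg.ase_platelets_abs)
            & (v <= (1 - cfg.ase_platelet_decline) * base.max()),
        )
        if ft is not None:
            fired["platelet_decline"] = pd.Timestamp(ft)
    return fired


def ase_label(events, encounter, config: CriteriaConfig | None = None) -> SepsisLabel:
    """ASE: blood culture + qualifying antibiotic days + concurrent organ
    dysfunction; time zero is the minimum over component times of the
    earliest qualifying episode (or the culture time, per config)."""
    cfg = config or CriteriaConfig()
    ev = _as_view(events)
    enc_id = encounter["encounter_id"]
    for c in ev.times_of("blood_culture_order"):
        culture = pd.Timestamp(c)
        qualifies, qad_start = qualifying_antibiotic_days(ev, culture, encounter, cfg)
        if not qualifies:
            continue
        od = ase_organ_dysfunction(ev, culture, config=cfg)
        if not od:
            continue
        first_od = min(od.values())
        if cfg.ase_time_zero_mode == "culture":
            t0 = culture
        else:
            t0 = min(culture, qad_start, first_od)
        return SepsisLabel(
            enc_id,
            "ase",
            True,
            t0,
            {
                "culture": str(culture),
                "qad_start": str(qad_start),
                "organ_dysfunction": {k: str(v) for k, v in od.items()},
            },
        )
    return SepsisLabel(enc_id, "ase", False, None)


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

_LABELLERS = {"sepsis3": sepsis3_label, "sep1": sep1_label, "ase": ase_label}


def label_cohort(
    events: pd.DataFrame,
    encounters: pd.DataFrame,
    definitions=("sepsis3", "sep1", "ase"),
    config: CriteriaConfig | None = None,
) -> pd.DataFrame:
    """Phenotype every encounter under the requested definitions.

    Events before ``arrival − pre_arrival_lookback_hours`` are ignored.
    Returns one row per encounter × definition:
    ``encounter_id, definition, is_case, time_zero, components_json``.
    """
    import json as _json

    cfg = config or CriteriaConfig()
    lookback = pd.Timedelta(hours=cfg.pre_arrival_lookback_hours)
    groups = dict(tuple(events.groupby("encounter_id", sort=False)))
    rows = []
    for enc in encounters.itertuples(index=False):
        enc_d = enc._asdict()
        g = groups.get(enc_d["encounter_id"])
        if g is not None:
            g = g[g["time"] >= pd.Timestamp(enc_d["arrival_time"]) - lookback]
            view = EncounterEvents(g)
        else:
            view = EncounterEvents(events.iloc[0:0])
        for d in definitions:
            lab = _LABELLERS[d](view, enc_d, cfg)
            rows.append(
                (
                    lab.encounter_id,
                    d,
                    lab.is_case,
                    lab.time_zero,
                    _json.dumps(lab.components) if lab.components else "{}",
                )
            )
    out = pd.DataFrame(
        rows, columns=["encounter_id", "definition", "is_case", "time_zero", "components_json"]
    )
    for d in definitions:
        sub = out[out["definition"] == d]
        logger.info("phenotype %s: %d/%d cases", d, int(sub["is_case"].sum()), len(sub))
    return out
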