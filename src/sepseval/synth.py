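"""Synthetic EHR event-stream generator with planted sepsis cases.

The generator emulates a silent-deployment evaluation cohort: a mix of
ED-only and admitted adult encounters, a 15-minute score stream per
encounter, and sepsis cases planted under three computable definitions
(Sepsis-3, SEP-1, CDC Adult Sepsis Event).  Planting is *constructive*:
case encounters receive event sequences that satisfy exactly the intended
definitions at known times, and non-case encounters are built so that no
event combination can satisfy any definition (background vitals stay below
every SIRS threshold, labs within normal ranges, no culture–antibiotic
pairing).  The planted truth table is therefore an exact oracle for the
phenotyping modules.

Score law
---------
A latent discrimination variable ``z`` follows the equal-variance binormal
model: ``z ~ N(δ, 1)`` for cases of the primary definition and ``N(0, 1)``
otherwise, with ``δ = √2·Φ⁻¹(AUROC*)`` so the implied AUROC has the closed
form ``Φ(δ/√2) = AUROC*``.  The emitted peak score is 100 times the exact
posterior risk ``P(case | z)`` passed through a configurable logit-scale
calibration map (identity ⇒ perfectly calibrated, so the expected
calibration error of the encounter-level evaluation converges to zero).
Because the posterior is a strictly monotone function of ``z``, the AUROC
of the emitted scores is unchanged.

Each case encounter's stream ramps from a low baseline up to its peak,
reaching the peak exactly at the last cadence tick strictly before the
earliest planted time zero; the maximum pre-time-zero score therefore
equals the latent peak exactly.  The ramp onset (a configurable mean lead
ahead of time zero) is recorded in the truth table for lead-time recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit, ndtri

from .model import ConfigError

MIN = "datetime64[m]"

_ABX_NAMES = ("cefepime", "vancomycin", "ceftriaxone", "piperacillin_tazobactam")

# Per-definition arrival-to-time-zero lognormals, parameterized so that the
# median and IQR ratio match the reported distributions (median m ⇒ μ = ln m;
# σ = ln(q3/q1) / (2·0.6745)).
_DEFAULT_T0_LOGNORMAL = {
    "sepsis3": (4.1, 2.257),  # median 4.1 h, IQR 1.2–25.2 h
    "sep1": (5.8, 2.117),  # median 5.8 h, IQR 1.8–31.3 h
    "ase": (1.7, 2.081),  # median 1.7 h, IQR 0.7–11.6 h
}

_DEFAULT_TYPE_MIX = {
    "ed_only": 0.681,
    "ed_to_hosp": 0.218,
    "direct_admission": 0.045,
    "or_to_hosp": 0.049,
    "ob_to_hosp": 0.007,
}

#: Median stay (hours) and lognormal sigma by encounter type.
_STAY_LAW = {
    "ed_only": (5.0, 0.45),
    "ed_to_hosp": (72.0, 0.55),
    "direct_admission": (84.0, 0.55),
    "or_to_hosp": (72.0, 0.45),
    "ob_to_hosp": (48.0, 0.35),
}


class SimConfig(BaseModel):
    """Study-condition parameters for the synthetic cohort."""

    n_encounters: int = 20_000
    seed: int = 0
    encounter_type_mix: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_TYPE_MIX))
    sepsis_incidence_by_definition: dict[str, float] = Field(
        default_factory=lambda: {"sepsis3": 0.029, "sep1": 0.012, "ase": 0.020}
    )
    #: Gaussian-copula correlation between the three case indicators.
    definition_correlation: float = 0.6
    #: Definition whose labels drive the score law.
    primary_definition: str = "sepsis3"
    arrival_to_t0_lognormal: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(_DEFAULT_T0_LOGNORMAL)
    )
    target_auroc: float = 0.89
    #: Logit-scale calibration map applied to the posterior risk;
    #: slope 1 / intercept 0 is the identity (perfect calibration).
    calibration_slope: float = 1.0
    calibration_intercept: float = 0.0
    score_cadence_minutes: int = 15
    mortality_given_sepsis: float = 0.15
    baseline_mortality: float = 0.005
    #: Fraction of encounters planted with a sub-1-hour stay (excluded by the
    #: cohort filter); ``short_stay_count`` overrides with an exact count.
    short_stay_fraction: float = 8995 / 207489
    short_stay_count: int | None = None
    #: Fraction of patients contributing 2–3 encounters.
    repeat_patient_fraction: float = 0.10
    #: Mean warning (hours) between score-ramp onset and time zero.
    mean_lead_hours: float = 4.0
    lead_sigma: float = 0.4
    #: Ramp shape: pre-onset scores stay below ``baseline_frac``·peak; the
    #: ramp starts at ``ramp_floor``·peak and ends exactly at the peak.
    baseline_frac: float = 0.2
    ramp_floor: float = 0.5
    study_start: str = "2024-03-17"
    study_weeks: int = 24

    @model_validator(mode="after")
    def _validate(self) -> "SimConfig":
        if abs(sum(self.encounter_type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("encounter_type_mix must sum to 1")
        for d, p in self.sepsis_incidence_by_definition.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"incidence for {d} outside [0, 1]")
        if not 0.5 < self.target_auroc < 1.0:
            raise ConfigError("target_auroc must be in (0.5, 1)")
        if self.primary_definition not in self.sepsis_incidence_by_definition:
            raise ConfigError("primary_definition must have an incidence entry")
        if not 0.0 <= self.definition_correlation < 1.0:
            raise ConfigError("definition_correlation must be in [0, 1)")
        if not 0.0 < self.ramp_floor <= 1.0 or not 0.0 <= self.baseline_frac < self.ramp_floor:
            raise ConfigError("require 0 <= baseline_frac < ramp_floor <= 1")
        return self


@dataclass
class SimResult:
    """Generated cohort: the three study tables plus the planted truth."""

    encounters: pd.DataFrame
    events: pd.DataFrame
    predictions: pd.DataFrame
    truth: pd.DataFrame


def binormal_delta(auroc: float) -> float:
    """Separation δ of the equal-variance binormal model with the given AUROC."""
    return float(np.sqrt(2.0) * ndtri(auroc))


# ---------------------------------------------------------------------------
# Encounter metadata
# ---------------------------------------------------------------------------


def _sample_patients(n: int, frac_repeat: float, rng: np.random.Generator) -> np.ndarray:
    """Patient index per encounter; ~``frac_repeat`` of patients get 2–3 visits."""
    sizes = rng.choice([1, 2, 3], size=n, p=[1 - frac_repeat, frac_repeat / 2, frac_repeat / 2])
    cum = np.cumsum(sizes)
    n_pat = int(np.searchsorted(cum, n)) + 1
    pid = np.repeat(np.arange(n_pat), sizes[:n_pat])[:n]
    return pid


def sample_encounter_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized draw of encounter metadata (no events or scores).

    Stays are preliminary: :func:`generate_cohort` extends case encounters so
    that planted criterion events fit inside the stay.
    """
    n = config.n_encounters
    types = list(config.encounter_type_mix)
    etype = rng.choice(types, size=n, p=[config.encounter_type_mix[t] for t in types])

    start = pd.Timestamp(config.study_start)
    arrival_min = rng.integers(0, config.study_weeks * 7 * 24 * 60, size=n)
    arrival = start.to_datetime64().astype(MIN) + arrival_min.astype("timedelta64[m]")

    med = np.array([_STAY_LAW[t][0] for t in etype])
    sig = np.array([_STAY_LAW[t][1] for t in etype])
    stay_h = np.maximum(np.exp(np.log(med) + sig * rng.standard_normal(n)), 1.25)

    if config.short_stay_count is not None:
        n_short = min(config.short_stay_count, n)
        short = np.zeros(n, dtype=bool)
        short[rng.choice(n, size=n_short, replace=False)] = True
    else:
        short = rng.random(n) < config.short_stay_fraction
    stay_h = np.where(short, rng.uniform(8, 55, size=n) / 60.0, stay_h)

    pid = _sample_patients(n, config.repeat_patient_fraction, rng)

    sex = rng.choice(["female", "male"], size=n, p=[0.548, 0.452])
    race = rng.choice(
        ["asian", "black", "white", "other", "unknown"],
        size=n,
        p=[0.035, 0.119, 0.696, 0.011, 0.139],
    )
    ethnicity = rng.choice(["hispanic", "non_hispanic", "unknown"], size=n, p=[0.160, 0.805, 0.035])
    hospital = rng.choice(["academic", "community", "critical_access"], size=n, p=[0.431, 0.513, 0.056])
    age = np.clip(rng.normal(52.0, 20.0, size=n), 18.0, 102.0)

    ed_based = np.isin(etype, ["ed_only", "ed_to_hosp"])
    esi = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.007, 0.304, 0.545, 0.124, 0.020])
    esi = pd.array(np.where(ed_based, esi, -1), dtype="Int64")
    esi[esi == -1] = pd.NA

    return pd.DataFrame(
        {
            "encounter_id": np.char.add("E", np.char.zfill(np.arange(n).astype(str), 7)),
            "patient_id": np.char.add("P", np.char.zfill(pid.astype(str), 7)),
            "arrival_time": arrival.astype("datetime64[ns]"),
            "stay_hours": stay_h,
            "encounter_type": etype,
            "hospital_type": hospital,
            "age_years": np.round(age, 1),
            "sex": sex,
            "race": race,
            "ethnicity": ethnicity,
            "esi": esi,
            "short_stay": short,
        }
    )


# ---------------------------------------------------------------------------
# Case profiles and the score law
# ---------------------------------------------------------------------------


def _sample_case_profile(config: SimConfig, eligible: np.ndarray, rng: np.random.Generator):
    """Correlated per-definition case indicators via a Gaussian copula."""
    n = eligible.size
    defs = list(config.sepsis_incidence_by_definition)
    rho = config.definition_correlation
    k = len(defs)
    cov = np.full((k, k), rho) + np.eye(k) * (1 - rho)
    L = np.linalg.cholesky(cov)
    Z = rng.standard_normal((n, k)) @ L.T
    cases = {}
    for j, d in enumerate(defs):
        p = config.sepsis_incidence_by_definition[d]
        cases[d] = eligible & (Z[:, j] < (ndtri(p) if p > 0 else -np.inf))
    return cases


def _sample_peak_scores(config: SimConfig, primary_case: np.ndarray, rng: np.random.Generator):
    """Latent peak score per encounter under the binormal posterior-risk law."""
    n = primary_case.size
    delta = binormal_delta(config.target_auroc)
    pi = config.sepsis_incidence_by_definition[config.primary_definition]
    z = rng.standard_normal(n) + delta * primary_case
    risk = expit(logit(pi) + delta * z - delta**2 / 2.0) if pi > 0 else np.zeros(n)
    cal = expit(config.calibration_intercept + config.calibration_slope * logit(np.clip(risk, 1e-12, 1 - 1e-12)))
    return 100.0 * cal, risk


def sample_scores(n: int, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lightweight draw of encounter-level instances (label + peak score).

    Shares the score law with :func:`generate_cohort` but skips event and
    stream construction; used for statistical recovery and bootstrap-coverage
    experiments at scale.
    """
    pid = _sample_patients(n, config.repeat_patient_fraction, rng)
    pi = config.sepsis_incidence_by_definition[config.primary_definition]
    label = rng.random(n) < pi
    peak, risk = _sample_peak_scores(config, label, rng)
    return pd.DataFrame(
        {
            "encounter_id": np.char.add("E", np.char.zfill(np.arange(n).astype(str), 7)),
            "patient_id": np.char.add("P", np.char.zfill(pid.astype(str), 7)),
            "label": label,
            "max_score_pre_t0": peak,
            "risk": risk,
        }
    )


# ---------------------------------------------------------------------------
# Event planting
# ---------------------------------------------------------------------------


class _EventSink:
    """Column-wise event accumulator."""

    def __init__(self):
        self.enc, self.pat, self.time, self.kind, self.concept, self.value, self.abx = (
            [],
            [],
            [],
            [],
            [],
            [],
            [],
        )

    def add(self, enc, pat, time, kind, concept, value=np.nan, abx=None):
        self.enc.append(enc)
        self.pat.append(pat)
        self.time.append(time)
        self.kind.append(kind)
        self.concept.append(concept)
        self.value.append(value)
        self.abx.append(abx)

    def extend_arrays(self, enc, pat, time, kind, concept, value, abx):
        self.enc.extend(enc)
        self.pat.extend(pat)
        self.time.extend(time)
        self.kind.extend(kind)
        self.concept.extend(concept)
        self.value.extend(value)
        self.abx.extend(abx)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "encounter_id": self.enc,
                "patient_id": self.pat,
                "time": np.array(self.time, dtype=MIN).astype("datetime64[ns]"),
                "kind": self.kind,
                "concept": self.concept,
                "value": self.value,
                "antibiotic_name": self.abx,
            }
        )


def _m(ts, minutes: float):
    """Shift a datetime64[m] by whole minutes."""
    return ts + np.timedelta64(int(round(minutes)), "m")


def _plant_case_events(
    sink: _EventSink,
    enc_id: str,
    pat_id: str,
    arrival,
    is_s3: bool,
    is_sep1: bool,
    is_ase: bool,
    t0_draws: dict[str, float],
    died: bool,
    rng: np.random.Generator,
):
    """Insert criterion events for one case encounter.

    Returns (per-definition planted time zeros, minimum required discharge).
    The construction keeps definitions orthogonal:

    * infection episode (culture + IV antibiotics) is shared by Sepsis-3 and
      ASE, so overlapping cases have coinciding time zeros at the culture;
    * the Sepsis-3 SOFA rise uses creatinine 1.5 + platelets 118 — two
      1-point subscores that stay below every SEP-1 and ASE organ-dysfunction
      threshold (< 2× baseline creatinine, platelets not < 100);
    * ASE organ dysfunction uses lactate 2.4, which is outside SOFA; when it
      could complete an earlier SEP-1 conjunction the SEP-1 block is shifted
      7 h later;
    * antibiotics run 5 calendar days for ASE cases but only 2 otherwise, and
      non-ASE deaths are pushed ≥ 2 days past the last antibiotic so the ASE
      death exception cannot fire.
    """
    t0 = {}
    times = []
    t_lactate = None
    last_abx = None

    if is_s3 or is_ase:
        offs = [t0_draws[d] for d, f in (("sepsis3", is_s3), ("ase", is_ase)) if f]
        t_inf = _m(arrival, max(30.0, min(offs) * 60.0))
        sink.add(enc_id, pat_id, t_inf, "order", "blood_culture_order")
        name = _ABX_NAMES[int(rng.integers(len(_ABX_NAMES)))]
        first_abx = _m(t_inf, 60)
        sink.add(enc_id, pat_id, first_abx, "med_admin", "iv_antibiotic_admin", abx=name)
        times += [t_inf, first_abx]
        last_abx = first_abx
        if is_ase:
            sink.add(enc_id, pat_id, _m(t_inf, 75), "order", "lactate_order")
            t_lactate = _m(t_inf, 90)
            sink.add(enc_id, pat_id, t_lactate, "lab", "lactate_mmol_L", 2.4)
            times.append(t_lactate)
            for day in range(1, 5):
                last_abx = _m(first_abx, day * 24 * 60)
                sink.add(enc_id, pat_id, last_abx, "med_admin", "iv_antibiotic_admin", abx=name)
        else:
            last_abx = _m(first_abx, 24 * 60)
            sink.add(enc_id, pat_id, last_abx, "med_admin", "iv_antibiotic_admin", abx=name)
        times.append(last_abx)
        if is_s3:
            sink.add(enc_id, pat_id, _m(t_inf, 120), "lab", "creatinine_mg_dL", 1.5)
            sink.add(enc_id, pat_id, _m(t_inf, 121), "lab", "platelets_k_per_uL", 118.0)
            times.append(_m(t_inf, 121))
            t0["sepsis3"] = t_inf
        if is_ase:
            t0["ase"] = t_inf

    if is_sep1:
        t_s = _m(arrival, max(45.0, t0_draws["sep1"] * 60.0))
        if t_lactate is not None and (t_s - np.timedelta64(390, "m")) < t_lactate <= t_s:
            # lactate would complete the SIRS conjunction before the planted
            # organ-dysfunction event; move the SEP-1 block out of the window
            t_s = _m(t_lactate, 7 * 60)
        sink.add(enc_id, pat_id, _m(t_s, -30), "vital", "temperature_c", 39.1)
        sink.add(enc_id, pat_id, _m(t_s, -15), "vital", "heart_rate", 112.0)
        sink.add(enc_id, pat_id, t_s, "vital", "sbp_mmHg", 82.0)
        times.append(t_s)
        t0["sep1"] = t_s

    end_needed = max(times) + np.timedelta64(120, "m")
    if died and last_abx is not None and not is_ase:
        # death must not rescue a 2-day antibiotic run under the ASE rule
        day = last_abx.astype("datetime64[D]")
        end_needed = max(end_needed, (day + np.timedelta64(2, "D")).astype(MIN) + np.timedelta64(120, "m"))
    return t0, end_needed


def _background_events(
    sink: _EventSink,
    enc_ids: np.ndarray,
    pat_ids: np.ndarray,
    arrival: np.ndarray,
    discharge: np.ndarray,
    rng: np.random.Generator,
):
    """Sub-threshold background vitals and labs for every encounter.

    Values are clipped inside all criterion thresholds (e.g. heart rate
    < 90, SBP within 100–140 so no drop can exceed 40 mmHg), so background
    alone can never fire any definition.
    """
    stay_min = (discharge - arrival).astype("timedelta64[m]").astype(np.int64)
    n_sets = stay_min // 240 + 1  # vitals every 4 h
    total = int(n_sets.sum())
    idx = np.repeat(np.arange(len(enc_ids)), n_sets)
    offsets = np.concatenate([np.arange(k) for k in n_sets]) * 240 + 15
    offsets = offsets + rng.integers(0, 10, size=total)
    t = arrival[idx] + offsets.astype("timedelta64[m]")

    vit = {
        "temperature_c": np.clip(rng.normal(36.9, 0.30, total), 36.1, 38.2),
        "heart_rate": np.clip(rng.normal(78, 7, total), 55, 89),
        "resp_rate": np.clip(rng.normal(15, 2, total), 10, 19.5),
        "sbp_mmHg": np.clip(rng.normal(122, 9, total), 100, 140),
    }
    for concept, vals in vit.items():
        sink.extend_arrays(
            enc_ids[idx],
            pat_ids[idx],
            t,
            ["vital"] * total,
            [concept] * total,
            np.round(vals, 1),
            [None] * total,
        )

    n = len(enc_ids)
    t_lab = arrival + np.timedelta64(45, "m")
    labs = {
        "wbc_k_per_uL": np.clip(rng.normal(7.5, 1.5, n), 4.5, 11.5),
        "creatinine_mg_dL": np.clip(rng.normal(0.85, 0.05, n), 0.7, 1.0),
        "platelets_k_per_uL": np.clip(rng.normal(240, 30, n), 160, 320),
    }
    for concept, vals in labs.items():
        sink.extend_arrays(
            enc_ids, pat_ids, t_lab, ["lab"] * n, [concept] * n, np.round(vals, 2), [None] * n
        )


# ---------------------------------------------------------------------------
# Score streams
# ---------------------------------------------------------------------------


def _build_streams(
    enc_ids: np.ndarray,
    arrival: np.ndarray,
    discharge: np.ndarray,
    peak: np.ndarray,
    any_case: np.ndarray,
    t0_min: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
):
    """Vectorized 15-minute score streams.

    Non-case streams are noise strictly below the peak, with the peak placed
    at a random tick strictly before discharge.  Case streams ramp linearly
    from ``ramp_floor``·peak at onset to exactly the peak at the last tick
    strictly before the earliest planted time zero; post-time-zero ticks
    stay high but strictly below the peak.
    """
    c = config.score_cadence_minutes
    A = arrival.astype(np.int64)
    D = discharge.astype(np.int64)
    K = (D - A) // c
    counts = K + 1
    total = int(counts.sum())
    idx = np.repeat(np.arange(len(A)), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    k = np.arange(total) - np.repeat(starts, counts)
    times = (A[idx] + k * c).astype(MIN)

    # per-encounter anchors (NaT for non-cases; replace before arithmetic)
    delta_t0 = np.where(any_case, t0_min.astype(np.int64), A + 1) - A
    J = np.maximum((delta_t0 - 1) // c, 0)
    lead_min = np.round(
        np.exp(np.log(config.mean_lead_hours) + config.lead_sigma * rng.standard_normal(len(A))) * 60
    ).astype(np.int64)
    onset = delta_t0 - lead_min
    j0 = np.clip(-(-onset // c), 0, J)
    peak_tick = rng.integers(0, np.maximum(K, 1))  # non-case peak position < discharge

    pk = peak[idx]
    u = rng.uniform(0.0, 0.9, total) * pk
    case_row = any_case[idx]
    j0r, Jr = j0[idx], J[idx]

    pre = case_row & (k < j0r)
    ramp = case_row & (k >= j0r) & (k <= Jr)
    post = case_row & (k > Jr)

    scores = u
    scores = np.where(pre, rng.uniform(0.0, config.baseline_frac, total) * pk, scores)
    span = np.maximum(Jr - j0r, 1)
    frac = config.ramp_floor + (1.0 - config.ramp_floor) * (k - j0r) / span
    frac = np.where(Jr == j0r, 1.0, frac)
    scores = np.where(ramp & (k == Jr), pk, np.where(ramp, frac * pk, scores))
    scores = np.where(post, rng.uniform(0.80, 0.999, total) * pk, scores)
    scores = np.where(~case_row & (k == peak_tick[idx]), pk, scores)

    preds = pd.DataFrame(
        {
            "encounter_id": enc_ids[idx],
            "time": times.astype("datetime64[ns]"),
            "score": np.clip(scores, 0.0, 100.0),
        }
    )
    onset_tick_time = (A + j0 * c).astype(MIN)
    return preds, onset_tick_time


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SimConfig, seed: int | None = None) -> SimResult:
    """Generate encounters, events, predictions and planted truth.

    Deterministic given ``config`` (and ``seed``, which overrides
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    enc = sample_encounter_table(config, rng)
    n = len(enc)
    arrival = enc["arrival_time"].to_numpy().astype(MIN)

    eligible = ~enc["short_stay"].to_numpy()
    cases = _sample_case_profile(config, eligible, rng)
    for d in ("sepsis3", "sep1", "ase"):
        cases.setdefault(d, np.zeros(n, dtype=bool))
    any_case = cases["sepsis3"] | cases["sep1"] | cases["ase"]

    peak, risk = _sample_peak_scores(config, cases[config.primary_definition], rng)

    died = rng.random(n) < np.where(
        any_case, config.mortality_given_sepsis, config.baseline_mortality
    )

    # arrival-to-t0 offsets (hours), one draw per definition per encounter
    t0_draws = {}
    for d in ("sepsis3", "sep1", "ase"):
        med, sig = config.arrival_to_t0_lognormal.get(d, (4.0, 2.0))
        t0_draws[d] = np.maximum(np.exp(np.log(med) + sig * rng.standard_normal(n)), 0.6)

    discharge = (arrival.astype(np.int64) + np.round(enc["stay_hours"].to_numpy() * 60).astype(np.int64)).astype(MIN)

    sink = _EventSink()
    enc_ids = enc["encounter_id"].to_numpy()
    pat_ids = enc["patient_id"].to_numpy()
    t0_cols = {d: np.full(n, np.datetime64("NaT", "m")) for d in ("sepsis3", "sep1", "ase")}
    t0_min_dt = np.full(n, np.datetime64("NaT", "m"))

    for i in np.flatnonzero(any_case):
        t0, end_needed = _plant_case_events(
            sink,
            enc_ids[i],
            pat_ids[i],
            arrival[i],
            bool(cases["sepsis3"][i]),
            bool(cases["sep1"][i]),
            bool(cases["ase"][i]),
            {d: t0_draws[d][i] for d in ("sepsis3", "sep1", "ase")},
            bool(died[i]),
            rng,
        )
        for d, t in t0.items():
            t0_cols[d][i] = t
        t0_min_dt[i] = min(t0.values())
        if end_needed > discharge[i]:
            discharge[i] = end_needed

    _background_events(sink, enc_ids, pat_ids, arrival, discharge, rng)
    events = (
        sink.frame()
        .sort_values(["encounter_id", "time"], kind="stable")
        .reset_index(drop=True)
    )

    predictions, onset = _build_streams(
        enc_ids, arrival, discharge, peak, any_case, t0_min_dt, config, rng
    )

    encounters = enc.drop(columns=["stay_hours", "short_stay"]).copy()
    encounters["arrival_time"] = arrival.astype("datetime64[ns]")
    encounters["discharge_time"] = discharge.astype("datetime64[ns]")
    encounters["died_in_hospital"] = died
    encounters["context"] = pd.NA
    encounters["unit_intervals"] = _unit_intervals(
        enc["encounter_type"].to_numpy(), arrival, discharge, died
    )
    encounters = encounters[
        [
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
    ]

    onset = np.where(any_case, onset, np.datetime64("NaT", "m")).astype(MIN)
    lead_h = np.full(n, np.nan)
    lead_h[any_case] = (
        t0_min_dt[any_case].astype(np.int64) - onset[any_case].astype(np.int64)
    ) / 60.0
    truth = pd.DataFrame(
        {
            "encounter_id": enc_ids,
            "patient_id": pat_ids,
            "sepsis3_case": cases["sepsis3"],
            "sepsis3_t0": t0_cols["sepsis3"].astype("datetime64[ns]"),
            "sep1_case": cases["sep1"],
            "sep1_t0": t0_cols["sep1"].astype("datetime64[ns]"),
            "ase_case": cases["ase"],
            "ase_t0": t0_cols["ase"].astype("datetime64[ns]"),
            "any_case": any_case,
            "t0_min": t0_min_dt.astype("datetime64[ns]"),
            "risk": risk,
            "peak_score": peak,
            "ramp_onset": onset.astype("datetime64[ns]"),
            "planted_lead_hours": lead_h,
        }
    )
    return SimResult(encounters=encounters, events=events, predictions=predictions, truth=truth)


def _unit_intervals(etype: np.ndarray, arrival: np.ndarray, discharge: np.ndarray, died: np.ndarray):
    """Unit timeline per encounter: ED-first for ED arrivals, ICU tail for
    in-hospital deaths, half-open [start, end) convention downstream."""
    out = []
    for t, a, d, dead in zip(etype, arrival, discharge, died):
        a = pd.Timestamp(a)
        d = pd.Timestamp(d)
        if t == "ed_only":
            out.append([("ED", a, d)])
            continue
        if t in ("ed_to_hosp",):
            cut = min(a + pd.Timedelta(hours=4), d)
            segs = [("ED", a, cut)]
            rest_start = cut
        else:
            segs = []
            rest_start = a
        if rest_start < d:
            if dead and d - rest_start > pd.Timedelta(hours=8):
                icu_start = d - (d - rest_start) / 4
                segs += [("ward", rest_start, icu_start), ("ICU", icu_start, d)]
            else:
                segs.append(("ward", rest_start, d))
        out.append(segs)
    return out


def truth_to_labels(truth: pd.DataFrame, definition: str) -> pd.DataFrame:
    """Planted truth in the phenotype-label layout for one definition."""
    return pd.DataFrame(
        {
            "encounter_id": truth["encounter_id"],
            "definition": definition,
            "is_case": truth[f"{definition}_case"].to_numpy(),
            "time_zero": truth[f"{definition}_t0"].to_numpy(),
        }
    )
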