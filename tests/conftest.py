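import numpy as np
import pandas as pd
import pytest

import sepseval as sv

T0 = pd.Timestamp("2024-03-20 08:00")


def ev(enc, hours, concept, value=None, kind=None, abx=None, pat=None):
    """One event row at T0 + hours, with the kind inferred from the concept."""
    if kind is None:
        kind = {
            "blood_culture_order": "order",
            "lactate_order": "order",
            "iv_antibiotic_admin": "med_admin",
            "vasopressor_admin": "med_admin",
            "mech_vent_start": "procedure",
        }.get(concept, "lab" if value is not None and concept not in
              ("temperature_c", "heart_rate", "resp_rate", "sbp_mmHg", "map_mmHg") else "vital")
    if concept == "iv_antibiotic_admin" and abx is None:
        abx = "cefepime"
    return {
        "encounter_id": enc,
        "patient_id": pat or f"P-{enc}",
        "time": T0 + pd.Timedelta(hours=hours),
        "kind": kind,
        "concept": concept,
        "value": np.nan if value is None else float(value),
        "antibiotic_name": abx,
    }


def events_frame(rows):
    return pd.DataFrame(rows).sort_values(["encounter_id", "time"]).reset_index(drop=True)


def encounter(enc="A", arrival_h=0.0, discharge_h=48.0, died=False, **kw):
    d = {
        "encounter_id": enc,
        "patient_id": f"P-{enc}",
        "arrival_time": T0 + pd.Timedelta(hours=arrival_h),
        "discharge_time": T0 + pd.Timedelta(hours=discharge_h),
        "encounter_type": "ed_to_hosp",
        "hospital_type": "academic",
        "unit_intervals": [("ED", T0 + pd.Timedelta(hours=arrival_h), T0 + pd.Timedelta(hours=discharge_h))],
        "age_years": 60.0,
        "sex": "female",
        "race": "white",
        "ethnicity": "non_hispanic",
        "esi": 2,
        "died_in_hospital": died,
        "context": pd.NA,
    }
    d.update(kw)
    return d


@pytest.fixture(scope="session")
def small_cohort():
    """A planted synthetic cohort shared by recovery tests."""
    return sv.generate_cohort(sv.SimConfig(n_encounters=600, seed=42))


@pytest.fixture(scope="session")
def small_included(small_cohort):
    included, _ = sv.apply_inclusion_filters(small_cohort.encounters)
    return included
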