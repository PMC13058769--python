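"""Criterion logic and time-zero semantics of the three sepsis phenotypes."""

import numpy as np
import pandas as pd
import pytest

import sepseval as sv
from conftest import T0, encounter, ev, events_frame

CFG = sv.CriteriaConfig()


class TestSirs:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            # all four criteria inside the window
            (
                [
                    ev("A", 1.0, "temperature_c", 39.0),
                    ev("A", 1.5, "heart_rate", 100),
                    ev("A", 2.0, "resp_rate", 22),
                    ev("A", 2.5, "wbc_k_per_uL", 13, kind="lab"),
                ],
                4,
            ),
            # normal vitals fire nothing
            ([ev("A", 1.0, "temperature_c", 37.0)], 0),
            # strict thresholds: boundary values do not fire
            (
                [
                    ev("A", 1.0, "heart_rate", 90),
                    ev("A", 1.0, "resp_rate", 20),
                    ev("A", 1.0, "wbc_k_per_uL", 12, kind="lab"),
                ],
                0,
            ),
            # hypothermia and bandemia each count once
            (
                [
                    ev("A", 1.0, "temperature_c", 35.5),
                    ev("A", 1.2, "band_pct", 15, kind="lab"),
                    ev("A", 1.4, "wbc_k_per_uL", 13, kind="lab"),  # same criterion as bands
                ],
                2,
            ),
        ],
    )
    def test_sirs_count(self, rows, expected):
        events = events_frame(rows)
        assert sv.sirs_count(events, T0 + pd.Timedelta(hours=3), 6.0) == expected

    def test_no_events_in_window(self):
        events = events_frame([ev("A", 1.0, "temperature_c", 39.0)])
        assert sv.sirs_count(events, T0 + pd.Timedelta(hours=20), 6.0) == 0


class TestSofa:
    def test_missing_components_score_zero(self):
        total, sub = sv.sofa_score(events_frame([ev("A", 1.0, "heart_rate", 80)]), T0 + pd.Timedelta(hours=2))
        assert total == 0 and all(v == 0 for v in sub.values())

    def test_platelets_and_bilirubin_bands(self):
        events = events_frame(
            [ev("A", 1.0, "platelets_k_per_uL", 90, kind="lab"), ev("A", 1.5, "bilirubin_mg_dL", 2.5, kind="lab")]
        )
        total, sub = sv.sofa_score(events, T0 + pd.Timedelta(hours=2))
        assert sub["coagulation"] == 2 and sub["liver"] == 2 and total == 4

    def test_vasopressor_scores_cardiovascular_three(self):
        events = events_frame([ev("A", 1.0, "vasopressor_admin")])
        total, sub = sv.sofa_score(events, T0 + pd.Timedelta(hours=2))
        assert sub["cardiovascular"] == 3

    def test_worst_value_wins_within_lookback(self):
        events = events_frame(
            [
                ev("A", 1.0, "creatinine_mg_dL", 0.9, kind="lab"),
                ev("A", 2.0, "creatinine_mg_dL", 3.6, kind="lab"),
                ev("A", 3.0, "creatinine_mg_dL", 1.0, kind="lab"),
            ]
        )
        total, sub = sv.sofa_score(events, T0 + pd.Timedelta(hours=4))
        assert sub["renal"] == 3

    def test_respiration_requires_support_for_severe_bands(self):
        base = [ev("A", 1.0, "pao2_fio2", 150, kind="lab")]
        _, sub = sv.sofa_score(events_frame(base), T0 + pd.Timedelta(hours=2))
        assert sub["respiration"] == 2  # capped without ventilation
        vented = base + [ev("A", 0.5, "mech_vent_start")]
        _, sub = sv.sofa_score(events_frame(vented), T0 + pd.Timedelta(hours=2))
        assert sub["respiration"] == 3


class TestSuspectedInfection:
    def test_antibiotic_within_72h_after_culture(self):
        events = events_frame([ev("A", 0.0, "blood_culture_order"), ev("A", 10.0, "iv_antibiotic_admin")])
        pairs = sv.detect_suspected_infection(events)
        assert len(pairs) == 1 and pairs[0][0] == T0

    def test_culture_too_late_after_antibiotic(self):
        events = events_frame([ev("A", 0.0, "iv_antibiotic_admin"), ev("A", 30.0, "blood_culture_order")])
        assert sv.detect_suspected_infection(events) == []

    def test_culture_within_24h_after_antibiotic(self):
        events = events_frame([ev("A", 0.0, "iv_antibiotic_admin"), ev("A", 20.0, "blood_culture_order")])
        pairs = sv.detect_suspected_infection(events)
        assert len(pairs) == 1 and pairs[0][0] == T0

    def test_no_antibiotics_no_pairs(self):
        events = events_frame([ev("A", 0.0, "blood_culture_order")])
        assert sv.detect_suspected_infection(events) == []


class TestSepsis3:
    def _infected(self, extra):
        return events_frame(
            [
                ev("A", 0.0, "creatinine_mg_dL", 0.8, kind="lab"),
                ev("A", 4.0, "blood_culture_order"),
                ev("A", 5.0, "iv_antibiotic_admin"),
            ]
            + extra
        )

    def test_sofa_rise_of_one_is_not_a_case(self):
        lab = sv.sepsis3_label(self._infected([ev("A", 6.0, "creatinine_mg_dL", 1.5, kind="lab")]), encounter())
        assert not lab.is_case and lab.time_zero is None

    def test_sofa_rise_without_suspicion_is_not_a_case(self):
        events = events_frame(
            [
                ev("A", 6.0, "creatinine_mg_dL", 2.5, kind="lab"),
                ev("A", 6.0, "platelets_k_per_uL", 80, kind="lab"),
            ]
        )
        assert not sv.sepsis3_label(events, encounter()).is_case

    def test_case_time_zero_is_suspicion_time(self):
        events = self._infected(
            [
                ev("A", 6.0, "creatinine_mg_dL", 1.5, kind="lab"),
                ev("A", 6.1, "platelets_k_per_uL", 120, kind="lab"),
            ]
        )
        lab = sv.sepsis3_label(events, encounter())
        assert lab.is_case and lab.time_zero == T0 + pd.Timedelta(hours=4)
        assert lab.components["sofa_max"] - lab.components["sofa_baseline"] >= 2

    def test_elevated_baseline_blocks_delta(self):
        """A chronically elevated pre-suspicion SOFA does not count as an acute rise."""
        events = events_frame(
            [
                ev("A", 1.0, "creatinine_mg_dL", 3.6, kind="lab"),  # baseline already 3 points
                ev("A", 4.0, "blood_culture_order"),
                ev("A", 5.0, "iv_antibiotic_admin"),
                ev("A", 6.0, "creatinine_mg_dL", 3.8, kind="lab"),
            ]
        )
        lab = sv.sepsis3_label(events, encounter())
        assert not lab.is_case


class TestSep1:
    def test_organ_dysfunction_thresholds(self):
        at = T0 + pd.Timedelta(hours=2)
        fired = sv.sep1_organ_dysfunction(events_frame([ev("A", 1.0, "lactate_mmol_L", 2.1, kind="lab")]), at)
        assert fired == {"lactate_high"}
        fired = sv.sep1_organ_dysfunction(events_frame([ev("A", 1.0, "lactate_mmol_L", 2.0, kind="lab")]), at)
        assert fired == set()  # strict >
        fired = sv.sep1_organ_dysfunction(
            events_frame([ev("A", 1.0, "sbp_mmHg", 85), ev("A", 1.2, "platelets_k_per_uL", 90, kind="lab")]), at
        )
        assert {"sbp_low", "platelets_low"} <= fired

    def test_sbp_drop_from_running_baseline(self):
        events = events_frame([ev("A", 0.5, "sbp_mmHg", 150), ev("A", 2.0, "sbp_mmHg", 105)])
        fired = sv.sep1_organ_dysfunction(events, T0 + pd.Timedelta(hours=3))
        assert fired == {"sbp_drop"}  # 45 mmHg drop, but not < 90

    def test_two_sirs_without_organ_dysfunction_not_case(self):
        events = events_frame([ev("A", 1.0, "temperature_c", 39.0), ev("A", 1.2, "heart_rate", 105)])
        assert not sv.sep1_label(events, encounter()).is_case

    def test_organ_dysfunction_outside_window_not_case(self):
        events = events_frame(
            [
                ev("A", 1.0, "temperature_c", 39.0),
                ev("A", 1.5, "heart_rate", 105),
                ev("A", 20.0, "lactate_mmol_L", 3.0, kind="lab"),
            ]
        )
        assert not sv.sep1_label(events, encounter()).is_case

    def test_time_zero_is_completion_of_conjunction(self):
        events = events_frame(
            [
                ev("A", 1.0, "temperature_c", 39.0),
                ev("A", 1.5, "heart_rate", 105),
                ev("A", 3.0, "lactate_mmol_L", 3.0, kind="lab"),
            ]
        )
        lab = sv.sep1_label(events, encounter())
        assert lab.is_case and lab.time_zero == T0 + pd.Timedelta(hours=3)


class TestQad:
    def _abx_days(self, days, died=False, discharge_h=240.0):
        rows = [ev("A", 0.0, "blood_culture_order")]
        rows += [ev("A", 1.0 + 24 * d, "iv_antibiotic_admin") for d in days]
        return events_frame(rows), encounter(died=died, discharge_h=discharge_h)

    def test_four_consecutive_days_qualify(self):
        events, enc = self._abx_days([0, 1, 2, 3])
        ok, start = sv.qualifying_antibiotic_days(events, T0, enc)
        assert ok and start == T0 + pd.Timedelta(hours=1)

    def test_two_days_then_live_discharge_does_not_qualify(self):
        events, enc = self._abx_days([0, 1], died=False)
        ok, _ = sv.qualifying_antibiotic_days(events, T0, enc)
        assert not ok

    def test_death_exception_qualifies(self):
        events, enc = self._abx_days([0, 1], died=True, discharge_h=50.0)
        ok, start = sv.qualifying_antibiotic_days(events, T0, enc)
        assert ok and start == T0 + pd.Timedelta(hours=1)

    def test_one_day_gap_is_bridged(self):
        events, enc = self._abx_days([0, 1, 3, 4])
        ok, _ = sv.qualifying_antibiotic_days(events, T0, enc)
        assert ok

    def test_start_outside_culture_window_does_not_qualify(self):
        events, enc = self._abx_days([4, 5, 6, 7])
        ok, _ = sv.qualifying_antibiotic_days(events, T0, enc)
        assert not ok

    def test_prior_antibiotics_block_new_start(self):
        events, enc = self._abx_days([-2, 0, 1, 2, 3])
        ok, _ = sv.qualifying_antibiotic_days(events, T0 + pd.Timedelta(hours=48), enc)
        assert not ok  # day-0 start is not "new" relative to day -2


class TestAseOrganDysfunction:
    def test_creatinine_doubling(self):
        events = events_frame(
            [
                ev("A", -72.0, "creatinine_mg_dL", 0.8, kind="lab"),
                ev("A", 2.0, "creatinine_mg_dL", 1.7, kind="lab"),
            ]
        )
        fired = sv.ase_organ_dysfunction(events, T0 + pd.Timedelta(hours=49))
        assert "creatinine_doubling" in fired

    def test_platelet_baseline_gate(self):
        events = events_frame(
            [
                ev("A", -72.0, "platelets_k_per_uL", 90, kind="lab"),
                ev("A", 2.0, "platelets_k_per_uL", 40, kind="lab"),
            ]
        )
        fired = sv.ase_organ_dysfunction(events, T0 + pd.Timedelta(hours=49))
        assert "platelet_decline" not in fired  # baseline < 100

    def test_lactate_inclusive_boundary(self):
        events = events_frame([ev("A", 1.0, "lactate_mmol_L", 2.0, kind="lab")])
        fired = sv.ase_organ_dysfunction(events, T0)
        assert "lactate" in fired  # >= per ASE


class TestAseLabel:
    def _base(self, extra, died=False):
        rows = [ev("A", 2.0, "blood_culture_order")]
        rows += [ev("A", 3.0 + 24 * d, "iv_antibiotic_admin") for d in range(4)]
        return events_frame(rows + extra), encounter(died=died, discharge_h=240.0)

    def test_culture_and_qad_without_dysfunction_not_case(self):
        events, enc = self._base([])
        assert not sv.ase_label(events, enc).is_case

    def test_time_zero_minimum_over_components(self):
        # organ dysfunction precedes the culture: time zero = dysfunction time
        events, enc = self._base([ev("A", 1.0, "lactate_mmol_L", 2.5, kind="lab")])
        lab = sv.ase_label(events, enc)
        assert lab.is_case and lab.time_zero == T0 + pd.Timedelta(hours=1)

    def test_culture_anchored_mode(self):
        events, enc = self._base([ev("A", 1.0, "lactate_mmol_L", 2.5, kind="lab")])
        cfg = sv.CriteriaConfig(ase_time_zero_mode="culture")
        lab = sv.ase_label(events, enc, cfg)
        assert lab.is_case and lab.time_zero == T0 + pd.Timedelta(hours=2)


class TestPlantedRecovery:
    def test_exact_case_sets_and_time_zeros(self, small_cohort, small_included):
        labels = sv.label_cohort(small_cohort.events, small_included)
        truth = small_cohort.truth.set_index("encounter_id")
        for d in ("sepsis3", "sep1", "ase"):
            lab = labels[labels["definition"] == d].set_index("encounter_id")
            tr = truth.loc[lab.index]
            assert (lab["is_case"] == tr[f"{d}_case"]).all()
            cases = lab.index[lab["is_case"]]
            assert (pd.to_datetime(lab.loc[cases, "time_zero"]) == tr.loc[cases, f"{d}_t0"]).all()

    def test_every_case_carries_component_provenance(self, small_cohort, small_included):
        labels = sv.label_cohort(small_cohort.events, small_included)
        fired = labels[labels["is_case"]]
        assert (fired["components_json"] != "{}").all()


class TestTimeZeroStability:
    def test_future_events_never_move_time_zero(self):
        """Appending later events cannot change an established time zero."""
        base = [
            ev("A", 0.0, "creatinine_mg_dL", 0.8, kind="lab"),
            ev("A", 4.0, "blood_culture_order"),
            ev("A", 5.0, "iv_antibiotic_admin"),
            ev("A", 6.0, "creatinine_mg_dL", 1.5, kind="lab"),
            ev("A", 6.1, "platelets_k_per_uL", 120, kind="lab"),
            ev("A", 1.0, "temperature_c", 39.0),
            ev("A", 1.2, "heart_rate", 110),
            ev("A", 2.0, "lactate_mmol_L", 3.0, kind="lab"),
        ]
        later = [
            ev("A", 30.0, "blood_culture_order"),
            ev("A", 31.0, "iv_antibiotic_admin"),
            ev("A", 32.0, "creatinine_mg_dL", 4.0, kind="lab"),
            ev("A", 33.0, "sbp_mmHg", 70),
            ev("A", 33.1, "temperature_c", 40.0),
            ev("A", 33.2, "heart_rate", 130),
        ]
        enc = encounter()
        for labeller in (sv.sepsis3_label, sv.sep1_label):
            before = labeller(events_frame(base), enc)
            after = labeller(events_frame(base + later), enc)
            assert before.is_case and after.is_case
            assert before.time_zero == after.time_zero

    def test_determinism_on_identical_streams(self, small_cohort, small_included):
        a = sv.label_cohort(small_cohort.events, small_included.head(40), definitions=("sep1",))
        b = sv.label_cohort(small_cohort.events.copy(), small_included.head(40), definitions=("sep1",))
        pd.testing.assert_frame_equal(a, b)
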