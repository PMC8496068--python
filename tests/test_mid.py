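import numpy as np
import pandas as pd
import pytest

from promid.changes import make_change_records
from promid.exceptions import EstimationError
from promid.mid import (
    MIDEstimate,
    apply_es_filter,
    between_group_mid,
    trial_interaction_test,
    within_group_mid,
)
from promid.simulate import generate, small_scenario


def records_frame(changes_by_ccg, trial="t1", start_patient=0, patient_per_record=True):
    """Construct a change-record frame directly from {ccg: [changes]}."""
    rows = []
    i = start_patient
    for ccg, changes in changes_by_ccg.items():
        for c in changes:
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "trial_id": trial,
                    "scale_code": "PF",
                    "anchor_code": "PS",
                    "time_from": 1,
                    "time_to": 2,
                    "score_from": 50.0,
                    "score_to": 50.0 + c,
                    "hrqol_change": float(c),
                    "anchor_change": {"improved": 1, "stable": 0, "deteriorated": -1, "excluded": 3}[ccg],
                    "ccg": ccg,
                }
            )
            if patient_per_record:
                i += 1
    return pd.DataFrame(rows)


class TestWithinGroup:
    def test_mean_change(self):
        rec = records_frame({"improved": [10, 20, 12], "stable": [0, 1, -1]})
        est = within_group_mid(rec, "improvement")
        assert est.mid == pytest.approx(14.0)
        assert est.n_records == 3

    def test_constant_changes(self):
        rec = records_frame({"deteriorated": [-5, -5, -5], "stable": [0, 2, -2]})
        est = within_group_mid(rec, "deterioration")
        assert est.mid == pytest.approx(-5.0)

    def test_es_uses_sd_over_all_records(self):
        rec = records_frame({"improved": [10, 10], "stable": [0, 0], "deteriorated": [-10, -10]})
        sd_all = rec[rec.ccg != "excluded"].hrqol_change.std(ddof=1)
        est = within_group_mid(rec, "improvement")
        assert est.es == pytest.approx(10.0 / sd_all)

    def test_empty_ccg_raises_no_mid(self):
        rec = records_frame({"stable": [0, 1, 2]})
        with pytest.raises(EstimationError, match="no MID"):
            within_group_mid(rec, "improvement")


class TestBetweenGroup:
    def test_balanced_contrast(self):
        rec = records_frame({"improved": [5, 4, 6, 5], "stable": [0, 1, -1, 0]})
        est = between_group_mid(rec, "improvement", working_correlation="independence")
        assert est.mid == pytest.approx(5.0)

    def test_empty_group_raises(self):
        rec = records_frame({"improved": [5, 6]})
        with pytest.raises(EstimationError, match="no MID"):
            between_group_mid(rec, "improvement")

    def test_gee_ols_identity_one_record_per_patient(self, rng):
        imp = list(rng.normal(5, 3, size=30))
        stab = list(rng.normal(0, 3, size=40))
        rec = records_frame({"improved": imp, "stable": stab})
        est = between_group_mid(rec, "improvement", working_correlation="independence")
        assert est.mid == pytest.approx(np.mean(imp) - np.mean(stab), abs=1e-8)


class TestEsFilter:
    @staticmethod
    def _est(es):
        return MIDEstimate("PF", "PS", "improvement", "within_group", 5.0, 0.5, 10, 10, es, False)

    @pytest.mark.parametrize(
        "es,expected",
        [
            (0.15, False),  # below the small-effect floor
            (0.2, True),    # lower bound inclusive
            (0.5, True),    # moderate: interior point
            (0.79, True),
            (0.8, False),   # large effects excluded (boundary exclusive)
            (-0.5, True),   # magnitude-based
            (-1.1, False),
        ],
    )
    def test_retention_band(self, es, expected):
        assert apply_es_filter(self._est(es)).retained is expected

    def test_reason_recorded(self):
        assert "0.2" in apply_es_filter(self._est(0.15)).reason


class TestExclusionSafety:
    def test_excluded_records_never_influence_estimates(self, rng):
        rec = records_frame(
            {"improved": list(rng.normal(5, 2, 20)), "stable": list(rng.normal(0, 2, 40)),
             "deteriorated": list(rng.normal(-8, 2, 20))}
        )
        poisoned = pd.concat(
            [rec, records_frame({"excluded": [500.0, -500.0, 900.0]}, start_patient=500)],
            ignore_index=True,
        )
        for direction in ("improvement", "deterioration"):
            a = within_group_mid(rec, direction)
            b = within_group_mid(poisoned, direction)
            assert (a.mid, a.se, a.es) == (b.mid, b.se, b.es)
            ba = between_group_mid(rec, direction, working_correlation="independence")
            bb = between_group_mid(poisoned, direction, working_correlation="independence")
            assert ba.mid == pytest.approx(bb.mid, abs=1e-12)


class TestTrialInteraction:
    def test_single_trial_skipped(self):
        rec = records_frame({"improved": [5, 6, 4], "stable": [0, 1, -1]})
        test = trial_interaction_test(rec, "improvement")
        assert test.p_value is None
        assert "single-trial" in test.reason

    def test_large_contrast_flagged(self, rng):
        rec1 = records_frame({"deteriorated": list(rng.normal(-5, 4, 80)),
                              "stable": list(rng.normal(0, 4, 120))}, trial="t1")
        rec2 = records_frame({"deteriorated": list(rng.normal(-25, 4, 80)),
                              "stable": list(rng.normal(0, 4, 120))},
                             trial="t2", start_patient=1000)
        test = trial_interaction_test(pd.concat([rec1, rec2], ignore_index=True), "deterioration")
        assert test.flagged and test.p_value < 1e-6


def test_within_group_recovery_over_twenty_trials():
    """Mean absolute estimation error across 20 simulated trials stays under
    one point for true deterioration MIDs of -5, -10 and -15."""
    errors = []
    seed = 100
    for true_det in (-5.0, -10.0, -15.0):
        for rep in (0, 1, 2, 3, 4, 5, 6)[: 7 if true_det != -15.0 else 6]:
            cfg = small_scenario(
                seed=seed, n_patients=(500, 500), n_timepoints=4,
                true_mid_deterioration=true_det,
            )
            seed += 1
            table, truth = generate(cfg)
            rec = make_change_records(table, "PF", table.anchor_defs["PS"])
            est = within_group_mid(rec, "deterioration")
            errors.append(abs(est.mid - true_det))
    assert len(errors) == 20
    assert np.mean(errors) < 1.0
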