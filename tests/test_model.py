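import numpy as np
import pandas as pd
import pytest

from gafunc.enface import ALL_FEATURES
from gafunc.grid import StandardGrid
from gafunc.model import (
    block_mean,
    bootstrap_evaluate,
    build_feature_table,
    predictor_columns,
    predictor_name,
    select_one_eye,
    sensitivity_one_eye,
)


def fake_table(n_patients, eyes_per_patient=1, n_predictors=20, seed=0,
               outcome="va_letters", y=None):
    """A feature table with random predictors and optional custom outcome."""
    rng = np.random.default_rng(seed)
    rows = n_patients * eyes_per_patient
    names = [predictor_name(ALL_FEATURES[0], 0, j) for j in range(n_predictors)]
    X = rng.random((rows, n_predictors))
    table = pd.DataFrame(X, columns=names)
    table.insert(0, "patient_id", np.repeat([f"P{i:03d}" for i in range(n_patients)],
                                            eyes_per_patient))
    table.insert(1, "eye_id", [f"E{i:04d}" for i in range(rows)])
    table[outcome] = rng.uniform(0, 100, rows) if y is None else y
    table.attrs["outcome"] = outcome
    return table


def grids_for(n_eyes, shape=(49, 49), seed=0):
    rng = np.random.default_rng(seed)
    return {
        f"E{i:04d}": {f: StandardGrid(rng.random(shape), 3.0, f) for f in ALL_FEATURES}
        for i in range(n_eyes)
    }


class TestFeatureTable:
    def test_block_mean(self):
        a = np.array([[0.2, 0.4], [0.6, 0.8]])
        assert block_mean(a, 2)[0, 0] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            block_mean(np.zeros((49, 49)), 5)

    def test_predictor_counts(self):
        grids = grids_for(2)
        outcomes = pd.DataFrame(
            {
                "patient_id": ["P0", "P1"],
                "eye_id": ["E0000", "E0001"],
                "va_letters": [50.0, 60.0],
            }
        )
        raw = build_feature_table(grids, outcomes, "va_letters", downsample_k=1)
        assert len(predictor_columns(raw)) == 4 * 49 * 49  # 9604
        ds = build_feature_table(grids, outcomes, "va_letters", downsample_k=7)
        assert len(predictor_columns(ds)) == 4 * 7 * 7  # 196
        # feature-major then row-major ordering
        cols = predictor_columns(ds)
        assert cols[0] == predictor_name(ALL_FEATURES[0], 0, 0)
        assert cols[49] == predictor_name(ALL_FEATURES[1], 0, 0)

    def test_short_outcome_name_resolves(self):
        grids = grids_for(2)
        outcomes = pd.DataFrame(
            {"patient_id": ["P0", "P1"], "eye_id": ["E0000", "E0001"],
             "va_letters": [50.0, 60.0]}
        )
        t = build_feature_table(grids, outcomes, "va", downsample_k=7)
        assert t.attrs["outcome"] == "va_letters"

    def test_missing_outcomes_dropped_or_rejected(self):
        grids = grids_for(3)
        outcomes = pd.DataFrame(
            {
                "patient_id": ["P0", "P1", "P2"],
                "eye_id": ["E0000", "E0001", "E0002"],
                "llva_letters": [40.0, np.nan, 30.0],
            }
        )
        t = build_feature_table(grids, outcomes, "llva_letters", downsample_k=7)
        assert len(t) == 2
        outcomes["llva_letters"] = np.nan
        with pytest.raises(ValueError, match="llva_letters"):
            build_feature_table(grids, outcomes, "llva_letters", downsample_k=7)


class TestBootstrapEvaluate:
    def test_recovers_noiseless_linear_signal(self):
        t = fake_table(200, n_predictors=40, seed=1)
        x = t[predictor_columns(t)[5]].to_numpy()
        t["va_letters"] = 10.0 + 80.0 * x
        res = bootstrap_evaluate(t, n_replicates=15, seed=2)
        assert res.summary["r2"] >= 0.9

    def test_no_patient_leaks_across_split(self):
        t = fake_table(30, eyes_per_patient=2, n_predictors=5, seed=3)
        res = bootstrap_evaluate(
            t, n_replicates=100, seed=4, rf_params={"n_estimators": 5},
            keep_splits=True,
        )
        assert len(res.splits) == 100
        for train_units, test_units in res.splits:
            assert not set(train_units) & set(test_units)
            assert len(test_units) > 0

    def test_reproducible_for_fixed_seed(self):
        t = fake_table(25, n_predictors=8, seed=5)
        kwargs = dict(n_replicates=10, seed=6, rf_params={"n_estimators": 10})
        a = bootstrap_evaluate(t, **kwargs)
        b = bootstrap_evaluate(t, **kwargs)
        np.testing.assert_array_equal(a.r2, b.r2)
        np.testing.assert_array_equal(a.mae, b.mae)
        np.testing.assert_array_equal(a.importances, b.importances)

    def test_split_only_scheme(self):
        t = fake_table(25, n_predictors=5, seed=7)
        res = bootstrap_evaluate(
            t, n_replicates=5, scheme="split_only", seed=8,
            rf_params={"n_estimators": 5}, keep_splits=True,
        )
        n_units = t["patient_id"].nunique()
        for train_units, test_units in res.splits:
            assert len(train_units) + len(test_units) == n_units

    def test_summary_quartiles_ordered(self):
        t = fake_table(25, n_predictors=5, seed=9)
        s = bootstrap_evaluate(
            t, n_replicates=20, seed=10, rf_params={"n_estimators": 5}
        ).summary
        assert 0 <= s["mae_q25"] <= s["mae"] <= s["mae_q75"] <= 100

    def test_constant_outcome_replicates_excluded(self):
        t = fake_table(12, n_predictors=4, seed=11, y=np.full(12, 50.0))
        with pytest.raises(RuntimeError, match="constant"):
            bootstrap_evaluate(t, n_replicates=3, seed=12,
                               rf_params={"n_estimators": 2})

    def test_too_few_patients_rejected(self):
        t = fake_table(5, n_predictors=4, seed=13)
        with pytest.raises(ValueError, match="10"):
            bootstrap_evaluate(t, n_replicates=2, seed=0)


class TestOneEyeSensitivity:
    def test_noop_on_unilateral_cohort(self):
        t = fake_table(20, eyes_per_patient=1, n_predictors=6, seed=14)
        kwargs = dict(n_replicates=8, rf_params={"n_estimators": 10})
        a = sensitivity_one_eye(t, seed=15, **kwargs)
        b = bootstrap_evaluate(t, seed=15, **kwargs)
        np.testing.assert_array_equal(a.r2, b.r2)
        np.testing.assert_array_equal(a.mae, b.mae)

    def test_published_cohort_structure_reduces_to_patients(self):
        # 476 eyes from 325 patients: 151 bilateral + 174 unilateral
        rows = []
        eye = 0
        for p in range(325):
            for _ in range(2 if p < 151 else 1):
                rows.append({"patient_id": f"P{p:03d}", "eye_id": f"E{eye:04d}",
                             "x__r00c00": 0.5, "va_letters": 50.0})
                eye += 1
        t = pd.DataFrame(rows)
        assert len(t) == 476
        sub = select_one_eye(t, rule="random", seed=16)
        assert len(sub) == 325
        assert sub["patient_id"].is_unique
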