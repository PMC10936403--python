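import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from ftss import (
    Cohort,
    DataError,
    SubjectRecord,
    build_design_matrix,
    classification_metrics,
    make_classification_problem,
    make_poisson_problem,
    mean_of_sexes,
    outcome_labels,
    poisson_elastic_net_cv,
    regression_metrics,
    sfs_logistic_cv,
)
from ftss.models import fit_logistic, poisson_elastic_net_path


def _cohort_and_features(n=24, seed=0):
    rng = np.random.default_rng(seed)
    subs, rows = [], []
    for i in range(n):
        subs.append(SubjectRecord(
            subject_id=f"S{i:03d}", age=float(rng.uniform(60, 90)),
            sex="male" if i % 2 else "female",
            height_cm=float(rng.normal(170, 8)), weight_kg=float(rng.normal(72, 9)),
            mmse=int(rng.integers(20, 31)), bbs=int(rng.integers(45, 57)),
            falls_12mo=int(rng.integers(0, 3)), injurious_fall=bool(rng.random() < 0.2),
            arm="clinic",
        ))
        for k in range(2):
            rows.append({"subject_id": f"S{i:03d}", "trial_id": f"t{k}",
                         "total_time": float(rng.normal(12, 2)),
                         "sss_time_mean": float(rng.normal(2.2, 0.3)),
                         "rms_accel_z": float(rng.normal(0.8, 0.1))})
    return Cohort(subs), pd.DataFrame(rows)


class TestDesignMatrix:
    def test_first_trial_only(self):
        cohort, feats = _cohort_and_features()
        dm = build_design_matrix(cohort, feats)
        assert len(dm.frame) == 24  # one row per subject

    def test_pairwise_interaction_count_and_names(self):
        cohort, feats = _cohort_and_features()
        base = build_design_matrix(cohort, feats, interactions=False)
        dm = build_design_matrix(
            cohort, feats, interactions=True,
            interaction_candidates=["total_time", "age", "height_cm"],
        )
        # 3 candidates -> C(3,2) = 3 interaction columns, canonically named
        assert len(dm.frame.columns) == len(base.frame.columns) + 3
        assert "age:total_time" in dm.frame.columns  # lexicographic order

    def test_sex_stratified_matrix_has_no_sex_column(self):
        cohort, feats = _cohort_and_features()
        dm = build_design_matrix(cohort, feats, stratum="female")
        assert "sex" not in dm.frame.columns
        assert len(dm.frame) == 12

    def test_training_standardization_is_exact(self):
        cohort, feats = _cohort_and_features()
        dm = build_design_matrix(cohort, feats)
        train = np.arange(16)
        X = dm.standardize(train)
        cont = [j for j, c in enumerate(dm.frame.columns) if c != "sex"]
        np.testing.assert_allclose(X[np.ix_(train, cont)].mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(X[np.ix_(train, cont)].std(axis=0), 1, atol=1e-9)

    def test_constant_column_dropped(self, caplog):
        cohort, feats = _cohort_and_features()
        feats["flat"] = 1.0
        with caplog.at_level("WARNING"):
            dm = build_design_matrix(cohort, feats)
        assert "flat" not in dm.frame.columns


class TestMetrics:
    def test_confusion_arithmetic(self):
        m = classification_metrics({"tp": 40, "fn": 8, "tn": 45, "fp": 7})
        assert m["acc"] == pytest.approx(85.0)
        assert m["sens"] == pytest.approx(83.3, abs=0.05)
        assert m["spec"] == pytest.approx(86.5, abs=0.05)

    def test_perfect_classifier(self):
        m = classification_metrics({"tp": 10, "fn": 0, "tn": 10, "fp": 0})
        assert all(v == 100.0 for v in m.values())

    def test_always_positive_on_balanced_data(self):
        m = classification_metrics({"tp": 50, "fn": 0, "tn": 0, "fp": 50})
        assert m["sens"] == 100.0 and m["spec"] == 0.0 and m["acc"] == 50.0

    def test_zero_denominator_not_applicable(self):
        m = classification_metrics({"tp": 0, "fn": 0, "tn": 10, "fp": 0})
        assert m["sens"] is None and m["ppv"] is None

    def test_regression_identity(self):
        y = np.array([50.0, 52, 54, 56])
        m = regression_metrics(y, y)
        assert m["r2"] == pytest.approx(1.0) and m["rmse"] == 0.0 and m["rho"] == 1.0

    def test_regression_mean_predictor_r2_zero(self):
        y = np.array([50.0, 52, 54, 56])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_regression_rmse_arithmetic(self):
        m = regression_metrics([50, 52, 54, 56], [51, 53, 53, 57])
        assert m["rmse"] == pytest.approx(1.0)


class TestLogistic:
    def test_matches_statsmodels_mle(self, rng):
        X = rng.standard_normal((200, 3))
        y = (rng.random(200) < 1 / (1 + np.exp(-(X @ [0.8, -0.5, 0.2])))).astype(float)
        beta = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        np.testing.assert_allclose(beta, ref, atol=1e-4)

    def test_separation_yields_finite_fit(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)  # perfectly separable
        beta = fit_logistic(X, y)
        assert np.all(np.isfinite(beta))


class TestSfs:
    def test_forced_feature_in_every_fold(self):
        dm, y, _ = make_classification_problem(150, 10, {"f01": 2.0}, seed=3)
        rep = sfs_logistic_cv(dm, y, seed=0)
        assert all("total_time" in sel for sel in rep.selected_features)

    def test_informative_features_found(self):
        dm, y, _ = make_classification_problem(300, 15, {"f01": 3.0, "f02": 3.0}, seed=4)
        rep = sfs_logistic_cv(dm, y, seed=0)
        found = sum(("f01" in s) and ("f02" in s) for s in rep.selected_features)
        assert found >= 8
        assert rep.acc >= 80.0

    def test_reproducible_from_seed(self):
        dm, y, _ = make_classification_problem(120, 8, {"f01": 2.0}, seed=5)
        a = sfs_logistic_cv(dm, y, seed=7)
        b = sfs_logistic_cv(dm, y, seed=7)
        assert a == b

    def test_confusion_covers_every_subject_once(self):
        dm, y, _ = make_classification_problem(140, 8, {"f01": 2.0}, seed=6)
        rep = sfs_logistic_cv(dm, y, seed=1)
        assert sum(rep.confusion.values()) == 140

    def test_heldout_rows_cannot_steer_selection(self):
        """Perturbing a held-out subject leaves that fold's selected features unchanged."""
        dm, y, _ = make_classification_problem(120, 8, {"f01": 2.0}, seed=8)
        rep = sfs_logistic_cv(dm, y, seed=2)
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=2)
        folds = list(splitter.split(dm.frame, y))
        target_fold, victim = 3, folds[3][1][0]
        frame2 = dm.frame.copy()
        frame2.iloc[victim] = frame2.iloc[victim] * 50 + 100
        dm2 = type(dm)(frame=frame2, binary_columns=dm.binary_columns)
        rep2 = sfs_logistic_cv(dm2, y, seed=2)
        assert rep2.selected_features[target_fold] == rep.selected_features[target_fold]

    def test_class_starved_fold_rejected(self):
        dm, y, _ = make_classification_problem(40, 5, seed=9)
        y = np.zeros(40)
        y[:3] = 1  # 3 positives cannot stratify 10 folds
        with pytest.raises(DataError):
            sfs_logistic_cv(dm, y, seed=0)

    def test_mean_of_sexes_is_unweighted(self):
        dm, y, _ = make_classification_problem(150, 6, {"f01": 2.0}, seed=10)
        a = sfs_logistic_cv(dm, y, seed=0, stratum="male")
        b = sfs_logistic_cv(dm, y, seed=1, stratum="female")
        m = mean_of_sexes(a, b)
        assert m["acc"] == pytest.approx(0.5 * (a.acc + b.acc))


class TestPoissonElasticNet:
    def test_tiny_penalty_matches_unpenalized_mle(self, rng):
        X = rng.standard_normal((300, 4))
        y = rng.poisson(np.exp(1.5 + X @ [0.3, -0.2, 0.1, 0.0])).astype(float)
        path = poisson_elastic_net_path(X, y, np.array([1e-8]))
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit().params
        np.testing.assert_allclose(path[0], ref, atol=1e-4)

    def test_ridge_limit_keeps_all_coefficients(self, rng):
        X = rng.standard_normal((200, 8))
        y = rng.poisson(np.exp(2.0 + X @ np.r_[0.3, np.zeros(7)])).astype(float)
        path = poisson_elastic_net_path(X, y, np.array([0.05]), alpha=0.0)
        assert np.all(np.abs(path[0][1:]) > 1e-8)  # pure ridge never zeroes

    def test_near_deterministic_counts_recovered(self):
        rng = np.random.default_rng(11)
        dm, _, _ = make_poisson_problem(400, 10, seed=11)
        X = dm.frame.to_numpy()
        beta = np.r_[0.4, -0.3, np.zeros(8)]
        y = np.round(np.exp(3.0 + X @ beta))
        rep = poisson_elastic_net_cv(dm, y, seed=0)
        assert rep.r2 >= 0.95

    def test_model_size_bounds_respected(self):
        dm, y, _ = make_poisson_problem(400, 30, {"total_time": -0.2, "f03": 0.3},
                                        seed=12)
        rep = poisson_elastic_net_cv(dm, y, seed=0)
        sizes = [len(s) for s in rep.selected_features]
        assert all(3 <= s <= 20 for s in sizes)

    def test_forced_feature_always_selected(self):
        dm, y, _ = make_poisson_problem(300, 12, {"f02": 0.3}, seed=13)
        rep = poisson_elastic_net_cv(dm, y, seed=0)
        assert all("total_time" in s for s in rep.selected_features)

    def test_non_integer_scores_rejected(self):
        dm, y, _ = make_poisson_problem(100, 5, seed=14)
        with pytest.raises(DataError):
            poisson_elastic_net_cv(dm, y + 0.5, seed=0)

    def test_reproducible_from_seed(self):
        dm, y, _ = make_poisson_problem(200, 8, {"f01": 0.2}, seed=15)
        a = poisson_elastic_net_cv(dm, y, seed=3)
        b = poisson_elastic_net_cv(dm, y, seed=3)
        assert a.rmse == b.rmse and a.selected_features == b.selected_features


def test_outcome_labels_mapping():
    cohort, _ = _cohort_and_features()
    for outcome in ("balance", "cognition", "falls"):
        lab = outcome_labels(cohort, outcome)
        assert set(lab.unique()) <= {0, 1}
    assert outcome_labels(cohort, "bbs").max() <= 56
    assert outcome_labels(cohort, "mmse").max() <= 30
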