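import warnings

import numpy as np
import pandas as pd
import pytest

from fearsig.io import ValidationError
from fearsig.modeling import (
    ConfusionMatrix,
    MetricSet,
    SplitPlan,
    aggregate_models,
    auc_score,
    compute_metrics,
    confusion_report,
    loso_eval,
    make_splits,
    smbo_minimize,
    subject_dependent_eval,
    tune_and_train,
    zscore_by_subject,
    Real,
    Integer,
    Categorical,
)


def make_table(n_subjects=4, n_per_subject=40, signal=1.0, n_features=6, seed=0, pos_frac=0.3):
    """Small feature table; `signal` is the class separation in feature units."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        offset = rng.normal(0, 2, n_features)  # subject-specific baseline
        n_pos = int(round(pos_frac * n_per_subject))
        labels = np.array([1] * n_pos + [0] * (n_per_subject - n_pos))
        rng.shuffle(labels)
        for i, lab in enumerate(labels):
            x = offset + rng.normal(0, 1, n_features) + signal * lab
            rows.append(
                {
                    "subject_id": f"S{s:02d}",
                    "trial_id": f"T{i // 5:02d}",
                    "window_index": i % 5,
                    **{f"f{j}": x[j] for j in range(n_features)},
                    "fear_label": int(lab),
                }
            )
    return pd.DataFrame(rows)


class TestZscore:
    def test_per_subject_mean_zero_sd_one(self):
        t = zscore_by_subject(make_table())
        for _, g in t.groupby("subject_id"):
            assert np.allclose(g[[f"f{j}" for j in range(6)]].mean(), 0, atol=1e-12)
            assert np.allclose(g[[f"f{j}" for j in range(6)]].std(ddof=1), 1, atol=1e-12)

    def test_shift_invariance(self):
        t = make_table(n_subjects=2, seed=1)
        shifted = t.copy()
        cols = [f"f{j}" for j in range(6)]
        shifted.loc[shifted.subject_id == "S00", cols] += 100.0
        np.testing.assert_allclose(
            zscore_by_subject(t)[cols].to_numpy(), zscore_by_subject(shifted)[cols].to_numpy()
        )

    def test_zero_variance_feature_passes_as_zero_with_warning(self):
        t = make_table(n_subjects=2)
        t["f0"] = 7.0
        with pytest.warns(UserWarning):
            z = zscore_by_subject(t)
        assert (z["f0"] == 0).all()

    def test_single_sample_subject_is_error(self):
        t = make_table(n_subjects=2)
        t = pd.concat([t, t.iloc[[0]].assign(subject_id="LONELY")], ignore_index=True)
        with pytest.raises(ValidationError):
            zscore_by_subject(t)


class TestSplits:
    def test_loso_plans_cover_every_subject_without_overlap(self):
        t = make_table(n_subjects=5)
        plans = make_splits(t, SplitPlan("loso"))
        assert len(plans) == 5
        for p in plans:
            train_subj = set(t.iloc[p["train"]]["subject_id"])
            test_subj = set(t.iloc[p["test"]]["subject_id"])
            assert test_subj == {p["subject"]}
            assert not train_subj & test_subj
            assert len(p["train"]) + len(p["test"]) == len(t)

    def test_stratified_folds_preserve_class_ratio(self):
        t = make_table(n_subjects=1, n_per_subject=100, pos_frac=0.3)
        plans = make_splits(t, SplitPlan("stratified_kfold", k=5, seed=0))
        for p in plans:
            y_val = t.iloc[p["validation"]]["fear_label"]
            assert len(y_val) == 20
            assert abs(y_val.sum() - 6) <= 1

    def test_errors(self):
        t = make_table(n_subjects=2)
        with pytest.raises(ValidationError):
            make_splits(t, SplitPlan("loso"))
        t2 = make_table(n_subjects=1, n_per_subject=20, pos_frac=0.1)
        with pytest.raises(ValidationError):
            make_splits(t2, SplitPlan("stratified_kfold", k=5))


class TestMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=50, tn=50, fp=0, fn=0)
        y = np.array([1] * 50 + [0] * 50)
        s = y.astype(float)
        m = compute_metrics(cm, s, y)
        assert (m.acc, m.auc, m.gmean, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_all_negative_predictor_on_imbalanced_truth(self):
        # 100 samples, 5 positives, constant scores: the imbalance pathology
        cm = ConfusionMatrix(tp=0, tn=95, fp=0, fn=5)
        y = np.array([1] * 5 + [0] * 95)
        scores = np.zeros(100)
        m = compute_metrics(cm, scores, y)
        assert m.acc == pytest.approx(0.95)
        assert m.auc == pytest.approx(0.50)
        assert m.gmean == 0.0
        assert m.f1 == 0.0

    def test_auc_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(30), 2)  # coarse scores force ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
            assert auc_score(y, s) == pytest.approx(np.mean(pairs))

    def test_metric_order_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:3] = [0, 1, 1]
        s = rng.random(40)
        perm = rng.permutation(40)
        assert auc_score(y, s) == pytest.approx(auc_score(y[perm], s[perm]))


class TestConfusionReport:
    def test_rates_recomputed_from_counts(self):
        cm = ConfusionMatrix(tp=20, tn=60, fp=10, fn=10)
        rep = confusion_report(cm)
        grid = rep["grid"]
        assert grid[0][:2] == [60, 10]
        assert grid[1][:2] == [10, 20]
        assert grid[0][2] == pytest.approx(10 / 70)  # false omission
        assert grid[1][2] == pytest.approx(20 / 30)  # precision
        assert grid[2][0] == pytest.approx(10 / 30)  # FNR
        assert grid[2][1] == pytest.approx(60 / 70)  # specificity
        assert grid[2][2] == pytest.approx(0.8)

    def test_pathological_accuracy_cell(self):
        rep = confusion_report(ConfusionMatrix(tp=0, tn=95, fp=0, fn=5))
        assert rep["grid"][2][2] == pytest.approx(0.95)


class TestAggregate:
    def test_identical_models_have_zero_mad(self):
        m = MetricSet(0.9, 0.8, 0.7, 0.6)
        agg = aggregate_models([m, m, m])
        assert all(v["mad"] == pytest.approx(0.0, abs=1e-12) for v in agg.values())

    def test_direct_formula(self):
        agg = aggregate_models([MetricSet(0.8, 0.8, 0.8, 0.8), MetricSet(1.0, 1.0, 1.0, 1.0)])
        assert agg["acc"]["mean"] == pytest.approx(0.9)
        assert agg["acc"]["mad"] == pytest.approx(0.1)

    def test_single_model(self):
        agg = aggregate_models([MetricSet(0.7, 0.7, 0.7, 0.7)])
        assert agg["gmean"] == {"mean": pytest.approx(0.7), "mad": 0.0}


class TestSmbo:
    def test_finds_minimum_of_smooth_function(self):
        space = [Real("x", -2.0, 2.0), Real("y", -2.0, 2.0)]
        res = smbo_minimize(lambda p: (p["x"] - 0.5) ** 2 + (p["y"] + 0.3) ** 2, space, n_calls=25, seed=0)
        assert res["best_value"] < 0.05

    def test_deterministic_under_seed(self):
        space = [Real("c", 1e-2, 1e2, log=True), Integer("k", 1, 9), Categorical("m", ("a", "b"))]

        def obj(p):
            return (np.log10(p["c"]) - 1) ** 2 + 0.1 * p["k"] + (0.5 if p["m"] == "b" else 0.0)

        r1 = smbo_minimize(obj, space, n_calls=15, seed=3)
        r2 = smbo_minimize(obj, space, n_calls=15, seed=3)
        assert r1["best_params"] == r2["best_params"]
        assert r1["history"] == r2["history"]


def _blobs(n=60, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 1, (n, 4)) + sep * y[:, None]
    return X, y


class TestTuneAndTrain:
    @pytest.mark.parametrize("algo", ["svm", "knn", "ens"])
    def test_separable_blobs_perfect_validation(self, algo):
        X, y = _blobs()
        model = tune_and_train(X, y, algo, budget=8, seed=0)
        assert model.cv_error == pytest.approx(0.0)
        assert (model.predict(X) == y).all()

    def test_pure_noise_auc_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (120, 6))
        y = np.array([0, 1] * 60)
        model = tune_and_train(X[:80], y[:80], "knn", budget=6, seed=1)
        auc = auc_score(y[80:], model.scores(X[80:]))
        assert 0.3 <= auc <= 0.7

    def test_deterministic_hyperparameters(self):
        X, y = _blobs(seed=2)
        p1 = tune_and_train(X, y, "ens", budget=6, seed=4).params
        p2 = tune_and_train(X, y, "ens", budget=6, seed=4).params
        assert p1 == p2

    def test_single_class_is_error(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValidationError):
            tune_and_train(X, np.zeros(10), "svm")


class TestProtocols:
    def test_subject_dependent_recovers_strong_signal(self):
        t = make_table(n_subjects=2, n_per_subject=50, signal=6.0, seed=3)
        rep = subject_dependent_eval(t, "knn", k=5, budget=5, seed=0)
        assert rep["aggregate"]["gmean"]["mean"] > 0.9
        assert len(rep["per_model"]) == 2

    def test_loso_held_out_subject_cannot_influence_training(self):
        t = make_table(n_subjects=4, n_per_subject=30, signal=3.0, seed=6)
        target = "S03"
        plans = make_splits(t, SplitPlan("loso", held_out_subject=target))
        train_idx = plans[0]["train"]

        def fit(tbl):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z = zscore_by_subject(tbl)
            cols = [f"f{j}" for j in range(6)]
            tr = z.iloc[train_idx]
            return tune_and_train(tr[cols].to_numpy(), tr["fear_label"].to_numpy(), "knn", budget=5, seed=0)

        poisoned = t.copy()
        mask = poisoned.subject_id == target
        poisoned.loc[mask, [f"f{j}" for j in range(6)]] = 1e6

        m_clean, m_poisoned = fit(t), fit(poisoned)
        assert m_clean.params == m_poisoned.params
        probe = np.random.default_rng(0).normal(0, 1, (20, 6))
        np.testing.assert_array_equal(m_clean.predict(probe), m_poisoned.predict(probe))

    def test_label_permutation_null_auc(self):
        t = make_table(n_subjects=3, n_per_subject=40, signal=4.0, seed=7)
        rng = np.random.default_rng(0)
        t = t.copy()
        t["fear_label"] = rng.permutation(t["fear_label"].to_numpy())
        rep = loso_eval(t, "knn", budget=5, seed=0)
        assert abs(rep["aggregate"]["auc"]["mean"] - 0.5) <= 0.15
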