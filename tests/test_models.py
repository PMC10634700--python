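"""Elastic-net LOPO machinery: labels, folds, preprocessing, SMOTE,
fitting, pooled scoring, and linear SHAP."""

import numpy as np
import pandas as pd
import pytest

from spatialtme.models import (
    ModelError,
    TaskSpec,
    balance_train,
    derive_dfs_labels,
    fit_en_model,
    make_folds_lopo,
    preprocess_fold,
    region_labels,
    run_lopo,
    score_pooled,
)


def _patients(dfs):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(dfs))],
            "cohort": "aCD40",
            "dfs_months": dfs,
        }
    ).set_index("patient_id", drop=False)


class TestDfsLabels:
    def test_median_split_tie_goes_short(self):
        out = derive_dfs_labels(_patients([2.0, 9.8, 30.0]))
        assert out["dfs_label"].tolist() == ["short", "short", "long"]

    def test_degenerate_all_equal(self):
        out = derive_dfs_labels(_patients([5.0, 5.0, 5.0]))
        assert (out["dfs_label"] == "short").all()

    def test_missing_dfs_rejected(self):
        with pytest.raises(ValueError, match="P1"):
            derive_dfs_labels(_patients([2.0, np.nan]))


def _regions(n_patients, regions_each, cohort="naive"):
    rows = []
    for p in range(n_patients):
        for r in range(regions_each):
            rows.append(
                {
                    "region_id": f"P{p}_R{r}",
                    "patient_id": f"P{p}",
                    "cohort": cohort,
                    "site": "IA",
                    "area_mm2": 0.5,
                }
            )
    return pd.DataFrame(rows).set_index("region_id", drop=False)


class TestFolds:
    def test_counting_contract(self):
        regions = _regions(3, 2)
        labels = pd.Series(
            ["a", "a", "a", "a", "b", "b"], index=regions.index
        )
        folds = make_folds_lopo(regions, labels)
        assert len(folds) == 3
        for _, test_ids in folds:
            assert len(test_ids) == 2

    def test_single_patient_rejected(self):
        regions = _regions(1, 3)
        labels = pd.Series(["a", "b", "a"], index=regions.index)
        with pytest.raises(ModelError):
            make_folds_lopo(regions, labels)

    def test_single_class_rejected(self):
        regions = _regions(3, 1)
        labels = pd.Series(["a", "a", "a"], index=regions.index)
        with pytest.raises(ModelError, match="one class"):
            make_folds_lopo(regions, labels)

    def test_folds_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n_pat = int(rng.integers(2, 8))
            regions = _regions(n_pat, int(rng.integers(1, 4)))
            labels = pd.Series(
                rng.choice(["a", "b"], len(regions)), index=regions.index
            )
            if labels.nunique() < 2:
                continue
            folds = make_folds_lopo(regions, labels)
            seen = [rid for _, test in folds for rid in test]
            assert sorted(seen) == sorted(regions.index)


class TestPreprocess:
    def _frames(self, train_col, test_col):
        cols = pd.MultiIndex.from_tuples([("density", "X")])
        train = pd.DataFrame({cols[0]: train_col})
        test = pd.DataFrame({cols[0]: test_col})
        return train, test

    def test_log_then_minmax_then_clip(self):
        train, test = self._frames([0.0, 9.0], [99.0])
        strain, stest = preprocess_fold(train, test)
        assert strain.to_numpy().ravel().tolist() == [0.0, 1.0]
        # log10(100) = 2 -> scaled 2 -> clipped to 1
        assert stest.to_numpy().ravel().tolist() == [1.0]

    def test_constant_train_column_maps_to_zero(self):
        train, test = self._frames([5.0, 5.0], [7.0])
        strain, stest = preprocess_fold(train, test)
        assert (strain.to_numpy() == 0).all()
        assert (stest.to_numpy() == 0).all()

    def test_all_zero_column_stays_zero(self):
        train, test = self._frames([0.0, 0.0], [0.0])
        strain, stest = preprocess_fold(train, test)
        assert (strain.to_numpy() == 0).all() and (stest.to_numpy() == 0).all()

    def test_negative_values_rejected(self):
        train, test = self._frames([-1.0, 2.0], [0.0])
        with pytest.raises(ValueError, match="non-negative"):
            preprocess_fold(train, test)


class TestSmote:
    def test_counts_balanced(self):
        rng = np.random.default_rng(0)
        X = rng.random((14, 3))
        y = np.array(["maj"] * 10 + ["min"] * 4)
        Xb, yb = balance_train(X, y, seed=0)
        assert (yb == "maj").sum() == 10 and (yb == "min").sum() == 10
        # original rows are untouched
        np.testing.assert_array_equal(Xb[:14], X)

    def test_synthetic_points_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[5.0, 5.0]] * 10)
        y = np.array(["min", "min"] + ["maj"] * 10)
        Xb, yb = balance_train(X, y, seed=1)
        synth = Xb[12:]
        # with k=1 every synthetic point is a convex combination of the
        # two minority points, i.e. x == y on the segment [0,1]
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_singleton_minority_skipped(self, caplog):
        X = np.random.default_rng(0).random((5, 2))
        y = np.array(["maj"] * 4 + ["min"])
        Xb, yb = balance_train(X, y, seed=0)
        assert len(Xb) == 5

    def test_one_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ModelError):
            balance_train(X, np.array(["a"] * 4), seed=0)


class TestFit:
    def test_constant_features_give_intercept_only(self):
        spec = TaskSpec("treatment", "IA", positive_class="b")
        X = np.zeros((20, 4))
        y = np.array(["a", "b"] * 10)
        model = fit_en_model(X, y, spec)
        assert np.allclose(model.coef_, 0.0)
        prob = model.predict_proba(np.zeros((1, 4)))[0, 1]
        assert prob == pytest.approx(0.5, abs=1e-6)

    def test_separated_data_classified_correctly(self):
        spec = TaskSpec("treatment", "IA", positive_class="b")
        X = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_en_model(X, y, spec)
        assert model.predict_proba([[5.0]])[0, 1] > 0.5
        assert model.predict_proba([[-5.0]])[0, 1] < 0.5

    def test_row_duplication_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 5))
        y = np.array(["a", "b"] * 15)
        spec = TaskSpec("treatment", "IA", positive_class="b")
        m1 = fit_en_model(X, y, spec)
        m2 = fit_en_model(np.vstack([X, X]), np.concatenate([y, y]), spec)
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=5e-4)


class TestScoring:
    def test_confusion_arithmetic(self):
        y_true = np.array(["p"] * 10 + ["n"] * 10)
        y_pred = np.array(["p"] * 8 + ["n"] * 2 + ["n"] * 8 + ["p"] * 2)
        prob = np.linspace(1, 0, 20)
        confusion, metrics = score_pooled(y_true, y_pred, prob, "p")
        assert confusion == {"TP": 8, "FP": 2, "FN": 2, "TN": 8}
        assert metrics["accuracy"] == pytest.approx(0.8)
        assert metrics["f1"] == pytest.approx(0.8)

    def test_perfect_ordering_auc_one(self):
        y = np.array(["p", "p", "n", "n"])
        _, metrics = score_pooled(y, y, np.array([0.9, 0.8, 0.2, 0.1]), "p")
        assert metrics["auc"] == 1.0

    def test_tied_probabilities_auc_half(self):
        y = np.array(["p", "p", "n", "n"])
        _, metrics = score_pooled(y, y, np.full(4, 0.5), "p")
        assert metrics["auc"] == 0.5

    def test_single_class_truth_rejected(self):
        y = np.array(["p", "p"])
        with pytest.raises(ModelError, match="AUC"):
            score_pooled(y, y, np.array([0.5, 0.5]), "p")


class TestLinearShap:
    def test_closed_form_example(self):
        w = np.array([2.0, -1.0])
        mu = np.array([0.5, 0.5])
        x = np.array([1.0, 0.0])
        shap = w * (x - mu)
        np.testing.assert_allclose(shap, [1.0, 0.5])
        assert shap.sum() == pytest.approx((w @ x) - (w @ mu))


@pytest.fixture(scope="module")
def lopo_result(phenotyped_cohort, gating):
    """One real LOPO run on the small synthetic cohort's IA regions."""
    from spatialtme.features import compute_features

    _, cells, regions, patients, _ = phenotyped_cohort
    matrix = compute_features(cells, regions, gating.leaves)
    ia = regions.index[regions["site"] == "IA"]
    labels = region_labels("treatment", regions, patients).loc[ia]
    spec = TaskSpec("treatment", "IA", seed=0)
    return run_lopo(spec, matrix.loc[ia], regions, labels)


class TestLopoRun:
    def test_no_patient_leakage(self, lopo_result, phenotyped_cohort):
        _, _, regions, _, _ = phenotyped_cohort
        patient_of = regions["patient_id"]
        for fold in lopo_result.folds:
            train_patients = {
                patient_of[r]
                for r in lopo_result.pooled["region_id"]
                if r not in set(fold.test_region_ids)
            }
            test_patients = {patient_of[r] for r in fold.test_region_ids}
            assert not (train_patients & test_patients)

    def test_every_region_predicted_once(self, lopo_result):
        pooled = lopo_result.pooled
        assert pooled["region_id"].is_unique

    def test_shap_additivity(self, lopo_result):
        """Per row, sum of SHAP + base value equals the model margin."""
        for fold in lopo_result.folds:
            margin = fold.test_X.to_numpy() @ fold.coef + fold.intercept
            total = fold.shap.to_numpy().sum(axis=1) + fold.base_value
            np.testing.assert_allclose(total, margin, atol=1e-6)

    def test_zero_coefficient_features_have_zero_importance(self, lopo_result):
        all_zero = np.all(
            np.vstack([f.coef for f in lopo_result.folds]) == 0.0, axis=0
        )
        imp = lopo_result.importance.to_numpy()
        assert np.allclose(imp[all_zero], 0.0)

    def test_metrics_in_unit_interval(self, lopo_result):
        for v in lopo_result.metrics.values():
            assert 0.0 <= v <= 1.0


def test_dfs_task_excludes_nap():
    with pytest.raises(ValueError, match="NAP"):
        TaskSpec("dfs", "NAP")
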