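"""Recurrent cellular neighborhoods: compositions, elbow, K-means,
residency, and functional fractions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spatialtme.rcn import (
    RCNModel,
    barcode_rcn_residency,
    elbow_k,
    fit_rcn,
    functional_fraction_by_rcn,
    neighborhood_composition,
    rcn_summaries,
)

TAXONOMY = ["A", "B", "C"]


def _cells(rows):
    return pd.DataFrame(
        rows, columns=["cell_id", "region_id", "x_um", "y_um", "state"]
    )


class TestComposition:
    def test_radius_rule(self):
        cells = _cells(
            [("s", "R1", 0, 0, "A"), ("n1", "R1", 0, 50, "A"), ("n2", "R1", 0, 70, "B")]
        )
        comp = neighborhood_composition(cells, TAXONOMY, radius_um=60)
        assert comp.loc["s", "A"] == 1.0
        assert comp.loc["s", "B"] == 0.0
        assert comp.loc["s", "n_neighbors"] == 2

    def test_isolated_cell_one_hot_on_own_state(self):
        cells = _cells([("s", "R1", 0, 0, "B")])
        comp = neighborhood_composition(cells, TAXONOMY)
        assert comp.loc["s", "B"] == 1.0
        assert comp.loc["s", "n_neighbors"] == 1

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        n = 150
        cells = _cells(
            [
                (f"c{i}", "R1", x, y, s)
                for i, (x, y, s) in enumerate(
                    zip(
                        rng.uniform(0, 400, n),
                        rng.uniform(0, 400, n),
                        rng.choice(TAXONOMY, n),
                    )
                )
            ]
        )
        comp = neighborhood_composition(cells, TAXONOMY)
        np.testing.assert_allclose(comp[TAXONOMY].sum(axis=1), 1.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        n = 120
        xy = rng.uniform(0, 300, (n, 2))
        states = rng.choice(TAXONOMY, n)
        cells = _cells(
            [(f"c{i}", "R1", xy[i, 0], xy[i, 1], states[i]) for i in range(n)]
        )
        comp = neighborhood_composition(cells, TAXONOMY, radius_um=60)
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        for i in range(n):
            members = np.flatnonzero(d2[i] <= 60.0**2)
            assert comp.iloc[i]["n_neighbors"] == len(members)
            for j, s in enumerate(TAXONOMY):
                assert comp.iloc[i][s] == pytest.approx(
                    (states[members] == s).mean()
                )


class TestElbow:
    def test_worked_sequence(self):
        curve = pd.Series([100, 40, 20, 15, 13, 12], index=range(2, 8))
        assert elbow_k(curve) == 4

    def test_linear_decay_ties_to_smallest(self):
        curve = pd.Series(np.linspace(100, 10, 6), index=range(2, 8))
        assert elbow_k(curve) == 2

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            elbow_k(pd.Series([10, 5], index=[2, 3]))

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            elbow_k(pd.Series([10, 12, 5], index=[2, 3, 4]))


def _archetype_compositions(n_per=100, noise=0.03, seed=0):
    rng = np.random.default_rng(seed)
    a = np.array([0.9, 0.05, 0.05])
    b = np.array([0.05, 0.05, 0.9])
    rows, labels = [], []
    for arch, lab in ((a, 0), (b, 1)):
        for _ in range(n_per):
            v = np.abs(arch + rng.normal(0, noise, 3))
            rows.append(v / v.sum())
            labels.append(lab)
    comp = pd.DataFrame(rows, columns=TAXONOMY)
    comp.index = [f"c{i}" for i in range(len(comp))]
    comp["n_neighbors"] = 10
    return comp, np.array(labels)


class TestFitRcn:
    def test_two_archetypes_recovered(self):
        comp, truth = _archetype_compositions()
        model = fit_rcn(comp, TAXONOMY, k_range=range(2, 6), seed=0)
        assert adjusted_rand_score(truth, model.assignments.to_numpy()) >= 0.8

    def test_identical_compositions_fall_back_to_one(self, caplog):
        comp = pd.DataFrame(
            np.tile([0.5, 0.25, 0.25], (30, 1)), columns=TAXONOMY
        )
        comp.index = [f"c{i}" for i in range(30)]
        model = fit_rcn(comp, TAXONOMY, k_range=range(2, 6), seed=0)
        assert model.k == 1
        assert (model.assignments == 1).all()

    def test_determinism(self):
        comp, _ = _archetype_compositions(seed=3)
        m1 = fit_rcn(comp, TAXONOMY, k_range=range(2, 6), seed=7)
        m2 = fit_rcn(comp, TAXONOMY, k_range=range(2, 6), seed=7)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)

    def test_inertia_non_increasing(self):
        comp, _ = _archetype_compositions(seed=4)
        model = fit_rcn(comp, TAXONOMY, k_range=range(2, 7), seed=0)
        assert (np.diff(model.inertia_curve.to_numpy()) <= 1e-9).all()

    def test_labels_sorted_by_size(self):
        comp, truth = _archetype_compositions(n_per=60, seed=5)
        comp2 = pd.concat([comp, comp.iloc[:20]])  # make cluster sizes unequal
        comp2.index = [f"c{i}" for i in range(len(comp2))]
        model = fit_rcn(comp2, TAXONOMY, k_range=range(2, 6), seed=0)
        sizes = model.assignments.value_counts()
        assert list(sizes.index) == sorted(sizes.index)
        assert (sizes.sort_index(ascending=True).diff().dropna() <= 0).all()


class TestSummaries:
    def _fixture(self):
        comp, truth = _archetype_compositions(n_per=50, seed=6)
        model = fit_rcn(comp, TAXONOMY, k_range=range(2, 6), seed=0)
        cells = pd.DataFrame(
            {
                "cell_id": comp.index,
                "region_id": ["R1"] * 50 + ["R2"] * 50,
            }
        )
        regions = pd.DataFrame(
            {
                "region_id": ["R1", "R2"],
                "patient_id": ["P1", "P2"],
                "cohort": ["aCD40", "aCD40"],
                "site": ["IA", "IA"],
                "area_mm2": [0.5, 0.5],
            }
        ).set_index("region_id", drop=False)
        return model, cells, regions, truth

    def test_mean_compositions_near_archetypes(self):
        model, cells, regions, _ = self._fixture()
        out = rcn_summaries(model, cells, regions)
        mean = out["mean_composition"]
        np.testing.assert_allclose(mean.sum(axis=1), 1.0, atol=1e-9)
        archetypes = np.array([[0.9, 0.05, 0.05], [0.05, 0.05, 0.9]])
        for arch in archetypes:
            l1 = np.abs(mean.to_numpy() - arch).sum(axis=1).min()
            assert l1 <= 0.05

    def test_region_proportions_rows_sum_to_one(self):
        model, cells, regions, _ = self._fixture()
        out = rcn_summaries(model, cells, regions)
        np.testing.assert_allclose(
            out["region_proportions"].sum(axis=1), 1.0
        )

    def test_single_rcn_proportions_all_one(self):
        comp = pd.DataFrame(np.tile([1.0, 0, 0], (20, 1)), columns=TAXONOMY)
        comp.index = [f"c{i}" for i in range(20)]
        model = fit_rcn(comp, TAXONOMY, k_range=range(2, 6), seed=0)
        cells = pd.DataFrame({"cell_id": comp.index, "region_id": "R1"})
        regions = pd.DataFrame(
            {"region_id": ["R1"], "patient_id": ["P1"], "cohort": ["aCD40"],
             "site": ["IA"], "area_mm2": [0.5]}
        ).set_index("region_id", drop=False)
        out = rcn_summaries(model, cells, regions)
        assert (out["region_proportions"].to_numpy() == 1.0).all()


def _residency_fixture():
    """Two planted residency archetypes over 2 RCNs."""
    assignments = pd.Series(
        [1] * 40 + [2] * 40, index=[f"c{i}" for i in range(80)]
    )
    centroids = pd.DataFrame(
        [[1.0, 0, 0], [0, 0, 1.0]], index=[1, 2], columns=TAXONOMY
    )
    model = RCNModel(60.0, 2, centroids, assignments, pd.Series(dtype=float),
                     pd.DataFrame())
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(80)],
            "region_id": "R1",
            # barcodes bA/bB live in RCN1; bC/bD in RCN2
            "barcode": ["bA"] * 20 + ["bB"] * 20 + ["bC"] * 20 + ["bD"] * 20,
            "state": "T",
        }
    )
    regions = pd.DataFrame(
        {"region_id": ["R1"], "patient_id": ["P1"], "cohort": ["aCD40"],
         "site": ["IA"], "area_mm2": [0.5]}
    ).set_index("region_id", drop=False)
    patients = pd.DataFrame(
        {"patient_id": ["P1"], "cohort": ["aCD40"], "dfs_label": ["long"]}
    ).set_index("patient_id", drop=False)
    return model, cells, regions, patients


class TestResidency:
    def test_one_hot_rows_and_sums(self):
        model, cells, regions, patients = _residency_fixture()
        out = barcode_rcn_residency(
            [("bA", "long"), ("bC", "long")], cells, regions, patients, model
        )
        res = out["residency"]
        np.testing.assert_allclose(res.sum(axis=1), 1.0)
        assert res.loc[("long", "bA"), "RCN1"] == 1.0
        assert res.loc[("long", "bC"), "RCN2"] == 1.0

    def test_planted_archetypes_recovered(self):
        model, cells, regions, patients = _residency_fixture()
        out = barcode_rcn_residency(
            [("bA", "long"), ("bB", "long"), ("bC", "long"), ("bD", "long")],
            cells, regions, patients, model,
        )
        clusters = out["clusters"]
        truth = [0, 0, 1, 1]
        assert adjusted_rand_score(truth, clusters.to_numpy()) == 1.0

    def test_out_of_scope_barcode_dropped(self, caplog):
        model, cells, regions, patients = _residency_fixture()
        out = barcode_rcn_residency(
            [("bA", "long"), ("zzz", "long")], cells, regions, patients, model
        )
        assert len(out["residency"]) == 1


class TestFunctionalFractions:
    def _fixture(self):
        model, cells, regions, patients = _residency_fixture()
        cells = cells.copy()
        cells["state"] = ["T_EFF"] * 60 + ["mT_REG"] * 20
        cells["KI67"] = [True, False] * 40
        cells["GRZB"] = [True] * 10 + [False] * 70
        return model, cells

    def test_counting(self):
        model, cells = self._fixture()
        out = functional_fraction_by_rcn(
            cells, model, "KI67", ["T_EFF", "mT_REG"], ["mT_REG"]
        )
        assert out.loc[1, "fraction"] == pytest.approx(0.5)
        assert out.loc[1, "n_t_cells"] == 40

    def test_treg_exclusion(self):
        model, cells = self._fixture()
        out = functional_fraction_by_rcn(
            cells, model, "GRZB", ["T_EFF", "mT_REG"], ["mT_REG"],
            exclude_treg=True,
        )
        assert out["n_t_cells"].sum() == 60  # regulatory cells removed

    def test_empty_rcn_reported_missing(self):
        model, cells = self._fixture()
        out = functional_fraction_by_rcn(
            cells.iloc[:40], model, "KI67", ["T_EFF"], []
        )
        assert out.loc[2, "n_t_cells"] == 0
        assert np.isnan(out.loc[2, "fraction"])

    def test_conservation_identity(self):
        model, cells = self._fixture()
        out = functional_fraction_by_rcn(
            cells, model, "KI67", ["T_EFF", "mT_REG"], ["mT_REG"]
        )
        recon = (out["fraction"].fillna(0) * out["n_t_cells"]).sum()
        assert recon == pytest.approx(cells["KI67"].sum())
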