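"""Module scoring, score comparisons, featured genes, bulk panel scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import crpcpanel as cp
from crpcpanel.normalize import NormMatrix
from conftest import make_annotation


def _z(df_dict, cells):
    return pd.DataFrame(df_dict, index=cells).T


class TestModuleScore:
    def test_sum_of_z_values(self):
        z = pd.DataFrame({"c1": [0.5, -0.5, 2.0]}, index=["a", "b", "c"])
        ms = cp.module_score(z, cp.GeneSet("s", ["a", "b", "c"]))
        assert ms.scores["c1"] == pytest.approx(2.0)

    def test_missing_genes_skipped_and_reported(self):
        z = pd.DataFrame({"c1": [1.0]}, index=["a"])
        ms = cp.module_score(z, cp.GeneSet("s", ["a", "zzz"]))
        assert ms.genes_used == ["a"]
        assert ms.genes_missing == ["zzz"]
        assert ms.scores["c1"] == 1.0

    def test_zero_overlap_fatal_names_set(self):
        z = pd.DataFrame({"c1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="nope"):
            cp.module_score(z, cp.GeneSet("nope", ["x", "y"]))

    def test_cancellation_gives_zero(self):
        z = pd.DataFrame({"c1": [1.5, -1.5], "c2": [-0.2, 0.2]}, index=["gA", "gB"])
        ms = cp.module_score(z, cp.GeneSet("s", ["gA", "gB"]))
        assert (ms.scores == 0).all()

    def test_linearity_over_disjoint_sets(self, sc_sim):
        cm, _, _ = sc_sim
        z = cp.zscore_by_gene(cp.log2cpm(cm))
        genes = list(z.index[:40])
        s1, s2 = cp.GeneSet("a", genes[:17]), cp.GeneSet("b", genes[17:])
        union = s1.union(s2)
        total = cp.module_score(z, union).scores
        parts = cp.module_score(z, s1).scores + cp.module_score(z, s2).scores
        np.testing.assert_allclose(total, parts, atol=1e-10)


class TestCompareScores:
    def test_identical_groups_null(self):
        s = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        res = cp.compare_scores(s, ["a", "b", "c"], ["d", "e", "f"])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_welch_worked_example(self):
        s = pd.Series([1, 2, 3, 4, 5, 6], dtype=float, index=list("abcdef"))
        res = cp.compare_scores(s, ["a", "b", "c"], ["d", "e", "f"])
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.p == pytest.approx(0.0214, abs=1e-3)
        assert res.stars == "*"

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=12)
        s1 = pd.Series(vals, index=[f"u{i}" for i in range(12)])
        s2 = s1 + 100.0
        a, b = [f"u{i}" for i in range(6)], [f"u{i}" for i in range(6, 12)]
        r1, r2 = cp.compare_scores(s1, a, b), cp.compare_scores(s2, a, b)
        assert r1.t == pytest.approx(r2.t, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-10)

    def test_matches_reference_welch(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 20))
            b = rng.normal(scale=2.0, size=rng.integers(3, 20))
            s = pd.Series(np.concatenate([a, b]),
                          index=[f"u{i}" for i in range(len(a) + len(b))])
            res = cp.compare_scores(s, s.index[:len(a)], s.index[len(a):])
            t_ref, p_ref = scipy.stats.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_variance_flagged(self, caplog):
        s = pd.Series([1.0, 1.0, 2.0, 2.0], index=list("abcd"))
        with caplog.at_level("WARNING"):
            res = cp.compare_scores(s, ["a", "b"], ["c", "d"])
        assert res.p == 1.0


class TestFeaturedGenes:
    def _toy_norm(self):
        # gene g expressed only in B (3 of 5 cells); filler genes keep BH company
        cells = ([f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
                 + [f"C{i}" for i in range(5)])
        rng = np.random.default_rng(0)
        vals = np.vstack([
            [0] * 5 + [2, 2, 2, 0, 0] + [0] * 5,
            rng.uniform(0.5, 1.5, 15),  # noisy fillers, no real structure
            rng.uniform(0.5, 1.5, 15),
            np.full(15, 1.0),  # constant
        ]).astype(float)
        norm = NormMatrix(["g", "f1", "f2", "const"], cells, vals)
        ann = make_annotation({"A": 5, "B": 5, "C": 5})
        return norm, ann

    def test_toy_marker_called_for_argmax_subgroup(self):
        norm, ann = self._toy_norm()
        calls = cp.featured_genes(norm, ann)
        g = calls[calls.gene == "g"]
        assert len(g) == 1
        assert g.iloc[0].subgroup == "B"
        assert g.iloc[0].expressed_fraction == pytest.approx(0.6)

    def test_fraction_filter_blocks_rare_gene(self):
        cells = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
        vals = np.zeros((2, 20))
        vals[0, 10] = 50.0  # huge in 1 of 10 B cells -> fraction 0.10
        vals[1] = np.linspace(0.1, 2.0, 20)
        norm = NormMatrix(["rare", "f"], cells, vals)
        ann = make_annotation({"A": 10, "B": 10})
        calls = cp.featured_genes(norm, ann)
        assert "rare" not in set(calls.gene)

    def test_constant_gene_never_called(self):
        norm, ann = self._toy_norm()
        calls = cp.featured_genes(norm, ann)
        assert "const" not in set(calls.gene)

    def test_each_gene_featured_at_most_once(self, sc_sim):
        cm, ann, _ = sc_sim
        calls = cp.featured_genes(cp.log2cpm(cm), ann)
        assert calls.gene.is_unique

    def test_recovers_planted_markers_single_seed(self, sc_sim):
        cm, ann, truth = sc_sim
        calls = cp.featured_genes(cp.log2cpm(cm), ann)
        markers = truth[truth.role == "marker"]
        recovered = set(calls.gene) & set(markers.gene)
        assert len(recovered) / len(markers) >= 0.9
        # calls map markers to their home subgroup
        home = dict(zip(markers.gene, markers.subgroup))
        for _, row in calls[calls.gene.isin(recovered)].iterrows():
            assert row.subgroup == home[row.gene]


class TestPanelScoreBulk:
    def test_twelve_equals_six_plus_added_six(self):
        extra = cp.GeneSet("added6", [g for g in cp.PANEL_12.genes
                                      if g not in cp.PANEL_6.genes])
        cohort12, _ = cp.simulate_bulk(cp.BulkSimConfig(seed=5, panel=cp.PANEL_12))
        a = cp.panel_score_bulk(cohort12, cp.PANEL_12).scores
        b = (cp.panel_score_bulk(cohort12, cp.PANEL_6).scores
             + cp.panel_score_bulk(cohort12, extra).scores)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_identical_samples_score_zero(self):
        expr = np.tile(np.array([[3.0], [7.0]]), (1, 5))
        pheno = pd.DataFrame(
            {"sample_type": "Primary Tumor", "recurrence": None,
             "therapy_type": None, "recurrence_time_days": np.nan},
            index=[f"s{i}" for i in range(5)])
        cohort = cp.BulkCohort(["PEG10", "AR"], list(pheno.index), expr, pheno)
        ms = cp.panel_score_bulk(cohort, cp.GeneSet("p", ["PEG10", "AR"]))
        assert (ms.scores == 0).all()

    def test_gene_order_and_affine_invariance(self, bulk_sim):
        cohort, _ = bulk_sim
        shuffled = cp.GeneSet("p6r", list(reversed(cp.PANEL_6.genes)))
        a = cp.panel_score_bulk(cohort, cp.PANEL_6).scores
        b = cp.panel_score_bulk(cohort, shuffled).scores
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_planted_shift_raises_positive_group_scores(self, bulk_sim):
        cohort, truth = bulk_sim
        scores = cp.panel_score_bulk(cohort, cp.PANEL_6).scores
        ht_rec = truth.index[truth.group == "HT_rec"]
        ht_norec = truth.index[truth.group == "HT_norec"]
        assert scores[ht_rec].mean() > scores[ht_norec].mean()
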