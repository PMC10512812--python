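"""Normalization primitives: CPM/log transform, z-scores, composition,
subgroup profiles and their Pearson similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crpcpanel as cp
from crpcpanel.normalize import NormMatrix
from conftest import make_annotation


def _cm(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    return cp.CountMatrix(genes, cells, counts)


class TestLog2CPM:
    def test_direct_arithmetic(self):
        nm = cp.log2cpm(_cm([[9], [1]]))
        assert nm.values[:, 0] == pytest.approx(
            [np.log2(9e5 + 1), np.log2(1e5 + 1)], abs=1e-3)

    def test_zero_count_maps_to_exact_zero(self):
        nm = cp.log2cpm(_cm([[0], [5]]))
        assert nm.values[0, 0] == 0.0

    def test_scale_invariance_under_count_doubling(self):
        a = cp.log2cpm(_cm([[3], [7]])).values
        b = cp.log2cpm(_cm([[6], [14]])).values
        np.testing.assert_allclose(a, b)

    def test_zero_total_cell_fatal_naming_cell(self):
        with pytest.raises(ValueError, match="c1"):
            cp.log2cpm(_cm([[1, 0], [2, 0]]))

    def test_cpm_column_sums_exactly_one_million(self, sc_sim):
        cm, _, _ = sc_sim
        sums = cp.normalize.cpm(cm).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-6)


class TestZScore:
    def test_closed_form(self):
        nm = NormMatrix(["g"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        z = cp.zscore_by_gene(nm)
        np.testing.assert_allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_gene_maps_to_zero(self):
        nm = NormMatrix(["g"], ["a", "b", "c"], np.array([[5.0, 5.0, 5.0]]))
        assert (cp.zscore_by_gene(nm).to_numpy() == 0).all()

    def test_mean_zero_unit_sample_sd(self, sc_sim):
        cm, _, _ = sc_sim
        z = cp.zscore_by_gene(cp.log2cpm(cm)).to_numpy()
        varying = z.std(axis=1) > 0
        np.testing.assert_allclose(z[varying].mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(z[varying].std(axis=1, ddof=1), 1, atol=1e-10)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-20, 20))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_positive_affine_rescaling(self, scale, shift):
        vals = np.array([[0.0, 1.0, 3.0, 7.0]])
        base = cp.zscore_by_gene(NormMatrix(["g"], list("abcd"), vals))
        rescaled = vals * scale + max(0.0, shift)  # keep non-negative
        other = cp.zscore_by_gene(NormMatrix(["g"], list("abcd"), rescaled))
        np.testing.assert_allclose(base.to_numpy(), other.to_numpy(), atol=1e-9)

    def test_single_cell_stratum_fatal(self):
        nm = NormMatrix(["g"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        within = pd.Series({"a": "d1", "b": "d1", "c": "d2"})
        with pytest.raises(ValueError, match="stratum"):
            cp.zscore_by_gene(nm, within=within)

    def test_per_stratum_scaling_is_blockwise(self):
        nm = NormMatrix(["g"], list("abcd"), np.array([[1.0, 3.0, 10.0, 30.0]]))
        within = pd.Series({"a": "d1", "b": "d1", "c": "d2", "d": "d2"})
        z = cp.zscore_by_gene(nm, within=within).to_numpy().ravel()
        np.testing.assert_allclose(z, [-2 ** -0.5, 2 ** -0.5] * 2)


class TestComposition:
    @pytest.mark.parametrize("counts,expected", [
        ({"basal": 633, "luminal": 18965, "cycling": 422},
         {"basal": 3.16, "luminal": 94.73, "cycling": 2.11}),
        ({"basal": 1668, "luminal": 10918, "neuroendocrine": 467},
         {"basal": 12.78, "luminal": 83.64, "neuroendocrine": 3.58}),
    ])
    def test_printed_percentages(self, counts, expected):
        ann = make_annotation(counts)
        table = cp.composition(ann, "D", "epithelial")
        got = dict(zip(table.subgroup, table.percent))
        assert got == expected

    def test_single_subgroup_is_100(self):
        table = cp.composition(make_annotation({"only": 7}), "D", "epithelial")
        assert list(table.percent) == [100.00]

    def test_percentages_sum_to_100_within_rounding(self):
        table = cp.composition(make_annotation({"a": 3, "b": 5, "c": 11}), "D", "epithelial")
        assert sum(table.percent) == pytest.approx(100, abs=0.02)

    def test_empty_selection_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            table = cp.composition(make_annotation({"a": 3}), "other", "epithelial")
        assert len(table) == 0


class TestProfilesAndSimilarity:
    def test_single_cell_subgroup_profile_equals_cell(self):
        nm = NormMatrix(["g1", "g2"], ["a0", "b0", "b1"],
                        np.array([[1.0, 0.0, 2.0], [4.0, 2.0, 0.0]]))
        ann = make_annotation({"a": 1, "b": 2})
        prof = cp.subgroup_mean_profiles(nm, ann)
        np.testing.assert_allclose(prof.loc["a"], [1.0, 4.0])
        np.testing.assert_allclose(prof.loc["b"], [1.0, 1.0])

    def test_profiles_invariant_to_cell_order(self, sc_sim):
        cm, ann, _ = sc_sim
        nm = cp.log2cpm(cm)
        perm = np.random.default_rng(0).permutation(nm.values.shape[1])
        shuffled = NormMatrix(nm.gene_ids, [nm.cell_ids[i] for i in perm], nm.values[:, perm])
        a = cp.subgroup_mean_profiles(nm, ann)
        b = cp.subgroup_mean_profiles(shuffled, ann)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [6, 4, 2], -1.0),
        ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
    ])
    def test_pearson_values(self, x, y, expected):
        prof = pd.DataFrame([x, y], index=["p", "q"], dtype=float)
        sim = cp.similarity_matrix(prof)
        assert sim.loc["p", "q"] == pytest.approx(expected, abs=1e-12)
        assert sim.loc["p", "p"] == 1.0
        assert sim.loc["q", "p"] == sim.loc["p", "q"]

    def test_constant_profile_reported_missing_not_zero(self):
        prof = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["p", "q"], dtype=float)
        sim = cp.similarity_matrix(prof)
        assert np.isnan(sim.loc["p", "q"])
        assert np.isnan(sim.loc["q", "q"])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(42)
        prof = pd.DataFrame(rng.normal(size=(5, 50)),
                            index=[f"s{i}" for i in range(5)])
        sim = cp.similarity_matrix(prof)
        for i in prof.index:
            for j in prof.index:
                xi, xj = prof.loc[i].to_numpy(), prof.loc[j].to_numpy()
                r = (np.sum((xi - xi.mean()) * (xj - xj.mean()))
                     / np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2)))
                assert sim.loc[i, j] == pytest.approx(r, abs=1e-12)
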