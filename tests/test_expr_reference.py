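import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methatlas.expr_reference import (
    ExpressionReferenceBuilder,
    assign_marker_targets,
    build_expression_reference,
    rank_markers,
    validate_reference_on_cells,
)
from methatlas.synthetic import simulate_sc_counts


def brute_force_u(x, y):
    """Mann-Whitney U by exhaustive pair enumeration: #(x > y) + ties/2."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def toy_sc(matrix, types):
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    cells = [f"c{i}" for i in range(matrix.shape[1])]
    sc = pd.DataFrame(matrix, index=genes, columns=cells)
    labels = pd.Series(types, index=cells)
    return sc, labels


class TestRankMarkers:
    def test_planted_marker_attains_maximal_specificity(self):
        # gene expressed only in type A out of K = 4 types -> MSS = 3
        mat = np.zeros((1, 8))
        mat[0, :2] = [5, 7]
        sc, labels = toy_sc(mat, ["A", "A", "B", "B", "C", "C", "D", "D"])
        table = rank_markers(sc, labels, mss_min=0, fdr=1.0)
        row = table[(table.gene == "g0") & (table.cell_type == "A")].iloc[0]
        assert row.mss == 3
        assert row.median_target == 6

    def test_uniformly_expressed_gene_has_zero_mss_and_is_not_selected(self):
        mat = np.full((1, 8), 3.0)
        sc, labels = toy_sc(mat, ["A", "A", "B", "B", "C", "C", "D", "D"])
        table = rank_markers(sc, labels, mss_min=1, fdr=0.05)
        assert (table.mss == 0).all()
        assert not table.selected.any()

    def test_wilcoxon_u_matches_pair_enumeration_on_toy(self):
        # the asymptotic test in the pipeline must agree with the U obtained
        # by exhaustively counting (target > rest) pairs with half ties
        x = np.array([5.0, 3.0, 3.0, 0.0])
        y = np.array([1.0, 3.0])
        u_expected = brute_force_u(x, y)
        res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert res.statistic == pytest.approx(u_expected)

    def test_mss_invariant_under_monotone_rescaling(self, small_cfg):
        sc, labels, _ = simulate_sc_counts(small_cfg)
        t1 = rank_markers(sc, labels, mss_min=0, fdr=1.0)
        t2 = rank_markers(np.sqrt(sc), labels, mss_min=0, fdr=1.0)
        pd.testing.assert_series_equal(t1.mss, t2.mss)

    def test_small_cell_type_errors_naming_the_type(self):
        mat = np.ones((2, 3))
        sc, labels = toy_sc(mat, ["A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            rank_markers(sc, labels)

    def test_marker_recovery_on_planted_simulation(self, small_cfg):
        sc, labels, truth = simulate_sc_counts(small_cfg)
        table = rank_markers(sc, labels)
        selected = set(assign_marker_targets(table).gene)
        planted = set(truth.index)
        recovered = len(selected & planted) / len(planted)
        false_admit = len(selected - planted) / small_cfg.n_background_genes
        assert recovered >= 0.95
        assert false_admit <= 0.01


class TestBuildReference:
    def test_median_over_cells(self):
        mat = np.array([[0.0, 0.0, 5.0, 0.0, 0.0, 0.0]])
        sc, labels = toy_sc(mat, ["A", "A", "A", "B", "B", "B"])
        markers = pd.DataFrame(
            {"gene": ["g0"], "cell_type": ["A"], "mss": [1], "selected": [True],
             "median_target": [0.0], "p": [0.01], "fdr": [0.01]}
        )
        with pytest.warns(UserWarning, match="recommended"):
            ref = build_expression_reference(sc, labels, markers)
        assert ref.values.loc["g0", "A"] == 0.0

    def test_block_structure_recovered_from_simulation(self, small_cfg):
        sc, labels, truth = simulate_sc_counts(small_cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            builder = ExpressionReferenceBuilder().fit(sc, labels)
        ref = builder.reference_
        for g in ref.values.index:
            if g not in truth.index:
                continue
            own = truth[g]
            assert ref.values.loc[g, own] > 0
            others = [c for c in ref.values.columns if c != own]
            assert (ref.values.loc[g, others] == 0).all()

    def test_absent_marker_gene_errors(self):
        mat = np.ones((1, 4))
        sc, labels = toy_sc(mat, ["A", "A", "B", "B"])
        markers = pd.DataFrame(
            {"gene": ["missing"], "cell_type": ["A"], "mss": [1],
             "selected": [True], "median_target": [1.0], "p": [0.01], "fdr": [0.01]}
        )
        with pytest.raises(ValueError, match="missing"):
            build_expression_reference(sc, labels, markers)

    def test_few_markers_warn_not_error(self, small_cfg):
        sc, labels, _ = simulate_sc_counts(small_cfg)
        table = rank_markers(sc, labels)
        with pytest.warns(UserWarning, match="recommended"):
            build_expression_reference(sc, labels, table)


class TestValidation:
    def _reference(self, small_cfg):
        sc, labels, _ = simulate_sc_counts(small_cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return ExpressionReferenceBuilder().fit(sc, labels).reference_

    def test_noiseless_self_profiles_are_perfectly_assigned(self, small_cfg):
        ref = self._reference(small_cfg)
        cells = pd.DataFrame(
            np.repeat(ref.values.to_numpy(), 3, axis=1),
            index=ref.values.index,
            columns=[f"v{i}" for i in range(3 * ref.values.shape[1])],
        )
        labels = pd.Series(np.repeat(ref.values.columns, 3), index=cells.columns)
        res = validate_reference_on_cells(cells, labels, ref)
        assert res["accuracy"] == 1.0

    def test_noisy_cells_accuracy_above_ninety_percent(self, small_cfg):
        ref = self._reference(small_cfg)
        rng = np.random.default_rng(11)
        n_cells = 500
        types = rng.choice(ref.values.columns, size=n_cells)
        base = ref.values[types].to_numpy()
        noisy = base * rng.lognormal(0.0, 0.3, size=base.shape)
        cells = pd.DataFrame(
            noisy, index=ref.values.index, columns=[f"v{i}" for i in range(n_cells)]
        )
        labels = pd.Series(types, index=cells.columns)
        res = validate_reference_on_cells(cells, labels, ref)
        assert res["accuracy"] > 0.9
        # confusion rows count every cell of the type
        counts = labels.value_counts()
        for t in res["confusion"].index:
            assert res["confusion"].loc[t].sum() == counts[t]

    def test_unrepresented_type_still_gets_an_argmax(self, small_cfg):
        ref = self._reference(small_cfg)
        cells = pd.DataFrame(
            rngvals := np.full((len(ref.values), 2), 1.0),
            index=ref.values.index,
            columns=["x1", "x2"],
        )
        labels = pd.Series(["UNSEEN", "UNSEEN"], index=cells.columns)
        res = validate_reference_on_cells(cells, labels, ref)
        assert res["fractions"].shape == (2, ref.values.shape[1])
        assert res["accuracy"] == 0.0

    def test_no_overlap_errors(self, small_cfg):
        ref = self._reference(small_cfg)
        cells = pd.DataFrame(np.ones((3, 2)), index=["x", "y", "z"], columns=["a", "b"])
        labels = pd.Series(["A", "B"], index=["a", "b"])
        with pytest.raises(ValueError, match="markers"):
            validate_reference_on_cells(cells, labels, ref)
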