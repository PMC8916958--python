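import warnings
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from methatlas.containers import DNAmReference, SingleNucleusMethylome
from methatlas.snm import (
    SnmReferenceBuilder,
    aggregate_nucleus_promoters,
    compare_references,
    derive_snm_reference,
    marker_hypomethylation_test,
)
from methatlas.synthetic import SimulationConfig, planted_dnam_reference, simulate_snm


def make_snm(records, labels):
    calls = pd.DataFrame(records, columns=["site_id", "nucleus_id", "call"])
    return SingleNucleusMethylome(calls=calls, labels=pd.Series(labels))


class TestAggregate:
    def test_mean_of_covered_calls(self):
        snm = make_snm(
            [("s1", "n1", 1), ("s2", "n1", 0)] + [(f"s{i%2+1}", f"n{i}", 0) for i in range(2, 7)],
            {f"n{i}": "A" for i in range(1, 7)},
        )
        cpg_map = pd.DataFrame({"site_id": ["s1", "s2"], "gene": ["G", "G"]})
        mat = aggregate_nucleus_promoters(snm, cpg_map, min_nuclei=1)
        assert mat.loc["G", "n1"] == pytest.approx(0.5)

    def test_low_coverage_cpg_dropped(self):
        # CpG covered in 4 nuclei at min_nuclei=5 is excluded entirely
        records = [("s1", f"n{i}", 1) for i in range(4)]
        records += [("s2", f"n{i}", 0) for i in range(5)]
        snm = make_snm(records, {f"n{i}": "A" for i in range(5)})
        cpg_map = pd.DataFrame({"site_id": ["s1", "s2"], "gene": ["G1", "G2"]})
        mat = aggregate_nucleus_promoters(snm, cpg_map, min_nuclei=5)
        assert "G1" not in mat.index
        assert "G2" in mat.index

    def test_empty_map_errors(self):
        snm = make_snm([("s1", "n1", 1)], {"n1": "A"})
        with pytest.raises(ValueError, match="empty"):
            aggregate_nucleus_promoters(snm, pd.DataFrame(columns=["site_id", "gene"]))

    def test_sparse_simulation_means_within_binomial_error(self, small_cfg, small_reference):
        snm, cpg_map = simulate_snm(small_reference, small_cfg)
        mat = aggregate_nucleus_promoters(snm, cpg_map)
        labels = snm.labels
        for t in small_reference.values.columns[:2]:
            genes = small_reference.values.index[:5]
            obs = mat.loc[genes, labels[labels == t].index].mean(axis=1)
            exp = small_reference.values.loc[genes, t]
            # ~80 nuclei/type x ~0.3 covered genes -> generous 3-sigma band
            assert (obs - exp).abs().max() < 0.15

    def test_values_in_unit_interval_and_cpg_order_invariance(self, small_cfg, small_reference):
        snm, cpg_map = simulate_snm(small_reference, small_cfg)
        mat = aggregate_nucleus_promoters(snm, cpg_map)
        arr = mat.to_numpy()
        ok = arr[~np.isnan(arr)]
        assert ((ok >= 0) & (ok <= 1)).all()
        shuffled = snm.calls.sample(frac=1.0, random_state=0)
        snm2 = SingleNucleusMethylome(calls=shuffled, labels=snm.labels)
        mat2 = aggregate_nucleus_promoters(snm2, cpg_map.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(mat.sort_index(), mat2.sort_index())


def brute_force_auc_lower(x, y):
    """P(x < y) + half ties by pair enumeration (AUC for 'lower in target')."""
    wins = 0.0
    for xi in x:
        for yj in y:
            if xi < yj:
                wins += 1.0
            elif xi == yj:
                wins += 0.5
    return wins / (len(x) * len(y))


class TestDeriveReference:
    def test_perfectly_separated_gene_has_auc_one_and_ranks_first(self):
        rng = np.random.default_rng(0)
        nuclei = [f"n{i}" for i in range(40)]
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=nuclei)
        perfect = np.r_[np.zeros(20), np.ones(20)]
        noisy = rng.uniform(0.3, 0.7, 40)
        mat = pd.DataFrame([perfect, noisy], index=["gPerfect", "gNoise"], columns=nuclei)
        ref, auc = derive_snm_reference(mat, labels, top_n=1, min_nonmissing=5)
        a_rows = auc[auc.cell_type == "A"].set_index("gene")
        assert a_rows.loc["gPerfect", "auc"] == pytest.approx(1.0)
        assert ref.target_type["gPerfect"] == "A"

    def test_auc_matches_pair_enumeration_on_12_nucleus_toy(self):
        nuclei = [f"n{i}" for i in range(12)]
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=nuclei)
        vals = np.array([0.1, 0.0, 0.3, 0.2, 0.3, 0.5, 0.6, 0.3, 0.9, 0.8, 0.2, 1.0])
        filler = np.linspace(0, 1, 12)
        mat = pd.DataFrame([vals, filler], index=["g", "f"], columns=nuclei)
        _, auc = derive_snm_reference(mat, labels, min_nonmissing=3, fdr=1.0)
        got = auc[(auc.gene == "g") & (auc.cell_type == "A")]["auc"].iloc[0]
        assert got == pytest.approx(brute_force_auc_lower(vals[:6], vals[6:]))

    def test_planted_markers_recovered_with_high_auc(self, small_cfg):
        cfg = SimulationConfig(
            seed=small_cfg.seed, markers_per_type=10, n_background_genes=30,
            nuclei_per_type=120,
        )
        ref_true = planted_dnam_reference(cfg, include_background=True)
        snm, cpg_map = simulate_snm(ref_true, cfg)
        mat = aggregate_nucleus_promoters(snm, cpg_map)
        builder = SnmReferenceBuilder(top_n=10).fit(mat, snm.labels)
        planted = set(cfg.marker_truth().index)
        assert set(builder.reference_.values.index) == planted
        selected = builder.auc_table_.merge(
            pd.DataFrame({"gene": list(planted)}), on="gene"
        )
        sel_auc = builder.auc_table_[builder.auc_table_.gene.isin(planted)]
        own = sel_auc[
            sel_auc.apply(lambda r: cfg.marker_truth()[r.gene] == r.cell_type, axis=1)
        ]
        assert own["auc"].min() >= 0.8

    def test_top_n_cap(self):
        rng = np.random.default_rng(2)
        nuclei = [f"n{i}" for i in range(60)]
        labels = pd.Series(["A"] * 30 + ["B"] * 30, index=nuclei)
        good = np.hstack([rng.uniform(0, 0.2, (20, 30)), rng.uniform(0.8, 1.0, (20, 30))])
        mat = pd.DataFrame(good, index=[f"g{i}" for i in range(20)], columns=nuclei)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ref, _ = derive_snm_reference(mat, labels, top_n=5, min_nonmissing=5)
        per_type = ref.target_type.value_counts()
        assert per_type.max() <= 5


class TestHypomethylationTest:
    def _mat(self, own, other, n=50, seed=0):
        rng = np.random.default_rng(seed)
        nuclei = [f"n{i}" for i in range(2 * n)]
        labels = pd.Series(["A"] * n + ["B"] * n, index=nuclei)
        vals = np.r_[
            np.clip(rng.normal(own, 0.05, n), 0, 1),
            np.clip(rng.normal(other, 0.05, n), 0, 1),
        ]
        mat = pd.DataFrame([vals], index=["g"], columns=nuclei)
        ref = DNAmReference(
            values=pd.DataFrame({"A": [own], "B": [other]}, index=["g"]),
            target_type=pd.Series({"g": "A"}),
        )
        return mat, labels, ref

    def test_identical_distributions_not_significant(self):
        mat, labels, ref = self._mat(0.5, 0.5, seed=1)
        res = marker_hypomethylation_test(mat, labels, ref)
        assert abs(res["t"].iloc[0]) < 2.5
        assert res["fdr"].iloc[0] > 0.01

    def test_planted_shift_detected_with_negative_t(self):
        mat, labels, ref = self._mat(0.2, 0.8, seed=2)
        res = marker_hypomethylation_test(mat, labels, ref)
        assert res["t"].iloc[0] < 0
        assert res["fdr"].iloc[0] < 0.05

    def test_t_matches_closed_form_on_six_value_toy(self):
        nuclei = [f"n{i}" for i in range(6)]
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=nuclei)
        x = np.array([0.1, 0.2, 0.3])
        z = np.array([0.6, 0.7, 0.9])
        mat = pd.DataFrame([np.r_[x, z]], index=["g"], columns=nuclei)
        ref = DNAmReference(
            values=pd.DataFrame({"A": [0.2], "B": [0.7]}, index=["g"]),
            target_type=pd.Series({"g": "A"}),
        )
        res = marker_hypomethylation_test(mat, labels, ref)
        # Welch statistic computed by hand
        se = np.sqrt(x.var(ddof=1) / 3 + z.var(ddof=1) / 3)
        expected = (x.mean() - z.mean()) / se
        assert res["t"].iloc[0] == pytest.approx(expected, rel=1e-10)


class TestCompareReferences:
    def _random_ref(self, seed, n=12, k=3):
        rng = np.random.default_rng(seed)
        return DNAmReference(
            values=pd.DataFrame(
                rng.uniform(size=(n, k)),
                index=[f"g{i}" for i in range(n)],
                columns=[f"T{j}" for j in range(k)],
            )
        )

    def test_identity_gives_zero_mad_unit_pcc_minimal_p(self):
        # 20 genes: a random permutation fixing half the rows (which would
        # tie the null MAD at zero) is then vanishingly unlikely
        ref = self._random_ref(0, n=20)
        res = compare_references(ref, ref, n_mc=199, seed=1)
        assert res["mad"] == 0.0
        assert res["pcc"] == pytest.approx(1.0)
        assert res["p_mad"] <= 1 / 200 + 1e-12
        assert res["p_pcc"] <= 1 / 200 + 1e-12

    def test_unrelated_reference_not_significant(self):
        ps = []
        for s in range(5):
            res = compare_references(
                self._random_ref(s), self._random_ref(100 + s), n_mc=200, seed=s
            )
            ps.append(res["p_pcc"])
        assert min(ps) > 0.005
        assert max(ps) > 0.2  # roughly uniform, not piling at zero

    def test_exhaustive_enumeration_on_five_gene_toy(self):
        ref_a = self._random_ref(3, n=5, k=2)
        ref_b = self._random_ref(4, n=5, k=2)
        res = compare_references(ref_a, ref_b, min_shared=5, exhaustive=True)
        A = ref_a.values.to_numpy()
        B = ref_b.values.to_numpy()
        mads = []
        pccs = []
        for p in permutations(range(5)):
            Bp = B[list(p)]
            mads.append(np.median(np.abs(A - Bp)))
            pccs.append(np.corrcoef(A.ravel(), Bp.ravel())[0, 1])
        assert res["p_mad"] == pytest.approx(np.mean(np.array(mads) <= res["mad"]))
        assert res["p_pcc"] == pytest.approx(np.mean(np.array(pccs) >= res["pcc"]))
        assert res["n_mc"] == 120

    def test_add_one_rule_keeps_p_positive(self):
        ref = self._random_ref(5)
        res = compare_references(ref, ref, n_mc=50, seed=0)
        assert res["p_mad"] > 0
        assert res["p_pcc"] > 0

    def test_too_few_shared_markers_errors(self):
        with pytest.raises(ValueError, match="shared"):
            compare_references(self._random_ref(0, n=4), self._random_ref(1, n=4))
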