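import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from myelotax.xspecies import (
    bootstrap_stability,
    correlate_groups,
    cross_species_flow,
    merge_on_orthologs,
    supercluster_similarity,
)


def _adata(genes, n_cells=4, seed=0):
    rng = np.random.default_rng(seed)
    return ad.AnnData(
        X=rng.poisson(2.0, size=(n_cells, len(genes))).astype(float),
        obs=pd.DataFrame(index=[f"c{seed}_{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )


class TestOrthologMerge:
    def test_identity_mapping_intersects(self):
        a = _adata(["G1", "G2", "G3"], seed=1)
        b = _adata(["G2", "G3", "G4"], seed=2)
        orth = pd.DataFrame({"source_gene": ["G2", "G3", "G4"], "target_gene": ["G2", "G3", "G4"]})
        merged = merge_on_orthologs(a, b, orth, min_shared=2)
        assert sorted(merged.var_names) == ["G2", "G3"]

    def test_one_to_many_dropped_by_default(self):
        a = _adata(["H1", "H2", "H3"], seed=3)
        b = _adata(["m1", "m2"], seed=4)
        orth = pd.DataFrame(
            {"source_gene": ["m1", "m1", "m2"], "target_gene": ["H1", "H2", "H3"]}
        )
        merged = merge_on_orthologs(a, b, orth, min_shared=1)
        assert list(merged.var_names) == ["H3"]  # m1 maps to two human genes
        assert "m1" in merged.uns["ortholog_merge"]["dropped_sources"]

    def test_constructed_partial_mapping_size(self):
        universe = [f"G{i}" for i in range(100)]
        a = _adata(universe, seed=5)
        b = _adata([f"m{i}" for i in range(100)], seed=6)
        # 90% mapped one-to-one, 10% unmapped
        orth = pd.DataFrame(
            {"source_gene": [f"m{i}" for i in range(90)], "target_gene": [f"G{i}" for i in range(90)]}
        )
        merged = merge_on_orthologs(a, b, orth, min_shared=50)
        assert merged.n_vars == 90

    def test_floor_enforced(self):
        a = _adata(["G1", "G2"], seed=7)
        b = _adata(["m1"], seed=8)
        orth = pd.DataFrame({"source_gene": ["m1"], "target_gene": ["G1"]})
        with pytest.raises(ValueError, match="shared genes"):
            merge_on_orthologs(a, b, orth, min_shared=50)


class TestCorrelateGroups:
    def test_identical_and_negated_profiles(self):
        genes = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        a = pd.DataFrame({"x": v}, index=genes)
        b = pd.DataFrame({"same": v, "neg": -v}, index=genes)
        rep = correlate_groups(a, b)
        assert rep.coefficients.loc["x", "same"] == pytest.approx(1.0)
        assert rep.coefficients.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(100)]
        a = pd.DataFrame(rng.normal(size=(100, 3)), index=genes, columns=list("abc"))
        b = pd.DataFrame(rng.normal(size=(100, 2)), index=genes, columns=list("xy"))
        rep = correlate_groups(a, b, method="pearson")
        for ca in "abc":
            for cb in "xy":
                u, v = a[ca].to_numpy(), b[cb].to_numpy()
                expected = ((u - u.mean()) * (v - v.mean())).sum() / (
                    np.sqrt(((u - u.mean()) ** 2).sum()) * np.sqrt(((v - v.mean()) ** 2).sum())
                )
                assert rep.coefficients.loc[ca, cb] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_profile_is_nan(self):
        genes = [f"g{i}" for i in range(10)]
        a = pd.DataFrame({"flat": np.ones(10)}, index=genes)
        b = pd.DataFrame({"x": np.arange(10.0)}, index=genes)
        rep = correlate_groups(a, b)
        assert np.isnan(rep.coefficients.loc["flat", "x"])

    def test_symmetric_when_self_correlated(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        a = pd.DataFrame(rng.normal(size=(40, 4)), index=genes, columns=list("abcd"))
        rep = correlate_groups(a, a)
        m = rep.coefficients.to_numpy(dtype=float)
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.allclose(np.diag(m), 1.0)

    def test_significance_stars(self):
        genes = [f"g{i}" for i in range(50)]
        v = np.arange(50.0)
        rep = correlate_groups(
            pd.DataFrame({"x": v}, index=genes), pd.DataFrame({"y": v}, index=genes)
        )
        assert rep.stars().loc["x", "y"] == "***"


class TestBootstrapStability:
    def test_defaults(self):
        import inspect

        sig = inspect.signature(bootstrap_stability)
        assert sig.parameters["n_iter"].default == 1000
        assert sig.parameters["gene_fraction"].default == 0.8

    def test_identical_profiles_fully_stable(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(50)]
        a = pd.DataFrame({"x": rng.normal(size=50)}, index=genes)
        stab = bootstrap_stability(a, a.rename(columns={"x": "y"}), n_iter=1000, seed=1)
        assert stab.loc["x", "y"] == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(60)]
        a = pd.DataFrame(rng.normal(size=(60, 2)), index=genes, columns=list("ab"))
        b = pd.DataFrame(rng.normal(size=(60, 2)), index=genes, columns=list("xy"))
        s1 = bootstrap_stability(a, b, n_iter=200, seed=42)
        s2 = bootstrap_stability(a, b, n_iter=200, seed=42)
        pd.testing.assert_frame_equal(s1, s2)

    def test_support_removal_collapses_correlation(self):
        """A correlation carried by a gene subset collapses when that subset
        is removed; with the subset present, the strong pair is stable."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        shared_signal = rng.normal(size=100) * 3
        a = pd.DataFrame({"x": shared_signal + rng.normal(size=100) * 0.1}, index=genes)
        b = pd.DataFrame({"y": shared_signal + rng.normal(size=100) * 0.1}, index=genes)
        r_full = correlate_groups(a, b).coefficients.loc["x", "y"]
        assert r_full > 0.95
        # under the literal |r_boot| >= |r_obs| rule, bootstrap correlations
        # fluctuate around r_obs, so a sizeable fraction meets the bar
        stab = bootstrap_stability(a, b, n_iter=300, seed=2)
        assert 0.2 <= stab.loc["x", "y"] <= 1.0
        # destroy the support: replace the shared signal with independent noise
        a2 = pd.DataFrame({"x": rng.normal(size=100)}, index=genes)
        b2 = pd.DataFrame({"y": rng.normal(size=100)}, index=genes)
        r_null = correlate_groups(a2, b2).coefficients.loc["x", "y"]
        assert abs(r_null) < 0.3


class TestSuperclusterSimilarity:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        m = pd.DataFrame(rng.normal(size=(30, 3)), index=genes, columns=["a", "b", "c"])
        m["dup"] = m["a"]
        rep = supercluster_similarity(m)
        assert rep.coefficients.loc["a", "dup"] == pytest.approx(1.0)
        assert np.allclose(np.diag(rep.coefficients.to_numpy(dtype=float)), 1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        m = pd.DataFrame(rng.normal(size=(30, 5)), index=genes, columns=list("abcde"))
        rep = supercluster_similarity(m)
        for c1 in "abcde":
            for c2 in "abcde":
                r1, r2 = rankdata(m[c1]), rankdata(m[c2])
                expected = np.corrcoef(r1, r2)[0, 1]
                assert rep.coefficients.loc[c1, c2] == pytest.approx(expected, abs=1e-12)

    def test_too_few_genes_rejected(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 1.0]], columns=["a", "b"])
        with pytest.raises(ValueError):
            supercluster_similarity(m)


class TestCrossSpeciesFlow:
    def _cells(self, n, labels, joints, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "supercluster": rng.choice(labels, size=n),
                "joint_cluster": rng.choice(joints, size=n),
            }
        )

    def test_default_min_link_fraction(self):
        import inspect

        assert inspect.signature(cross_species_flow).parameters["min_link_fraction"].default == 0.01

    def test_equal_sizes_not_downsampled(self):
        a = self._cells(100, ["P", "Q"], ["j1", "j2"], 1)
        b = self._cells(100, ["P", "Q"], ["j1", "j2"], 2)
        links = cross_species_flow(a, b, seed=0)
        assert links["share"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_downsampling_preserves_proportions(self):
        a = self._cells(400, ["P", "Q", "R"], ["j1", "j2"], 3)
        b = self._cells(100, ["P", "Q", "R"], ["j1", "j2"], 4)
        from myelotax.xspecies import _largest_remainder

        sizes = a["supercluster"].value_counts().sort_index()
        take = _largest_remainder(sizes.to_numpy(dtype=float), 100)
        assert take.sum() == 100
        expected = sizes / sizes.sum() * 100
        assert np.all(np.abs(take - expected.to_numpy()) <= 1.0)  # within one cell

    def test_disjoint_superclusters_rejected(self):
        a = self._cells(50, ["P"], ["j1"], 5)
        b = self._cells(50, ["Z"], ["j1"], 6)
        with pytest.raises(ValueError):
            cross_species_flow(a, b)
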