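import numpy as np
import pandas as pd
import pytest

import varapport as vp
from varapport._utils import linkage_to_newick, upgma_linkage
from varapport.structure import (kmeans_profiles, pc_trait_correlations,
                                 pca_individuals, population_distance_tree)

from conftest import make_design


class TestPCA:
    def test_duplicate_individuals_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 30))
        X[1] = X[0]
        res = pca_individuals(pd.DataFrame(X))
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])

    def test_explained_fractions_valid(self):
        rng = np.random.default_rng(1)
        res = pca_individuals(pd.DataFrame(rng.normal(size=(10, 40))))
        ev = res.explained_ratio.to_numpy()
        assert (ev >= 0).all() and ev.sum() <= 1 + 1e-12
        assert (np.diff(ev) <= 1e-12).all()

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(8, 20)))
        res = pca_individuals(X)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy()
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        assert np.allclose(recon, centered, atol=1e-10)

    def test_injected_axis_dominates_pc1(self):
        rng = np.random.default_rng(3)
        axis = rng.normal(size=30)
        scores = np.linspace(-3, 3, 12)
        X = np.outer(scores, axis) + rng.normal(scale=0.05, size=(12, 30))
        res = pca_individuals(pd.DataFrame(X))
        assert res.explained_ratio.iloc[0] > 0.95

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(7, 15)))
        a, b = pca_individuals(X), pca_individuals(X.copy())
        pd.testing.assert_frame_equal(a.scores, b.scores)
        for pc in a.loadings.index:
            j = a.loadings.loc[pc].abs().idxmax()
            assert a.loadings.loc[pc, j] > 0


class TestPCTraits:
    def _design(self, n):
        idx = [f"I{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        return pd.DataFrame({"group": ["G1"] * n, "mapped_reads": 1_000_000,
                             "rin": 8.0, "weight": rng.normal(3.4, 0.4, n),
                             "sex": rng.integers(0, 2, n)}, index=idx)

    def test_trait_equal_to_scores_gives_r_one(self):
        design = self._design(10)
        scores = pd.DataFrame({"PC1": design["weight"].to_numpy()},
                              index=design.index)
        out = pc_trait_correlations(scores, design, traits=["weight", "sex"])
        row = out.query("pc == 'PC1' and trait == 'weight'").iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert out.attrs["n_tests"] == 2

    def test_constant_trait_skipped_with_note(self):
        design = self._design(8)
        design["sex"] = 1
        scores = pd.DataFrame({"PC1": np.arange(8.0)}, index=design.index)
        out = pc_trait_correlations(scores, design, traits=["weight", "sex"])
        note = out.query("trait == 'sex'")["note"].iloc[0]
        assert "skipped" in note
        assert out.attrs["n_tests"] == 1

    def test_bonferroni_never_below_raw_p(self):
        design = self._design(12)
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(12, 3)),
                              columns=["PC1", "PC2", "PC3"], index=design.index)
        out = pc_trait_correlations(scores, design, traits=["weight", "sex"])
        ok = out.dropna(subset=["p"])
        assert (ok["p_bonferroni"] >= ok["p"] - 1e-15).all()
        assert (ok["p_bonferroni"] <= 1.0).all()


class TestUPGMA:
    def test_hand_agglomeration(self):
        # d(1,2)=2, d(1,3)=4, d(2,3)=4 -> ((1,2),3); 1,2 join at height 2,
        # 3 joins at height 4: leaf branches 1,1 and 2; internal branch 1
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        z = upgma_linkage(d)
        newick = linkage_to_newick(z, ["A", "B", "C"])
        assert newick == "(C:2,(A:1,B:1):1);"

    def test_tie_break_deterministic(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        a = linkage_to_newick(upgma_linkage(d), ["A", "B", "C"])
        b = linkage_to_newick(upgma_linkage(d), ["A", "B", "C"])
        assert a == b


class TestPopulationTree:
    @pytest.fixture(scope="class")
    def shifted_fits(self):
        # one group (G4) with a strong shift at many genes -> outgroup
        regimes = [vp.SelectionRegime("directional", 100, {"shift": 2.0})]
        ds = vp.generate_dataset(vp.SimulationConfig(
            n_genes=300, seed=43, beta_mapped_reads=0, beta_rin=0), regimes)
        return vp.pairwise_apportionments(ds.latent, ds.design, covariates=())

    def test_shifted_group_is_outgroup(self, shifted_fits):
        tree = population_distance_tree(shifted_fits)
        d = tree.distances
        others = [g for g in d.index if g != "G4"]
        within = max(d.loc[a, b] for a in others for b in others if a != b)
        to_g4 = min(d.loc["G4", g] for g in others)
        assert to_g4 > within
        assert tree.newick.rstrip(";").endswith("G4:" + tree.newick.rstrip(";").split("G4:")[-1])

    def test_distances_symmetric_nonnegative(self, shifted_fits):
        d = population_distance_tree(shifted_fits).distances
        assert np.allclose(d, d.T)
        assert (d.to_numpy() >= 0).all()
        assert np.allclose(np.diag(d), 0.0)

    def test_missing_pair_rejected(self, shifted_fits):
        incomplete = dict(list(shifted_fits.items())[:-1])
        with pytest.raises(ValueError, match="missing pairwise"):
            population_distance_tree(incomplete)

    def test_invariant_to_uniform_weight_rescaling(self, shifted_fits):
        a = population_distance_tree(shifted_fits, weighting="ss_total")
        for fit in shifted_fits.values():
            fit.ss_["ss_total"] *= 7.0
        b = population_distance_tree(shifted_fits, weighting="ss_total")
        pd.testing.assert_frame_equal(a.distances, b.distances)


class TestKMeans:
    def _data(self):
        design_ind = pd.DataFrame(
            {"group": ["G1"] * 5 + ["G2"] * 5, "mapped_reads": 1, "rin": 8.0},
            index=[f"I{i}" for i in range(10)])
        up = np.linspace(-1, 1, 10)
        rng = np.random.default_rng(0)
        profiles = np.vstack([np.tile(up, (15, 1)), np.tile(-up, (15, 1))])
        profiles += rng.normal(scale=0.05, size=profiles.shape)
        expr = pd.DataFrame(profiles, index=[f"g{i}" for i in range(30)],
                            columns=design_ind.index)
        return expr, design_ind

    def test_mirror_profiles_perfectly_separated(self):
        expr, design_ind = self._data()
        out = kmeans_profiles(expr, design_ind, k=2, seed=0)
        labels = out["labels"]
        assert labels.iloc[:15].nunique() == 1
        assert labels.iloc[15:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]
        assert set(out["group_profiles"].columns) == {"G1", "G2"}

    def test_k_one_single_cluster(self):
        expr, design_ind = self._data()
        out = kmeans_profiles(expr, design_ind, k=1, seed=0)
        assert (out["labels"] == 0).all()

    def test_labels_stable_at_fixed_seed(self):
        expr, design_ind = self._data()
        a = kmeans_profiles(expr, design_ind, k=2, seed=3)["labels"]
        b = kmeans_profiles(expr, design_ind, k=2, seed=3)["labels"]
        pd.testing.assert_series_equal(a, b)

    def test_k_exceeding_genes_rejected(self):
        expr, design_ind = self._data()
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_profiles(expr, design_ind, k=31, seed=0)
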