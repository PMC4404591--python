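import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import varapport as vp
from varapport.anova import NestedAnova, ems_coefficients, nested_ss

from conftest import make_design


def brute_force_ss(y, groups, indivs):
    """Sums of squares from explicit means — the independent oracle."""
    y = np.asarray(y, dtype=float)
    grand = y.mean()
    ss_a = ss_b = ss_e = 0.0
    for g in set(groups):
        sel_g = [i for i, gg in enumerate(groups) if gg == g]
        gm = y[sel_g].mean()
        ss_a += len(sel_g) * (gm - grand) ** 2
        for ind in {indivs[i] for i in sel_g}:
            sel_i = [i for i in sel_g if indivs[i] == ind]
            im = y[sel_i].mean()
            ss_b += len(sel_i) * (im - gm) ** 2
            ss_e += ((y[sel_i] - im) ** 2).sum()
    return ss_a, ss_b, ss_e


def random_nested_design(rng):
    """Random, possibly unbalanced nested design (>=2 indiv/group, >=2 reps)."""
    n_groups = rng.integers(2, 5)
    groups, indivs = [], []
    for g in range(n_groups):
        for i in range(rng.integers(2, 6)):
            for _ in range(rng.integers(2, 4)):
                groups.append(f"G{g}")
                indivs.append(f"G{g}_I{i}")
    return groups, indivs


@pytest.mark.parametrize("seed", range(12))
def test_nested_ss_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    groups, indivs = random_nested_design(rng)
    y = rng.normal(size=(len(groups), 3))
    _, gcodes = np.unique(groups, return_inverse=True)
    _, icodes = np.unique(indivs, return_inverse=True)
    ss_a, ss_b, ss_e = nested_ss(y, gcodes, icodes)
    for g in range(3):
        ea, eb, ee = brute_force_ss(y[:, g], groups, indivs)
        assert ss_a[g] == pytest.approx(ea, abs=1e-10)
        assert ss_b[g] == pytest.approx(eb, abs=1e-10)
        assert ss_e[g] == pytest.approx(ee, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_decomposition_identity_property(seed):
    """SS_A + SS_B + SS_e equals the total centered SS for any data."""
    rng = np.random.default_rng(seed)
    groups, indivs = random_nested_design(rng)
    y = rng.normal(size=(len(groups), 2)) * rng.uniform(0.1, 10)
    _, gcodes = np.unique(groups, return_inverse=True)
    _, icodes = np.unique(indivs, return_inverse=True)
    ss_a, ss_b, ss_e = nested_ss(y, gcodes, icodes)
    total = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    assert np.allclose(ss_a + ss_b + ss_e, total, rtol=1e-8, atol=1e-10)


def test_balanced_toy_all_variation_among_groups(balanced_toy):
    expr, design = balanced_toy
    fit = vp.fit_simple_model(expr, design, covariates=())
    row = fit.ss_.loc["gene_1"]
    assert row["ss_group"] == pytest.approx(8.0)
    assert row["ss_individual"] == pytest.approx(0.0, abs=1e-12)
    assert row["ss_error"] == pytest.approx(0.0, abs=1e-12)
    assert fit.apportionment_.loc["gene_1", "Nst"] == pytest.approx(1.0)


def test_constant_gene_flagged_undefined():
    design = make_design(2, 2, 2)
    expr = pd.DataFrame([[3.0] * 8], index=["flat"], columns=design.index)
    fit = vp.fit_simple_model(expr, design, covariates=())
    assert not fit.apportionment_.loc["flat", "defined"]
    assert np.isnan(fit.apportionment_.loc["flat", "Nst"])


def test_covariate_gene_fully_absorbed():
    rng = np.random.default_rng(0)
    design = make_design(2, 3, 2, rng=rng)
    x = design["mapped_reads"].to_numpy(dtype=float)
    expr = pd.DataFrame([2.0 + 0.5 * (x - x.mean()) / x.std()],
                        index=["tech"], columns=design.index)
    fit = vp.fit_simple_model(expr, design)
    assert fit.ss_.loc["tech", "ss_total"] == pytest.approx(0.0, abs=1e-16)
    assert fit.ss_.loc["tech", "ss_mapped_reads"] > 0


def test_ems_coefficients_balanced_case():
    gcodes = np.repeat(np.arange(4), 20)
    icodes = np.repeat(np.arange(40), 2)
    n0, n0p, nb = ems_coefficients(gcodes, icodes)
    assert n0 == pytest.approx(2.0)
    assert n0p == pytest.approx(2.0)
    assert nb == pytest.approx(20.0)


def test_degrees_of_freedom_account_for_covariates(small_expr, small_dataset):
    fit = NestedAnova().fit(small_expr.T, small_dataset.design)
    df = fit.df_
    assert df["group"] == 3 and df["individual"] == 36 and df["error"] == 38
    assert df.sum() == 80 - 1 - 2


def test_apportionment_formulas_from_known_ss():
    """SS (1,1,2) -> Nst=.25, Nit=.25, Net=.5, Nis=1/3, Nig=.5;
    components (0,3,1) -> Mst=0, Mit=.75, Met=.25."""
    from varapport.anova import apportionment_table

    table = apportionment_table(
        pd.Index(["g"]), np.array([1.0]), np.array([1.0]), np.array([2.0]),
        np.array([0.0]), np.array([3.0]), np.array([1.0]))
    row = table.loc["g"]
    assert row["Nst"] == pytest.approx(0.25)
    assert row["Nit"] == pytest.approx(0.25)
    assert row["Net"] == pytest.approx(0.50)
    assert row["Nis"] == pytest.approx(1 / 3)
    assert row["Nig"] == pytest.approx(0.5)
    assert row["Mst"] == pytest.approx(0.0)
    assert row["Mit"] == pytest.approx(0.75)
    assert row["Met"] == pytest.approx(0.25)


def test_apportionment_bounds_and_sums(small_expr, small_dataset):
    fit = NestedAnova().fit(small_expr.T, small_dataset.design)
    table = fit.apportionment_.query("defined")
    n_sum = table[["Nst", "Nit", "Net"]].sum(axis=1)
    assert np.allclose(n_sum, 1.0, atol=1e-10)
    for col in ("Nst", "Nit", "Net", "Nis", "Nig", "Mst", "Mit", "Met"):
        assert table[col].between(-1e-12, 1 + 1e-12).all()
    m_sum = table[["Mst", "Mit", "Met"]].sum(axis=1)
    assert np.allclose(m_sum[np.isfinite(m_sum)], 1.0, atol=1e-10)


def test_single_individual_group_rejected():
    design = make_design(2, 2, 2)
    design = design.drop(index=[lib for lib in design.index
                                if lib.startswith("G2_I02")])
    expr = pd.DataFrame(np.ones((1, len(design))), index=["g"],
                        columns=design.index)
    with pytest.raises(ValueError, match="fewer than 2 individuals"):
        vp.fit_simple_model(expr, design, covariates=())


def test_pairwise_returns_all_pairs(small_expr, small_dataset):
    fits = vp.pairwise_apportionments(small_expr, small_dataset.design)
    assert len(fits) == 6
    four = vp.fit_simple_model(small_expr, small_dataset.design)
    mean_nst = {pair: f.apportionment_["Nst"].mean() for pair, f in fits.items()}
    # 4-group mean Nst lies within a tolerance band of the pairwise envelope
    lo, hi = min(mean_nst.values()), max(mean_nst.values())
    assert lo - 0.05 <= four.apportionment_["Nst"].mean() <= hi + 0.05


class TestIndividualDE:
    def test_null_simulation_controls_fdr(self):
        ds = vp.generate_dataset(vp.SimulationConfig(
            n_genes=1000, sigma2_B=0.0, seed=31, beta_mapped_reads=0,
            beta_rin=0))
        fit = vp.fit_simple_model(ds.latent, ds.design, covariates=())
        de = fit.individual_de_tests(fdr=0.05)
        assert de["significant_F"].mean() <= 0.02
        assert de["significant_F_inverted"].mean() <= 0.02

    def test_strong_effects_high_power_and_test_overlap(self):
        ds = vp.generate_dataset(vp.SimulationConfig(
            n_genes=400, sigma2_B=0.5, sigma2_e=0.1, seed=32))
        fit = vp.fit_simple_model(ds.latent, ds.design)
        de = fit.individual_de_tests(fdr=0.05)
        assert de["significant_F"].mean() > 0.95
        agree = (de["significant_F"] == de["significant_LRT"]).mean()
        assert agree > 0.9

    def test_equal_individual_means_not_significant(self):
        design = make_design(2, 3, 2)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1, (1, len(design)))
        # force identical means for each individual's replicate pair
        y = noise - np.repeat(noise.reshape(1, -1, 2).mean(axis=2), 2, axis=1)
        expr = pd.DataFrame(y, index=["g"], columns=design.index)
        fit = vp.fit_simple_model(expr, design, covariates=())
        de = fit.individual_de_tests()
        assert de.loc["g", "F"] == pytest.approx(0.0, abs=1e-20)
        assert de.loc["g", "p_F"] == pytest.approx(1.0)


class TestFullModel:
    @pytest.fixture(scope="class")
    def trait_fit(self):
        eff = vp.TraitEffect("weight", lambda rng, n: rng.normal(3.4, 0.45, n),
                             effect_sd=0.5, fraction=0.1)
        ds = vp.generate_dataset(vp.SimulationConfig(
            n_genes=400, seed=13, trait_effects=[eff]))
        full = vp.fit_full_model(ds.latent, ds.design)
        return ds, full

    def test_eta2_sums_to_one(self, trait_fit):
        _, full = trait_fit
        assert np.allclose(full.eta2_.sum(axis=1), 1.0, atol=1e-10)

    def test_factor_order_matches_model(self, trait_fit):
        _, full = trait_fit
        assert list(full.eta2_.columns) == [
            "mapped_reads", "rin", "sex", "weight", "length", "cesarean",
            "maternal_age", "bmi", "alcohol", "vegetarian", "group",
            "individual", "error"]

    def test_injected_trait_flagged_with_direction(self, trait_fit):
        ds, full = trait_fit
        inc, dec = vp.trait_direction_partition(full, "weight")
        sig = inc | dec
        assert len(sig) >= 15
        assert not (inc & dec)
        sig_set = set(full.qvalues_.index[full.qvalues_["weight"] <= full.fdr])
        assert sig == sig_set

    def test_constant_trait_dropped_with_warning(self, small_expr, small_dataset):
        design = small_dataset.design.copy()
        design["vegetarian"] = 0
        with pytest.warns(UserWarning, match="vegetarian"):
            full = vp.fit_full_model(small_expr, design)
        assert (full.eta2_["vegetarian"] == 0).all()


def test_mean_expression_diagnostics_reports_undefined():
    design = make_design(2, 2, 2)
    rng = np.random.default_rng(3)
    y = rng.normal(size=(12, len(design)))
    y = y - y.mean(axis=1, keepdims=True)  # constant (zero) mean everywhere
    expr = pd.DataFrame(y, index=[f"g{i}" for i in range(12)],
                        columns=design.index)
    fit = vp.fit_simple_model(expr, design, covariates=())
    diag = vp.mean_expression_diagnostics(fit.apportionment_, fit)
    assert np.isnan(diag.loc["ss_error", "r"])
    assert "undefined" in diag.loc["ss_error", "note"]


def test_mean_variance_coupling_positive_residual_correlation():
    """Replicate variability growing with expression level shows up as a
    positive correlation between mean expression and residual SS."""
    ds = vp.generate_dataset(vp.SimulationConfig(
        n_genes=800, seed=17, baseline_log_mean_range=(4, 12),
        sigma2_e_mean_slope=0.25))
    expr = vp.variance_stabilize(ds.counts)
    fit = vp.fit_simple_model(expr, ds.design)
    diag = vp.mean_expression_diagnostics(fit.apportionment_, fit)
    assert diag.loc["ss_error", "r"] > 0.3
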