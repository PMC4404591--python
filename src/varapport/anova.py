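"""Nested model-II ANOVA apportionment of per-gene expression variation.

Each gene's normalized expression y_ijk (replicate k of individual j in
group i) follows

    y_ijk = mu + x + z + A_i + B_ij + e_ijk

with technical covariates x (mapped reads) and z (RIN) removed first by
sequential least squares, then the remaining variation decomposed into
nested sums of squares:

    SS_A = sum_i n_i (ybar_i - ybar)^2          among groups
    SS_B = sum_ij n_ij (ybar_ij - ybar_i)^2     among individuals in groups
    SS_e = sum_ijk (y_ijk - ybar_ij)^2          among replicates (residual)

Two families of apportionment statistics are derived per gene:

* variation (eta^2-style) parameters from the SS directly —
  Nst = SS_A/SS_T, Nit = SS_B/SS_T, Net = SS_e/SS_T, plus
  Nis = SS_B/(SS_B+SS_e) and Nig = SS_B/(SS_A+SS_B);
* variance parameters from additive variance components obtained by
  inverting the expected mean squares of the random-effects model —
  Mst = s2_A/s2_T, Mit = s2_B/s2_T, Met = s2_e/s2_T, the expression
  analogs of Wright's F statistics.

Unbalanced designs use the standard Sokal-Rohlf n0-style EMS coefficients;
negative component estimates are truncated at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import bh_adjust, sequential_block_projection
from .io import design_traits

__all__ = [
    "NestedAnova",
    "FullModelAnova",
    "fit_simple_model",
    "apportion_statistics",
    "pairwise_apportionments",
    "individual_de_tests",
    "fit_full_model",
    "trait_direction_partition",
    "mean_expression_diagnostics",
    "nested_ss",
]


@dataclass
class NestedIndex:
    """Integer-coded nested design: libraries -> individuals -> groups."""

    group_codes: np.ndarray  # per library
    indiv_codes: np.ndarray  # per library
    indiv_group: np.ndarray  # per individual
    group_labels: np.ndarray
    indiv_labels: np.ndarray

    @classmethod
    def from_design(cls, design: pd.DataFrame) -> "NestedIndex":
        groups = design["group"].to_numpy()
        indivs = design["individual"].to_numpy()
        indiv_labels, indiv_codes = np.unique(indivs, return_inverse=True)
        group_labels, group_codes = np.unique(groups, return_inverse=True)
        indiv_group = np.full(len(indiv_labels), -1, dtype=int)
        for lib in range(len(indivs)):
            prev = indiv_group[indiv_codes[lib]]
            if prev >= 0 and prev != group_codes[lib]:
                raise ValueError(
                    f"individual {indiv_labels[indiv_codes[lib]]!r} appears in "
                    "multiple groups"
                )
            indiv_group[indiv_codes[lib]] = group_codes[lib]
        return cls(group_codes, indiv_codes, indiv_group, group_labels, indiv_labels)

    @property
    def n_groups(self):
        return len(self.group_labels)

    @property
    def n_individuals(self):
        return len(self.indiv_labels)

    @property
    def n_libraries(self):
        return len(self.group_codes)


def apportionment_table(genes, ss_a, ss_b, ss_e, s2_a, s2_b, s2_e,
                        mean_expression=None, zero_tol=1e-12):
    """All apportionment statistics from SS strata and variance components."""
    ss_t = ss_a + ss_b + ss_e
    defined = ss_t > zero_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        nst = np.where(defined, ss_a / ss_t, np.nan)
        nit = np.where(defined, ss_b / ss_t, np.nan)
        net = np.where(defined, ss_e / ss_t, np.nan)
        nis = np.where(ss_b + ss_e > zero_tol, ss_b / (ss_b + ss_e), np.nan)
        nig = np.where(ss_a + ss_b > zero_tol, ss_b / (ss_a + ss_b), np.nan)
        s2_t = s2_a + s2_b + s2_e
        mdef = s2_t > zero_tol
        mst = np.where(mdef, s2_a / s2_t, np.nan)
        mit = np.where(mdef, s2_b / s2_t, np.nan)
        met = np.where(mdef, s2_e / s2_t, np.nan)
    if mean_expression is None:
        mean_expression = np.full(len(ss_t), np.nan)
    return pd.DataFrame(
        {
            "Nst": nst, "Nit": nit, "Net": net, "Nis": nis, "Nig": nig,
            "Mst": mst, "Mit": mit, "Met": met,
            "mean_expression": mean_expression, "defined": defined,
        },
        index=genes,
    )


def nested_ss(Y, group_codes, indiv_codes):
    """Nested sums of squares per gene from library-level values.

    Y has shape (n_libraries, n_genes); returns (ss_a, ss_b, ss_e) arrays.
    The decomposition SS_A + SS_B + SS_e = total centered SS is an identity.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    a = int(group_codes.max()) + 1
    b = int(indiv_codes.max()) + 1
    G = np.zeros((a, n))
    G[group_codes, np.arange(n)] = 1.0
    Ind = np.zeros((b, n))
    Ind[indiv_codes, np.arange(n)] = 1.0
    n_i = G.sum(axis=1)
    n_ij = Ind.sum(axis=1)
    grand = Y.mean(axis=0)
    gmeans = (G @ Y) / n_i[:, None]
    imeans = (Ind @ Y) / n_ij[:, None]
    ss_a = (n_i[:, None] * (gmeans - grand) ** 2).sum(axis=0)
    indiv_group = (G @ Ind.T > 0).argmax(axis=0)  # group of each individual
    ss_b = (n_ij[:, None] * (imeans - gmeans[indiv_group]) ** 2).sum(axis=0)
    ss_e = ((Y - imeans[indiv_codes]) ** 2).sum(axis=0)
    return ss_a, ss_b, ss_e


def ems_coefficients(group_codes, indiv_codes):
    """Unbalanced nested EMS coefficients (n0, n0', n_b).

    E[MS_e] = s2
    E[MS_B] = s2 + n0  * s2_B
    E[MS_A] = s2 + n0' * s2_B + n_b * s2_A
    """
    n = len(group_codes)
    a = int(group_codes.max()) + 1
    b = int(indiv_codes.max()) + 1
    n_ij = np.bincount(indiv_codes, minlength=b).astype(float)
    n_i = np.bincount(group_codes, minlength=a).astype(float)
    indiv_group = np.full(b, -1, dtype=int)
    indiv_group[indiv_codes] = group_codes
    sum_nij2_by_group = np.bincount(indiv_group, weights=n_ij**2, minlength=a)
    term = (sum_nij2_by_group / n_i).sum()
    n0 = (n - term) / (b - a)
    n0p = (term - (n_ij**2).sum() / n) / (a - 1)
    nb = (n - (n_i**2).sum() / n) / (a - 1)
    return n0, n0p, nb


class NestedAnova(BaseEstimator):
    """Per-gene nested random-effects ANOVA with technical covariates.

    Parameters
    ----------
    covariates : tuple of str
        Design columns removed sequentially (standardized) before the
        nested decomposition.  Empty tuple fits the pure nested model.
    truncate_negative : bool
        Truncate negative variance-component estimates at zero before
        computing the M statistics.
    zero_tol : float
        Genes whose residual total SS falls below this are flagged as
        undefined rather than producing statistics from numerical noise.

    Attributes (after ``fit(X, design)`` with X of shape (n_libraries, n_genes))
    ----------
    ss_ : DataFrame with SS per covariate and stratum per gene
    df_ : Series of degrees of freedom per stratum
    ms_ : DataFrame of mean squares
    variance_components_ : DataFrame (sigma2_group, sigma2_individual, sigma2_error)
    apportionment_ : DataFrame of Nst/Nit/Net/Nis/Nig/Mst/Mit/Met + mean expression
    ems_coefficients_ : dict of the EMS coefficients used
    """

    def __init__(self, covariates=("mapped_reads", "rin"), truncate_negative=True,
                 zero_tol=1e-12):
        self.covariates = covariates
        self.truncate_negative = truncate_negative
        self.zero_tol = zero_tol

    def fit(self, X, design: pd.DataFrame):
        X = self._as_frame(X)
        design = design.loc[X.index]
        idx = NestedIndex.from_design(design)
        if idx.n_groups < 2:
            raise ValueError("need at least 2 groups")
        indiv_per_group = np.bincount(idx.indiv_group, minlength=idx.n_groups)
        if (indiv_per_group < 2).any():
            bad = idx.group_labels[indiv_per_group < 2].tolist()
            raise ValueError(f"groups with fewer than 2 individuals: {bad}")

        Y = X.to_numpy(dtype=float)
        n = Y.shape[0]
        blocks = [("intercept", np.ones((n, 1)))]
        for cov in self.covariates:
            v = design[cov].to_numpy(dtype=float)
            sd = v.std()
            v = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
            blocks.append((cov, v[:, None]))
        proj = sequential_block_projection(blocks, n)
        resid = Y.copy()
        cov_ss = {}
        n_cov_df = 0
        for name, q, df in proj:
            contrib = q @ (q.T @ resid)
            if name != "intercept":
                cov_ss[f"ss_{name}"] = (contrib**2).sum(axis=0)
                n_cov_df += df
            resid -= contrib

        ss_a, ss_b, ss_e = nested_ss(resid, idx.group_codes, idx.indiv_codes)
        ss_t = ss_a + ss_b + ss_e

        df_a = idx.n_groups - 1
        df_b = idx.n_individuals - idx.n_groups
        df_e = n - idx.n_individuals - n_cov_df
        if df_e <= 0:
            raise ValueError("no residual degrees of freedom for the error stratum")

        n0, n0p, nb = ems_coefficients(idx.group_codes, idx.indiv_codes)
        ms_a, ms_b, ms_e = ss_a / df_a, ss_b / df_b, ss_e / df_e
        s2_e = ms_e
        s2_b_raw = (ms_b - ms_e) / n0
        s2_a_raw = (ms_a - ms_e - n0p * s2_b_raw) / nb
        if self.truncate_negative:
            s2_b = np.maximum(s2_b_raw, 0.0)
            s2_a = np.maximum(s2_a_raw, 0.0)
        else:
            s2_b, s2_a = s2_b_raw, s2_a_raw

        genes = X.columns
        self.index_ = idx
        self.design_ = design
        self.n_libraries_ = n
        self.residual_ = pd.DataFrame(resid, index=X.index, columns=genes)
        self.ss_ = pd.DataFrame(
            {**cov_ss, "ss_group": ss_a, "ss_individual": ss_b, "ss_error": ss_e,
             "ss_total": ss_t},
            index=genes,
        )
        self.df_ = pd.Series(
            {"group": df_a, "individual": df_b, "error": df_e}, name="df"
        )
        self.ms_ = pd.DataFrame(
            {"ms_group": ms_a, "ms_individual": ms_b, "ms_error": ms_e}, index=genes
        )
        self.ems_coefficients_ = {"n0": n0, "n0_prime": n0p, "n_b": nb}
        self.variance_components_ = pd.DataFrame(
            {"sigma2_group": s2_a, "sigma2_individual": s2_b, "sigma2_error": s2_e},
            index=genes,
        )
        self.mean_expression_ = pd.Series(Y.mean(axis=0), index=genes,
                                          name="mean_expression")
        self.apportionment_ = apportionment_table(
            genes, ss_a, ss_b, ss_e, s2_a, s2_b, s2_e,
            mean_expression=self.mean_expression_.to_numpy(),
            zero_tol=self.zero_tol)
        return self

    def individual_de_tests(self, fdr: float = 0.05) -> pd.DataFrame:
        """Three tests of inter-individual differential expression per gene.

        * F-ratio MS_individual / MS_error on (df_B, df_e);
        * the inverted F-ratio MS_error / MS_individual (excess
          intra-individual variation);
        * a Gaussian likelihood-ratio comparison of the covariate-only model
          against covariate + individual, referred to chi-squared.

        All p-values are Benjamini-Hochberg adjusted across genes.
        """
        df_b, df_e = self.df_["individual"], self.df_["error"]
        ms_b = self.ms_["ms_individual"].to_numpy()
        ms_e = self.ms_["ms_error"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ms_b / ms_e
            f_inv = ms_e / ms_b
        p_f = stats.f.sf(f, df_b, df_e)
        p_inv = stats.f.sf(f_inv, df_e, df_b)
        # LRT: RSS under covariates-only vs covariates + individual factor
        rss0 = self.ss_[["ss_group", "ss_individual", "ss_error"]].sum(axis=1).to_numpy()
        rss1 = self.ss_["ss_error"].to_numpy()
        n = self.n_libraries_
        with np.errstate(divide="ignore", invalid="ignore"):
            lrt = n * np.log(rss0 / rss1)
        lrt_df = self.index_.n_individuals - 1
        p_lrt = stats.chi2.sf(lrt, lrt_df)
        out = pd.DataFrame(
            {
                "F": f, "p_F": p_f, "q_F": bh_adjust(p_f),
                "F_inverted": f_inv, "p_F_inverted": p_inv,
                "q_F_inverted": bh_adjust(p_inv),
                "LRT": lrt, "p_LRT": p_lrt, "q_LRT": bh_adjust(p_lrt),
            },
            index=self.ss_.index,
        )
        out["significant_F"] = out["q_F"] <= fdr
        out["significant_F_inverted"] = out["q_F_inverted"] <= fdr
        out["significant_LRT"] = out["q_LRT"] <= fdr
        return out

    @staticmethod
    def _as_frame(X):
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X)


class FullModelAnova(BaseEstimator):
    """Partially nested model-II ANOVA with biological traits, no interactions.

    Sequential (Type I) sums of squares in the fixed fitting order
    mapped_reads, rin, sex, weight, length, cesarean, maternal_age, bmi,
    alcohol, vegetarian, group, individual, error; eta^2 = SS/SS_T per
    factor, F = MS_factor/MS_error, BH adjustment per factor across genes.
    Order is part of the model contract: the SS identity holds sequentially.
    """

    def __init__(self, covariates=("mapped_reads", "rin"), traits=None, fdr=0.05):
        self.covariates = covariates
        self.traits = traits
        self.fdr = fdr

    def fit(self, X, design: pd.DataFrame):
        X = NestedAnova._as_frame(X)
        design = design.loc[X.index]
        idx = NestedIndex.from_design(design)
        Y = X.to_numpy(dtype=float)
        n = Y.shape[0]
        traits = list(self.traits) if self.traits is not None else design_traits(design)

        blocks = [("intercept", np.ones((n, 1)))]
        trait_vectors = {}
        dropped = []
        for cov in list(self.covariates) + traits:
            v = self._numeric(design[cov])
            sd = v.std()
            if sd == 0:
                dropped.append(cov)
                warnings.warn(f"constant factor {cov!r} dropped from the full model")
                continue
            v = (v - v.mean()) / sd
            trait_vectors[cov] = v
            blocks.append((cov, v[:, None]))
        a = idx.n_groups
        G = np.zeros((n, a))
        G[np.arange(n), idx.group_codes] = 1.0
        blocks.append(("group", G))
        b = idx.n_individuals
        Ind = np.zeros((n, b))
        Ind[np.arange(n), idx.indiv_codes] = 1.0
        blocks.append(("individual", Ind))

        proj = sequential_block_projection(blocks, n)
        grand = Y.mean(axis=0)
        ss_total = ((Y - grand) ** 2).sum(axis=0)
        ss = {}
        dfs = {}
        signs = {}
        used_df = 0
        for name, q, df in proj:
            coef = q.T @ Y
            if name == "intercept":
                continue
            ss[name] = (coef**2).sum(axis=0)
            dfs[name] = df
            used_df += df
            if name in trait_vectors and df == 1:
                # orient the orthonormal column along increasing trait values
                orient = np.sign(float(q[:, 0] @ trait_vectors[name])) or 1.0
                signs[name] = np.sign(orient * coef[0])
        for name in dropped:
            ss[name] = np.zeros(Y.shape[1])
            dfs[name] = 0
        ss_error = ss_total - sum(
            ss[name] for name in ss if name not in dropped
        )
        ss_error = np.maximum(ss_error, 0.0)
        df_error = n - 1 - used_df
        if df_error <= 0:
            raise ValueError("full model leaves no residual degrees of freedom")
        ms_error = ss_error / df_error

        order = [nm for nm, _ in blocks if nm != "intercept"] + dropped
        order = list(dict.fromkeys(order)) + ["error"]
        ss["error"] = ss_error
        dfs["error"] = df_error

        genes = X.columns
        self.factors_ = [nm for nm in order if nm != "error"]
        self.df_ = pd.Series({nm: dfs[nm] for nm in order}, name="df")
        self.ss_ = pd.DataFrame({nm: ss[nm] for nm in order}, index=genes)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.eta2_ = self.ss_.div(pd.Series(ss_total, index=genes), axis=0)
        fstats, pvals, qvals = {}, {}, {}
        for nm in self.factors_:
            if dfs[nm] == 0:
                fstats[nm] = np.full(len(genes), np.nan)
                pvals[nm] = np.full(len(genes), np.nan)
                qvals[nm] = np.full(len(genes), np.nan)
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                fv = (ss[nm] / dfs[nm]) / ms_error
            fstats[nm] = fv
            pvals[nm] = stats.f.sf(fv, dfs[nm], df_error)
            qvals[nm] = bh_adjust(pvals[nm])
        self.f_ = pd.DataFrame(fstats, index=genes)
        self.pvalues_ = pd.DataFrame(pvals, index=genes)
        self.qvalues_ = pd.DataFrame(qvals, index=genes)
        self.signs_ = pd.DataFrame(signs, index=genes)
        self.dropped_factors_ = dropped
        self.traits_ = [t for t in traits if t not in dropped]
        return self

    @staticmethod
    def _numeric(series: pd.Series) -> np.ndarray:
        if series.dtype == bool:
            return series.to_numpy(dtype=float)
        if series.dtype == object or str(series.dtype) == "category":
            levels = pd.unique(series)
            if len(levels) > 2:
                raise ValueError(
                    f"non-numeric trait {series.name!r} has >2 levels; code it numerically"
                )
            mapping = {lv: i for i, lv in enumerate(sorted(map(str, levels)))}
            return series.astype(str).map(mapping).to_numpy(dtype=float)
        return series.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# thin functional wrappers (genes x libraries orientation)


def fit_simple_model(expr: pd.DataFrame, design: pd.DataFrame, groups=None,
                     covariates=("mapped_reads", "rin")) -> NestedAnova:
    """Fit the simple nested model; ``expr`` is genes x libraries."""
    X = expr.T
    if groups is not None:
        keep = design["group"].isin(groups)
        design = design.loc[keep]
        X = X.loc[design.index]
    return NestedAnova(covariates=covariates).fit(X, design)


def apportion_statistics(fit: NestedAnova) -> pd.DataFrame:
    return fit.apportionment_


def pairwise_apportionments(expr: pd.DataFrame, design: pd.DataFrame,
                            covariates=("mapped_reads", "rin")):
    """One fitted model per group pair, keyed by (group1, group2)."""
    groups = sorted(pd.unique(design["group"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for pairwise apportionment")
    out = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            out[(g1, g2)] = fit_simple_model(expr, design, groups=(g1, g2),
                                             covariates=covariates)
    return out


def individual_de_tests(fit: NestedAnova, fdr: float = 0.05) -> pd.DataFrame:
    return fit.individual_de_tests(fdr=fdr)


def fit_full_model(expr: pd.DataFrame, design: pd.DataFrame, fdr: float = 0.05,
                   traits=None) -> FullModelAnova:
    return FullModelAnova(traits=traits, fdr=fdr).fit(expr.T, design)


def trait_direction_partition(full: FullModelAnova, trait: str):
    """Split a trait's significant genes by the direction of its effect."""
    if trait not in full.qvalues_.columns:
        raise ValueError(f"trait {trait!r} was not fitted")
    sig = full.qvalues_[trait] <= full.fdr
    if trait not in full.signs_.columns:
        raise ValueError(f"trait {trait!r} has no single-df direction")
    signs = full.signs_[trait]
    increasing = set(full.qvalues_.index[sig & (signs > 0)])
    decreasing = set(full.qvalues_.index[sig & (signs <= 0)])
    return increasing, decreasing


def mean_expression_diagnostics(table: pd.DataFrame, fit: NestedAnova) -> pd.DataFrame:
    """Pearson correlation of per-gene mean expression with SS and N statistics."""
    if len(table) < 10:
        raise ValueError("need at least 10 genes for diagnostics")
    mean_expr = table["mean_expression"]
    rows = []
    targets = {
        "ss_group": fit.ss_["ss_group"],
        "ss_individual": fit.ss_["ss_individual"],
        "ss_error": fit.ss_["ss_error"],
        "Nst": table["Nst"],
        "Nit": table["Nit"],
        "Net": table["Net"],
        "Nis": table["Nis"],
    }
    for name, v in targets.items():
        ok = np.isfinite(v) & np.isfinite(mean_expr)
        me_sd, v_sd = mean_expr[ok].std(), v[ok].std()
        me_flat = me_sd <= 1e-10 * (np.abs(mean_expr[ok]).max() + 1.0)
        v_flat = v_sd <= 1e-10 * (np.abs(v[ok]).max() + 1.0)
        if ok.sum() < 3 or me_flat or v_flat:
            rows.append({"statistic": name, "r": np.nan, "p": np.nan,
                         "r_squared": np.nan, "note": "undefined (constant input)"})
            continue
        r, p = stats.pearsonr(mean_expr[ok], v[ok])
        rows.append({"statistic": name, "r": r, "p": p, "r_squared": r * r, "note": ""})
    return pd.DataFrame(rows).set_index("statistic")
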