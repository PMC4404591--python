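"""Classification of expression profiles into selection-consistent modes.

A gene's profile is called consistent with

* directional selection when its among-group apportionment Nst exceeds the
  99th percentile of the individuals-among-groups permutation null
  (differential expression among groups);
* balancing selection when its Nig = SS_B/(SS_A+SS_B) exceeds the 99th
  percentile of the replicates-within-groups permutation null (high
  inter-individual, low among-group variation);
* stabilizing / diversifying selection when its inter-individual expression
  variance falls below the 1st / above the 99th percentile of an
  artificial-gene resampling null.

Neutral is the complement of the union.  These are profile classifications,
not formal tests of selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score

from ._utils import child_seed, is_exclusive_clade, linkage_to_newick, upgma_linkage
from .anova import NestedAnova
from .permutation import NullDistribution, null_nig, null_nst

__all__ = [
    "ArtificialGeneNull",
    "SelectionProfileClassifier",
    "artificial_gene_null",
    "classify_selection",
    "directional_structure_check",
]


class ArtificialGeneNull(BaseEstimator):
    """Resampling null for inter-individual expression variance.

    Every gene is first shifted to the global mean expression (additive
    centering), so that resampled profiles mix genes on a common scale.
    Each artificial gene draws, independently for every individual, the
    centered value of one uniformly chosen real gene; its variance is taken
    across all individuals with no regard for group membership.

    Attributes after ``fit(X)`` with X of shape (n_individuals, n_genes):

    variances_ : ndarray of artificial-gene variances
    cutoff_low_, cutoff_high_ : 1st / 99th percentile cutoffs
    gene_variances_ : Series of real-gene inter-individual variances
    """

    def __init__(self, n_artificial: int = 10_000, low_percentile: float = 1.0,
                 high_percentile: float = 99.0, random_state: int | None = None):
        self.n_artificial = n_artificial
        self.low_percentile = low_percentile
        self.high_percentile = high_percentile
        self.random_state = random_state

    def fit(self, X, y=None):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        n_ind, n_genes = X.shape
        if n_genes < 2:
            raise ValueError("need at least 2 genes to resample artificial genes")
        values = X.to_numpy(dtype=float)
        grand = values.mean()
        centered = values - values.mean(axis=0, keepdims=True) + grand
        rng = np.random.default_rng(self.random_state)
        picks = rng.integers(0, n_genes, size=(n_ind, self.n_artificial))
        draws = centered[np.arange(n_ind)[:, None], picks]
        self.variances_ = draws.var(axis=0, ddof=1)
        self.cutoff_low_ = float(np.percentile(self.variances_, self.low_percentile))
        self.cutoff_high_ = float(np.percentile(self.variances_, self.high_percentile))
        self.gene_variances_ = pd.Series(values.var(axis=0, ddof=1), index=X.columns,
                                         name="inter_individual_variance")
        return self


def artificial_gene_null(expr_by_individual: pd.DataFrame, n: int = 10_000,
                         seed: int | None = None) -> ArtificialGeneNull:
    """Functional wrapper; ``expr_by_individual`` is genes x individuals."""
    return ArtificialGeneNull(n_artificial=n, random_state=seed).fit(
        expr_by_individual.T
    )


def classify_selection(apportionment: pd.DataFrame,
                       nst_null: NullDistribution,
                       nig_null: NullDistribution,
                       var_null: ArtificialGeneNull,
                       gene_variances: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene boolean flags for the four selection modes plus neutral.

    Directional and the variance-based modes may overlap; stabilizing and
    diversifying are mutually exclusive by construction (disjoint tails).
    """
    for name, null in (("nst_null", nst_null), ("nig_null", nig_null),
                       ("var_null", var_null)):
        if null is None:
            raise ValueError(f"missing null distribution: {name}")
    if gene_variances is None:
        gene_variances = var_null.gene_variances_
    gene_variances = gene_variances.reindex(apportionment.index)
    calls = pd.DataFrame(index=apportionment.index)
    calls["directional"] = apportionment["Nst"] > nst_null.cutoff
    calls["balancing"] = apportionment["Nig"] > nig_null.cutoff
    calls["stabilizing"] = gene_variances < var_null.cutoff_low_
    calls["diversifying"] = gene_variances > var_null.cutoff_high_
    assert not (calls["stabilizing"] & calls["diversifying"]).any()
    calls["neutral"] = ~calls[
        ["directional", "balancing", "stabilizing", "diversifying"]
    ].any(axis=1)
    calls["Nst"] = apportionment["Nst"]
    calls["Nig"] = apportionment["Nig"]
    calls["inter_individual_variance"] = gene_variances
    return calls


def selection_summary(calls: pd.DataFrame) -> pd.Series:
    modes = ["neutral", "stabilizing", "directional", "diversifying", "balancing"]
    return pd.Series({m: calls[m].mean() for m in modes}, name="proportion")


class SelectionProfileClassifier(BaseEstimator):
    """End-to-end selection-profile classifier.

    ``fit(X, design, X_individual=None)`` takes library-level normalized
    expression X (n_libraries, n_genes); the inter-individual variance modes
    use X_individual (n_individuals, n_genes, independently renormalized
    replicate-summed data) when given, else the replicate mean of X.

    Attributes: ``apportionment_``, ``nst_null_``, ``nig_null_``,
    ``variance_null_``, ``calls_``, ``summary_``.
    """

    def __init__(self, n_permutations: int = 1000, genes_per_permutation: int = 100,
                 n_artificial: int = 10_000, percentile: float = 99.0,
                 covariates=("mapped_reads", "rin"), random_state: int | None = None):
        self.n_permutations = n_permutations
        self.genes_per_permutation = genes_per_permutation
        self.n_artificial = n_artificial
        self.percentile = percentile
        self.covariates = covariates
        self.random_state = random_state

    def fit(self, X, design: pd.DataFrame, X_individual: pd.DataFrame | None = None):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        design = design.loc[X.index]
        fit = NestedAnova(covariates=self.covariates).fit(X, design)
        expr = X.T  # genes x libraries for the permutation helpers
        self.nst_null_ = null_nst(
            expr, design, n_perm=self.n_permutations,
            genes_per_perm=self.genes_per_permutation,
            seed=child_seed(self.random_state, 0), covariates=self.covariates,
            percentile=self.percentile, _fit=fit)
        self.nig_null_ = null_nig(
            expr, design, n_perm=self.n_permutations,
            genes_per_perm=self.genes_per_permutation,
            seed=child_seed(self.random_state, 1), covariates=self.covariates,
            percentile=self.percentile, _fit=fit)
        if X_individual is None:
            X_individual = X.groupby(design["individual"]).mean()
        self.variance_null_ = ArtificialGeneNull(
            n_artificial=self.n_artificial,
            low_percentile=100.0 - self.percentile,
            high_percentile=self.percentile,
            random_state=child_seed(self.random_state, 2),
        ).fit(X_individual)
        self.anova_ = fit
        self.apportionment_ = fit.apportionment_
        self.calls_ = classify_selection(self.apportionment_, self.nst_null_,
                                         self.nig_null_, self.variance_null_)
        self.summary_ = selection_summary(self.calls_)
        return self


def directional_structure_check(expr_by_individual: pd.DataFrame,
                                design_individual: pd.DataFrame,
                                directional_genes) -> dict:
    """Group structure among individuals restricted to directional genes.

    Builds a UPGMA tree on the 1 - r expression distance, a PCA, and a
    silhouette score of the group labels on that distance; reports which
    groups form exclusive clades.
    """
    genes = [g for g in directional_genes if g in expr_by_individual.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 directional genes")
    sub = expr_by_individual.loc[genes]
    values = sub.to_numpy(dtype=float).T  # individuals x genes
    r = np.corrcoef(values)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = upgma_linkage(dist)
    individuals = sub.columns
    groups = design_individual.loc[individuals, "group"]
    pos = {ind: i for i, ind in enumerate(individuals)}
    monophyletic = {}
    degenerate = False
    for g, members in groups.groupby(groups):
        leaves = {pos[ind] for ind in members.index}
        if len(leaves) == 1:
            monophyletic[g] = True
            degenerate = True
        else:
            monophyletic[g] = is_exclusive_clade(z, len(individuals), leaves)
    sil = (silhouette_score(dist, groups.to_numpy(), metric="precomputed")
           if groups.nunique() > 1 and len(individuals) > groups.nunique()
           else np.nan)

    from .structure import pca_individuals

    pca = pca_individuals(pd.DataFrame(values, index=individuals, columns=genes))
    return {
        "newick": linkage_to_newick(z, list(individuals)),
        "linkage": z,
        "silhouette": float(sil) if np.isfinite(sil) else np.nan,
        "monophyletic": monophyletic,
        "degenerate": degenerate,
        "pca": pca,
        "n_genes": len(genes),
    }
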