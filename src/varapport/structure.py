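"""Global structure analyses: PCA with trait screening, population distance
dendrograms, and k-means partitioning of expression profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._utils import linkage_to_newick, upgma_linkage
from .anova import FullModelAnova, NestedAnova
from .io import design_traits

__all__ = [
    "PCAResult",
    "pca_individuals",
    "pc_trait_correlations",
    "population_distance_tree",
    "kmeans_profiles",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # individuals x PCs
    loadings: pd.DataFrame  # PCs x genes
    explained_ratio: pd.Series


def pca_individuals(X: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA over individuals (rows) on gene-centered expression.

    Sign convention: the largest-magnitude gene loading of each component is
    made positive, so scores are deterministic across runs and platforms.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    values = X.to_numpy(dtype=float)
    centered = values - values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components is None:
        n_components = rank
    n_components = min(n_components, rank)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    total = (centered**2).sum()
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=X.index, columns=pcs),
        loadings=pd.DataFrame(vt, index=pcs, columns=X.columns),
        explained_ratio=pd.Series(explained, index=pcs, name="explained_ratio"),
    )


def pc_trait_correlations(scores: pd.DataFrame, design_individual: pd.DataFrame,
                          n_pcs: int | None = None, traits=None) -> pd.DataFrame:
    """Pearson correlations between PC scores and traits, Bonferroni adjusted.

    The Bonferroni multiplier is the full tested grid n_pcs x n_traits
    (constant traits are skipped but still counted as planned tests only if
    actually tested; skipped tests are reported with a note).
    """
    if traits is None:
        traits = design_traits(design_individual)
    pcs = list(scores.columns[: n_pcs or len(scores.columns)])
    design_individual = design_individual.loc[scores.index]
    tested = []
    skipped = []
    for trait in traits:
        v = FullModelAnova._numeric(design_individual[trait])
        if np.std(v) == 0:
            skipped.append(trait)
            continue
        tested.append((trait, v))
    n_tests = len(pcs) * len(tested)
    rows = []
    for pc in pcs:
        sc = scores[pc].to_numpy(dtype=float)
        for trait, v in tested:
            r, p = stats.pearsonr(sc, v)
            rows.append({"pc": pc, "trait": trait, "r": r, "p": p,
                         "p_bonferroni": min(p * n_tests, 1.0), "note": ""})
        for trait in skipped:
            rows.append({"pc": pc, "trait": trait, "r": np.nan, "p": np.nan,
                         "p_bonferroni": np.nan, "note": "constant trait skipped"})
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = n_tests
    return out


@dataclass
class PopulationDistanceTree:
    distances: pd.DataFrame
    newick: str
    linkage: np.ndarray
    statistic: str
    weighting: str


def population_distance_tree(pairwise_fits: dict, statistic: str = "Nst",
                             weighting: str = "ss_total") -> PopulationDistanceTree:
    """UPGMA dendrogram of weighted mean pairwise apportionment distances.

    ``pairwise_fits`` maps (group1, group2) to a fitted NestedAnova.  The
    distance for a pair is the weighted mean of the per-gene statistic;
    weights are the pairwise per-gene total SS (default), per-gene mean
    expression, or uniform ("none").  Groups are ordered lexicographically,
    which also breaks agglomeration ties deterministically.
    """
    groups = sorted({g for pair in pairwise_fits for g in pair})
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            if (g1, g2) not in pairwise_fits and (g2, g1) not in pairwise_fits:
                raise ValueError(f"missing pairwise fit for ({g1}, {g2})")
    dist = pd.DataFrame(0.0, index=groups, columns=groups)
    for pair, fit in pairwise_fits.items():
        fit_obj: NestedAnova = fit
        table = fit_obj.apportionment_
        stat = table[statistic]
        ok = np.isfinite(stat)
        if weighting == "ss_total":
            w = fit_obj.ss_["ss_total"]
        elif weighting == "mean_expression":
            w = table["mean_expression"]
        elif weighting == "none":
            w = pd.Series(1.0, index=table.index)
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        w = w.where(ok, 0.0)
        d = float((stat.fillna(0.0) * w).sum() / w.sum())
        g1, g2 = pair
        dist.loc[g1, g2] = dist.loc[g2, g1] = d
    z = upgma_linkage(dist.to_numpy())
    return PopulationDistanceTree(
        distances=dist, newick=linkage_to_newick(z, groups), linkage=z,
        statistic=statistic, weighting=weighting,
    )


def kmeans_profiles(expr_by_individual: pd.DataFrame, design_individual: pd.DataFrame,
                    gene_set=None, k: int = 2, seed: int | None = None,
                    n_init: int = 10) -> dict:
    """k-means partitioning of per-gene standardized expression profiles.

    Each gene (row) is standardized to mean 0, sd 1 across individuals
    before clustering.  Returns per-gene labels, the per-cluster mean
    standardized profile, and its group-mean summary.
    """
    if gene_set is not None:
        genes = [g for g in gene_set if g in expr_by_individual.index]
        expr_by_individual = expr_by_individual.loc[genes]
    if expr_by_individual.empty:
        raise ValueError("gene set is empty")
    if k > len(expr_by_individual):
        raise ValueError(f"k={k} exceeds the number of genes")
    values = expr_by_individual.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
    labels = pd.Series(km.labels_, index=expr_by_individual.index, name="cluster")
    profiles = pd.DataFrame(km.cluster_centers_, columns=expr_by_individual.columns)
    profiles.index.name = "cluster"
    groups = design_individual.loc[expr_by_individual.columns, "group"]
    group_profiles = profiles.T.groupby(groups).mean().T
    return {"labels": labels, "profiles": profiles,
            "group_profiles": group_profiles, "inertia": float(km.inertia_),
            "model": km}
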