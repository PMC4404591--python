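"""Replicate-pairing quality control.

Libraries are clustered by average linkage on the expression distance
1 - |r| (Pearson correlation across genes).  An individual passes QC when
its replicate libraries form an exclusive subtree (a cherry for two
replicates); individuals whose replicates scatter are flagged for removal,
the interpretation being dissection or processing error.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import is_exclusive_clade, linkage_to_newick, upgma_linkage


class ReplicatePairingQC(BaseEstimator):
    """Flag individuals whose replicate libraries do not cluster together.

    Attributes after ``fit(X, design)`` with X (n_libraries, n_genes):

    distance_matrix_ : DataFrame, 1 - |r| between libraries
    linkage_ : scipy average-linkage matrix
    tree_newick_ : str
    paired_ : Series of bool per individual
    dropped_individuals_ : list of individuals failing QC
    """

    def __init__(self, linkage_method: str = "average"):
        self.linkage_method = linkage_method

    def fit(self, X, design: pd.DataFrame):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        design = design.loc[X.index]
        counts_per_ind = design.groupby("individual").size()
        if (counts_per_ind < 2).any():
            bad = counts_per_ind[counts_per_ind < 2].index.tolist()
            raise ValueError(f"individuals with fewer than 2 replicates: {bad}")

        values = X.to_numpy(dtype=float)
        sd = values.std(axis=1)
        constant = sd <= 1e-10 * (np.abs(values).max(axis=1) + 1.0)
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant libraries: correlation undefined, "
                "distance set to 1"
            )
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(values)
        dist = 1.0 - np.abs(r)
        dist[np.isnan(dist)] = 1.0
        dist[constant, :] = 1.0
        dist[:, constant] = 1.0
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)

        z = upgma_linkage(dist)
        libs = X.index
        lib_pos = {lib: i for i, lib in enumerate(libs)}
        paired = {}
        for ind, sub in design.groupby("individual"):
            leaf_set = {lib_pos[lib] for lib in sub.index}
            paired[ind] = is_exclusive_clade(z, len(libs), leaf_set)

        self.distance_matrix_ = pd.DataFrame(dist, index=libs, columns=libs)
        self.linkage_ = z
        self.tree_newick_ = linkage_to_newick(z, list(libs))
        self.paired_ = pd.Series(paired, name="paired").sort_index()
        self.dropped_individuals_ = sorted(self.paired_.index[~self.paired_])
        return self

    def filter(self, counts: pd.DataFrame, design: pd.DataFrame):
        """Drop all libraries of unpaired individuals from counts and design."""
        keep = ~design["individual"].isin(self.dropped_individuals_)
        design_f = design.loc[keep]
        return counts[design_f.index], design_f

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"paired": self.paired_,
             "dropped": self.paired_.index.isin(self.dropped_individuals_)}
        )


def replicate_qc(expr: pd.DataFrame, design: pd.DataFrame,
                 linkage_method: str = "average") -> ReplicatePairingQC:
    """Functional wrapper; ``expr`` is genes x libraries."""
    return ReplicatePairingQC(linkage_method=linkage_method).fit(expr.T, design)
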