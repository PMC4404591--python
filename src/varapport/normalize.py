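"""Library-depth normalization and variance stabilization.

Counts are scaled by median-of-ratios size factors and transformed with a
shifted log2 (default pseudocount 1).  The transform is deterministic and
monotone; the method and pseudocount are recorded in the provenance dict
attached to every normalized matrix (``matrix.attrs['normalization']``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, one per library (column).

    The reference is the per-gene geometric mean across libraries; only genes
    expressed in every library (positive geometric mean) enter the medians.
    With ``allow_pseudo_reference`` the geometric mean is computed on
    count+0.5 instead, for data sets where no gene is ubiquitously expressed.
    """
    values = counts.to_numpy(dtype=float)
    if allow_pseudo_reference:
        log_ref = np.log(values + 0.5).mean(axis=1)
        usable = np.ones(len(log_ref), dtype=bool)
        values = values + 0.5
    else:
        with np.errstate(divide="ignore"):
            log_ref = np.log(values).mean(axis=1)
        usable = np.isfinite(log_ref)
        if not usable.any():
            raise ValueError(
                "no gene has a nonzero count in every library; "
                "re-run with allow_pseudo_reference=True"
            )
    ratios = values[usable] / np.exp(log_ref[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor encountered")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def variance_stabilize(
    counts: pd.DataFrame, factors: pd.Series | None = None, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), genes x libraries."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all libraries")
    expr = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy() + pseudocount)
    out = pd.DataFrame(expr, index=counts.index, columns=counts.columns)
    out.attrs["normalization"] = {
        "method": "median_of_ratios_shifted_log2",
        "pseudocount": pseudocount,
    }
    return out


def sum_replicates(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate library counts within each individual.

    Returns a genes x individuals count matrix; total reads are conserved.
    Individual-level analyses re-normalize this matrix independently.
    """
    groups = design.loc[counts.columns, "individual"]
    return counts.T.groupby(groups).sum().T


def individual_design(design: pd.DataFrame) -> pd.DataFrame:
    """Collapse a library-level design to one row per individual.

    Technical covariates are summed (mapped_reads) or averaged (rin); traits
    are constant within individual and taken from the first library.
    """
    agg = {c: "first" for c in design.columns}
    agg["mapped_reads"] = "sum"
    agg["rin"] = "mean"
    out = design.groupby("individual").agg(agg)
    out = out.drop(columns=["individual"], errors="ignore")
    out.index.name = "individual"
    return out


def normalize_individuals(
    counts: pd.DataFrame, design: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Replicate-summed counts, independently size-factor normalized and logged."""
    summed = sum_replicates(counts, design)
    return variance_stabilize(summed, pseudocount=pseudocount)


class SizeFactorLogNormalizer(BaseEstimator, TransformerMixin):
    """Transformer form of the normalization for sklearn pipelines.

    Operates on X of shape (n_libraries, n_genes).  ``fit`` learns one size
    factor per library from X itself, so transform is meant for the same
    libraries (per-sample scaling, unlike feature-wise sklearn scalers).
    """

    def __init__(self, pseudocount: float = 1.0, allow_pseudo_reference: bool = False):
        self.pseudocount = pseudocount
        self.allow_pseudo_reference = allow_pseudo_reference

    def fit(self, X, y=None):
        counts = self._as_frame(X)
        self.size_factors_ = size_factors(
            counts, allow_pseudo_reference=self.allow_pseudo_reference
        )
        self.n_features_in_ = counts.shape[0]
        return self

    def transform(self, X):
        counts = self._as_frame(X)
        expr = variance_stabilize(counts, self.size_factors_, self.pseudocount)
        return expr.T if isinstance(X, pd.DataFrame) else expr.to_numpy().T

    @staticmethod
    def _as_frame(X):
        # transpose to the genes x libraries layout used by the functions
        if isinstance(X, pd.DataFrame):
            return X.T
        return pd.DataFrame(np.asarray(X).T)
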