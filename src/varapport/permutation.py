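"""Permutation null distributions for the apportionment statistics.

Four resampling schemes, each destroying exactly one stratum of structure:

* individuals_among_groups — whole individuals (replicates travel together)
  are reassigned to groups of the original sizes; nulls for Nst.
* replicates_within_groups — replicate libraries are shuffled among
  individuals within each group, randomizing inter-individual differences;
  nulls for Nig (and mean Nit).
* libraries_among_individuals — alias of the scheme above used for the
  mean-level Nit p-value.
* reads_among_replicates — each individual's per-gene read total is
  redistributed among its replicate libraries multinomially in proportion
  to library depth, then renormalized; nulls for mean Net.

Cutoffs are empirical percentiles (linear interpolation) of the pooled
permuted statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import NestedAnova, NestedIndex, nested_ss
from .normalize import variance_stabilize

__all__ = [
    "NullDistribution",
    "null_nst",
    "null_nig",
    "mean_apportionment_pvalues",
    "de_genes_pairwise",
]


@dataclass
class NullDistribution:
    scheme: str
    statistic: str
    n_permutations: int
    genes_per_permutation: int
    samples: np.ndarray
    percentile: float = 99.0
    seed: int | None = None
    degenerate: bool = field(default=False)

    @property
    def cutoff(self) -> float:
        if self.samples.size == 0:
            return float("nan")
        return float(np.percentile(self.samples, self.percentile))

    def percentile_cutoff(self, q: float) -> float:
        return float(np.percentile(self.samples, q))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.statistic: self.samples})


def _prepare(expr: pd.DataFrame, design: pd.DataFrame, covariates):
    """Fit once to residualize covariates; permutations reuse the residuals."""
    fit = NestedAnova(covariates=covariates).fit(expr.T, design)
    return fit


def _permute_groups(idx: NestedIndex, rng):
    """Reassign whole individuals to groups, preserving group sizes."""
    perm = rng.permutation(idx.n_individuals)
    new_indiv_group = idx.indiv_group[perm]
    return new_indiv_group[idx.indiv_codes]


def _permute_individuals_within_groups(idx: NestedIndex, rng):
    """Shuffle library -> individual assignment within each group."""
    new_codes = idx.indiv_codes.copy()
    for g in range(idx.n_groups):
        libs = np.flatnonzero(idx.group_codes == g)
        new_codes[libs] = new_codes[libs[rng.permutation(len(libs))]]
    return new_codes


def null_nst(expr: pd.DataFrame, design: pd.DataFrame, n_perm: int = 1000,
             genes_per_perm: int = 100, seed: int | None = None,
             covariates=("mapped_reads", "rin"), percentile: float = 99.0,
             _fit: NestedAnova | None = None) -> NullDistribution:
    """Null Nst from permuting individuals among groups."""
    fit = _fit or _prepare(expr, design, covariates)
    idx = fit.index_
    if idx.n_groups < 2:
        raise ValueError("cannot permute a single-group design")
    resid = fit.residual_.to_numpy()
    n_genes = resid.shape[1]
    if genes_per_perm > n_genes:
        warnings.warn("genes_per_perm exceeds the number of genes; capping")
        genes_per_perm = n_genes
    rng = np.random.default_rng(seed)
    samples = np.empty(n_perm * genes_per_perm)
    for p in range(n_perm):
        gidx = rng.choice(n_genes, size=genes_per_perm, replace=False)
        gcodes = _permute_groups(idx, rng)
        ss_a, ss_b, ss_e = nested_ss(resid[:, gidx], gcodes, idx.indiv_codes)
        tot = ss_a + ss_b + ss_e
        with np.errstate(invalid="ignore", divide="ignore"):
            samples[p * genes_per_perm:(p + 1) * genes_per_perm] = ss_a / tot
    samples = samples[np.isfinite(samples)]
    return NullDistribution("individuals_among_groups", "Nst", n_perm,
                            genes_per_perm, samples, percentile, seed)


def null_nig(expr: pd.DataFrame, design: pd.DataFrame, n_perm: int = 1000,
             genes_per_perm: int = 100, seed: int | None = None,
             covariates=("mapped_reads", "rin"), percentile: float = 99.0,
             _fit: NestedAnova | None = None) -> NullDistribution:
    """Null Nig from shuffling replicates among individuals within groups."""
    fit = _fit or _prepare(expr, design, covariates)
    idx = fit.index_
    counts_per_ind = np.bincount(idx.indiv_codes)
    if (counts_per_ind < 2).any():
        raise ValueError("every individual needs >= 2 replicate libraries")
    resid = fit.residual_.to_numpy()
    n_genes = resid.shape[1]
    if genes_per_perm > n_genes:
        warnings.warn("genes_per_perm exceeds the number of genes; capping")
        genes_per_perm = n_genes
    rng = np.random.default_rng(seed)
    samples = np.empty(n_perm * genes_per_perm)
    for p in range(n_perm):
        gidx = rng.choice(n_genes, size=genes_per_perm, replace=False)
        icodes = _permute_individuals_within_groups(idx, rng)
        ss_a, ss_b, ss_e = nested_ss(resid[:, gidx], idx.group_codes, icodes)
        with np.errstate(invalid="ignore", divide="ignore"):
            samples[p * genes_per_perm:(p + 1) * genes_per_perm] = (
                ss_b / (ss_a + ss_b)
            )
    samples = samples[np.isfinite(samples)]
    dist = NullDistribution("replicates_within_groups", "Nig", n_perm,
                            genes_per_perm, samples, percentile, seed)
    if samples.size == 0 or np.ptp(samples) < 1e-12:
        dist.degenerate = True
        warnings.warn("permutation left the data invariant; Nig null is degenerate")
    return dist


def _redistribute_reads(counts: pd.DataFrame, design: pd.DataFrame, rng):
    """Pool each individual's per-gene reads and split them among its
    replicate libraries multinomially, proportional to library depth."""
    values = counts.to_numpy()
    new = np.empty_like(values)
    depths = counts.sum(axis=0).to_numpy(dtype=float)
    cols = {lib: i for i, lib in enumerate(counts.columns)}
    for _, sub in design.groupby("individual"):
        lib_idx = [cols[lib] for lib in sub.index]
        total = values[:, lib_idx].sum(axis=1)
        remaining = total.copy()
        weight_left = depths[lib_idx].sum()
        for j in lib_idx[:-1]:
            p = depths[j] / weight_left
            draw = rng.binomial(remaining, p)
            new[:, j] = draw
            remaining = remaining - draw
            weight_left -= depths[j]
        new[:, lib_idx[-1]] = remaining
    return pd.DataFrame(new, index=counts.index, columns=counts.columns)


def mean_apportionment_pvalues(expr: pd.DataFrame, design: pd.DataFrame,
                               counts: pd.DataFrame | None = None,
                               n_perm: int = 1000, seed: int | None = None,
                               covariates=("mapped_reads", "rin"),
                               pseudocount: float = 1.0) -> dict:
    """Permutation p-values for the mean Nst, Nit and Net across all genes.

    Each scheme permutes the stratum it tests: individuals among groups
    (Nst), libraries among individuals within groups (Nit), and reads among
    replicates (Net; requires raw counts).  p-values use the add-one
    convention (1 + exceedances) / (n_perm + 1).
    """
    fit = _prepare(expr, design, covariates)
    idx = fit.index_
    resid = fit.residual_.to_numpy()
    app = fit.apportionment_
    observed = {
        "Nst": float(app["Nst"].mean()),
        "Nit": float(app["Nit"].mean()),
        "Net": float(app["Net"].mean()),
    }
    rng = np.random.default_rng(seed)
    exceed = {"Nst": 0, "Nit": 0}
    for _ in range(n_perm):
        gcodes = _permute_groups(idx, rng)
        ss_a, ss_b, ss_e = nested_ss(resid, gcodes, idx.indiv_codes)
        tot = ss_a + ss_b + ss_e
        with np.errstate(invalid="ignore", divide="ignore"):
            if np.nanmean(ss_a / tot) >= observed["Nst"]:
                exceed["Nst"] += 1
        icodes = _permute_individuals_within_groups(idx, rng)
        ss_a, ss_b, ss_e = nested_ss(resid, idx.group_codes, icodes)
        tot = ss_a + ss_b + ss_e
        with np.errstate(invalid="ignore", divide="ignore"):
            if np.nanmean(ss_b / tot) >= observed["Nit"]:
                exceed["Nit"] += 1
    out = {
        "Nst": (1 + exceed["Nst"]) / (n_perm + 1),
        "Nit": (1 + exceed["Nit"]) / (n_perm + 1),
    }
    if counts is not None:
        counts = counts[design.index]
        hits = 0
        for _ in range(n_perm):
            shuffled = _redistribute_reads(counts, design, rng)
            perm_expr = variance_stabilize(shuffled, pseudocount=pseudocount)
            pf = NestedAnova(covariates=covariates).fit(perm_expr.T, design)
            if float(pf.apportionment_["Net"].mean()) >= observed["Net"]:
                hits += 1
        out["Net"] = (1 + hits) / (n_perm + 1)
    out["observed"] = observed
    out["n_permutations"] = n_perm
    return out


def de_genes_pairwise(expr: pd.DataFrame, design: pd.DataFrame,
                      n_perm: int = 1000, genes_per_perm: int = 100,
                      seed: int | None = None, percentile: float = 99.0,
                      covariates=("mapped_reads", "rin")) -> dict:
    """Differentially expressed genes per group pair via pair-specific
    permutation Nst cutoffs; returns per-pair calls and their union."""
    groups = sorted(pd.unique(design["group"]))
    rng = np.random.default_rng(seed)
    per_pair = {}
    union: set = set()
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            sub_design = design[design["group"].isin((g1, g2))]
            sub_expr = expr[sub_design.index]
            fit = NestedAnova(covariates=covariates).fit(sub_expr.T, sub_design)
            child = int(rng.integers(0, 2**31 - 1))
            null = null_nst(sub_expr, sub_design, n_perm=n_perm,
                            genes_per_perm=genes_per_perm, seed=child,
                            covariates=covariates, percentile=percentile,
                            _fit=fit)
            obs = fit.apportionment_["Nst"]
            genes = set(obs.index[obs > null.cutoff])
            per_pair[(g1, g2)] = {"genes": genes, "cutoff": null.cutoff,
                                  "null": null}
            union |= genes
    return {"pairs": per_pair, "union": union}
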