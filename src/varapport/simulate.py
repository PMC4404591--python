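"""Synthetic hierarchical RNA-seq experiments with known variance components.

The generator emulates the replicated, nested design of a multi-group
tissue study: groups contain individuals, individuals contribute replicate
dissection libraries.  For each gene g a latent log2 expression is drawn as

    y_ijk = mu_g + A_i + B_ij + e_ijk + bx * x_std + bz * z_std

with A ~ N(0, s2_A), B ~ N(0, s2_B), e ~ N(0, s2_e) and small technical
contributions from standardized log library size (x) and RIN (z).  Counts
are negative binomial with mean proportional to 2^latent times library size
and a mean-dependent dispersion.  The latent matrix (the model's y) and the
per-gene truth record are retained so estimators can be validated against
the generating components.

Selection regimes overwrite components for disjoint gene blocks:

* directional — fixed per-group mean shifts in log2 units;
* balancing — inflated s2_B with s2_A pinned at zero;
* stabilizing — s2_B and s2_e shrunk by a common factor;
* diversifying — s2_B inflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import TRAIT_COLUMNS

__all__ = [
    "SimulationConfig",
    "SelectionRegime",
    "TraitEffect",
    "SyntheticDataset",
    "generate_dataset",
    "export_fixture",
    "default_dispersion",
]


def default_dispersion(mean):
    """Mean-dependent NB dispersion a + b/mean (BCV^2 ~ 0.01 at high depth)."""
    return 0.01 + 0.5 / np.maximum(np.asarray(mean, dtype=float), 1e-8)


@dataclass
class TraitEffect:
    """A biological trait influencing a fraction of genes.

    ``sampler(rng, n_individuals)`` draws per-individual trait values;
    affected genes get a slope ~ N(0, effect_sd^2) per standardized trait unit.
    """

    name: str
    sampler: object
    effect_sd: float = 0.2
    fraction: float = 0.05


@dataclass
class SimulationConfig:
    n_groups: int = 4
    n_individuals_per_group: int = 10
    n_replicates: int = 2
    n_genes: int = 2000
    baseline_log_mean_range: tuple = (0.0, 12.0)
    sigma2_A: object = 0.02
    sigma2_B: object = 0.15
    sigma2_e: object = 0.08
    #: linear coupling of sigma2_e to baseline log2 expression (per log2 unit,
    #: relative): emulates replicate variability growing with expression level
    sigma2_e_mean_slope: float = 0.0
    nb_dispersion_model: object = None  # None -> default_dispersion
    library_size_range: tuple = (1_200_000, 1_700_000)
    rin_range: tuple = (7.0, 10.0)
    beta_mapped_reads: float = 0.07  # log2 units per SD of log library size
    beta_rin: float = 0.07
    trait_effects: list = field(default_factory=list)
    include_traits: bool = True
    seed: int = 0

    def validate(self):
        for name in ("n_groups", "n_individuals_per_group", "n_replicates", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("library_size_range", "rin_range", "baseline_log_mean_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} must be a non-empty interval")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be strictly positive")
        for eff in self.trait_effects:
            if not 0.0 <= eff.fraction <= 1.0:
                raise ValueError(f"trait {eff.name}: fraction must be in [0, 1]")


_REGIME_DEFAULTS = {
    "directional": {"group_shifts": None, "shift": 2.0,
                    "per_gene_patterns": False},
    "balancing": {"sigma2_B_factor": 5.0, "sigma2_A_value": 0.0,
                  "center_group_means": True},
    "stabilizing": {"shrink_factor": 0.1},
    "diversifying": {"sigma2_B_factor": 5.0},
}


@dataclass
class SelectionRegime:
    mode: str
    n_genes: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in _REGIME_DEFAULTS and self.mode != "neutral":
            raise ValueError(f"unknown selection mode {self.mode!r}")
        merged = dict(_REGIME_DEFAULTS.get(self.mode, {}))
        merged.update(self.parameters)
        self.parameters = merged


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame  # genes x libraries, int
    design: pd.DataFrame  # library-level metadata
    truth: pd.DataFrame  # per-gene components, regime, expected M statistics
    latent: pd.DataFrame  # genes x libraries latent log2 expression (the model's y)
    config: SimulationConfig
    seed: int


def _resolve_components(spec, n_genes, rng):
    """Scalar, array, callable(rng, n) or frozen distribution -> per-gene array."""
    if callable(spec):
        arr = np.asarray(spec(rng, n_genes), dtype=float)
    elif hasattr(spec, "rvs"):
        arr = np.asarray(spec.rvs(size=n_genes, random_state=rng), dtype=float)
    elif np.ndim(spec) == 0:
        arr = np.full(n_genes, float(spec))
    else:
        arr = np.asarray(spec, dtype=float)
    if arr.shape != (n_genes,):
        raise ValueError("variance component spec must yield one value per gene")
    if (arr < 0).any():
        raise ValueError("variance components must be non-negative")
    return arr


def _default_trait_table(rng, individuals):
    n = len(individuals)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),
            "weight": np.round(rng.normal(3.4, 0.45, n), 3),
            "length": np.round(rng.normal(50.0, 2.5, n), 1),
            "cesarean": (rng.random(n) < 0.3).astype(int),
            "maternal_age": np.round(rng.normal(30.0, 5.0, n), 1),
            "bmi": np.round(rng.normal(25.0, 4.0, n), 2),
            "alcohol": (rng.random(n) < 0.3).astype(int),
            "vegetarian": (rng.random(n) < 0.15).astype(int),
        },
        index=individuals,
    )


def generate_dataset(config: SimulationConfig, regimes=()) -> SyntheticDataset:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    total_regime = sum(r.n_genes for r in regimes)
    if total_regime > n_genes:
        raise ValueError("selection regimes request more genes than n_genes")

    # --- design ------------------------------------------------------------
    groups, individuals, libraries, lib_group, lib_indiv = [], [], [], [], []
    for gi in range(config.n_groups):
        gname = f"G{gi + 1}"
        groups.append(gname)
        for ii in range(config.n_individuals_per_group):
            ind = f"{gname}_I{ii + 1:02d}"
            individuals.append(ind)
            for ri in range(config.n_replicates):
                libraries.append(f"{ind}_R{ri + 1}")
                lib_group.append(gname)
                lib_indiv.append(ind)
    n_lib = len(libraries)
    mapped = rng.integers(config.library_size_range[0],
                          config.library_size_range[1] + 1, n_lib)
    rin = np.round(rng.uniform(*config.rin_range, n_lib), 2)
    design = pd.DataFrame(
        {"individual": lib_indiv, "group": lib_group,
         "mapped_reads": mapped, "rin": rin},
        index=pd.Index(libraries, name="library_id"),
    )
    if config.include_traits:
        trait_table = _default_trait_table(rng, pd.Index(individuals, name="individual"))
        for col in TRAIT_COLUMNS:
            design[col] = trait_table.loc[design["individual"], col].to_numpy()
    else:
        trait_table = pd.DataFrame(index=pd.Index(individuals, name="individual"))

    # --- per-gene components and regimes -----------------------------------
    s2_a = _resolve_components(config.sigma2_A, n_genes, rng)
    s2_b = _resolve_components(config.sigma2_B, n_genes, rng)
    s2_e = _resolve_components(config.sigma2_e, n_genes, rng)
    regime_label = np.array(["neutral"] * n_genes, dtype=object)
    shifts = np.zeros((config.n_groups, n_genes))
    balancing_centered = np.zeros(n_genes, dtype=bool)

    perm = rng.permutation(n_genes)
    cursor = 0
    for regime in regimes:
        idx = perm[cursor:cursor + regime.n_genes]
        cursor += regime.n_genes
        regime_label[idx] = regime.mode
        p = regime.parameters
        if regime.mode == "directional":
            gs = p["group_shifts"]
            if gs is None:
                gs = [0.0] * (config.n_groups - 1) + [p["shift"]]
            gs = np.asarray(gs, dtype=float)
            if gs.shape != (config.n_groups,):
                raise ValueError("group_shifts must give one shift per group")
            if p.get("per_gene_patterns", False):
                # each gene realizes its own group ordering of the shifts,
                # so directional genes carry diverse group patterns
                for g in idx:
                    shifts[:, g] = rng.permutation(gs)
            else:
                shifts[:, idx] = gs[:, None]
        elif regime.mode == "balancing":
            s2_b[idx] *= p["sigma2_B_factor"]
            s2_a[idx] = p["sigma2_A_value"]
            # balancing maintains equal population means: realized group
            # means of the individual effects are pinned to zero, not just
            # their expectation (see the methods note)
            balancing_centered[idx] = p.get("center_group_means", True)
        elif regime.mode == "stabilizing":
            s2_b[idx] *= p["shrink_factor"]
            s2_e[idx] *= p["shrink_factor"]
        elif regime.mode == "diversifying":
            s2_b[idx] *= p["sigma2_B_factor"]

    # --- latent expression ---------------------------------------------------
    gene_ids = pd.Index([f"gene_{i + 1:05d}" for i in range(n_genes)], name="gene_id")
    baseline = rng.uniform(*config.baseline_log_mean_range, n_genes)
    if config.sigma2_e_mean_slope:
        factor = 1.0 + config.sigma2_e_mean_slope * (baseline - baseline.mean())
        s2_e = s2_e * np.clip(factor, 0.05, None)
    A = rng.standard_normal((config.n_groups, n_genes)) * np.sqrt(s2_a) + shifts
    n_ind = len(individuals)
    B = rng.standard_normal((n_ind, n_genes)) * np.sqrt(s2_b)
    if balancing_centered.any():
        ind_group = np.repeat(np.arange(config.n_groups),
                              config.n_individuals_per_group)
        cols = np.flatnonzero(balancing_centered)
        for g in range(config.n_groups):
            members = ind_group == g
            B[np.ix_(members, cols)] -= B[np.ix_(members, cols)].mean(axis=0)
    E = rng.standard_normal((n_lib, n_genes)) * np.sqrt(s2_e)

    gcode = pd.Index(groups).get_indexer(lib_group)
    icode = pd.Index(individuals).get_indexer(lib_indiv)
    log_size = np.log(mapped.astype(float))
    x_std = (log_size - log_size.mean()) / (log_size.std() or 1.0)
    z_std = (rin - rin.mean()) / (rin.std() or 1.0)
    tech = config.beta_mapped_reads * x_std + config.beta_rin * z_std

    latent = baseline[None, :] + A[gcode] + B[icode] + E + tech[:, None]

    # trait effects act at the individual level on affected genes
    for eff in config.trait_effects:
        values = np.asarray(eff.sampler(rng, n_ind), dtype=float)
        sd = values.std() or 1.0
        t_std = (values - values.mean()) / sd
        n_aff = int(round(eff.fraction * n_genes))
        affected = rng.choice(n_genes, size=n_aff, replace=False)
        slopes = rng.normal(0.0, eff.effect_sd, n_aff)
        latent[:, affected] += np.outer(t_std[icode], slopes)
        design[eff.name] = values[icode]
        trait_table[eff.name] = values

    # --- counts ---------------------------------------------------------------
    weights = np.exp2(latent)
    props = weights / weights.sum(axis=1, keepdims=True)
    mu = props * mapped[:, None].astype(float)
    model = config.nb_dispersion_model or default_dispersion
    disp = np.broadcast_to(np.asarray(model(mu), dtype=float), mu.shape)
    if (disp < 0).any():
        lib_i, gene_i = np.argwhere(disp < 0)[0]
        raise ValueError(
            f"dispersion model returned a negative dispersion for gene "
            f"{gene_ids[gene_i]!r} (mean count {mu[lib_i, gene_i]:.3f})"
        )
    counts = np.empty(mu.shape, dtype=np.int64)
    pois = disp <= 0
    counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        shape = 1.0 / disp[~pois]
        lam = rng.gamma(shape, mu[~pois] * disp[~pois])
        counts[~pois] = rng.poisson(lam)

    # --- truth ----------------------------------------------------------------
    shift_var = shifts.var(axis=0)  # fixed-effect among-group variance
    s2_a_eff = s2_a + shift_var
    s2_t = s2_a_eff + s2_b + s2_e
    with np.errstate(divide="ignore", invalid="ignore"):
        truth = pd.DataFrame(
            {
                "sigma2_group": s2_a_eff,
                "sigma2_individual": s2_b,
                "sigma2_error": s2_e,
                "regime": regime_label,
                "expected_Mst": np.where(s2_t > 0, s2_a_eff / s2_t, np.nan),
                "expected_Mit": np.where(s2_t > 0, s2_b / s2_t, np.nan),
                "expected_Met": np.where(s2_t > 0, s2_e / s2_t, np.nan),
            },
            index=gene_ids,
        )

    lib_cols = design.index.rename(None)
    counts_df = pd.DataFrame(counts.T, index=gene_ids, columns=lib_cols)
    latent_df = pd.DataFrame(latent.T, index=gene_ids, columns=lib_cols)
    return SyntheticDataset(counts=counts_df, design=design, truth=truth,
                            latent=latent_df, config=config, seed=config.seed)


def export_fixture(dataset: SyntheticDataset, directory, overwrite: bool = False):
    """Write counts.tsv, design.tsv, truth.tsv and a config echo (YAML)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.tsv" for name in ("counts", "design", "truth")}
    paths["config"] = directory / "config.yaml"
    existing = [str(p) for p in paths.values() if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(f"refusing to overwrite existing files: {existing}")
    dataset.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    dataset.design.to_csv(paths["design"], sep="\t", index_label="library_id")
    dataset.truth.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    echo = asdict(dataset.config)
    echo["nb_dispersion_model"] = getattr(
        dataset.config.nb_dispersion_model, "__name__", "default_dispersion"
    )
    echo["trait_effects"] = [
        {"name": e.name, "effect_sd": e.effect_sd, "fraction": e.fraction}
        for e in dataset.config.trait_effects
    ]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return paths
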