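"""End-to-end pipeline: (simulate|ingest) -> QC -> apportionment ->
permutation nulls -> selection calls -> structure analyses.

Every stage is a pure function of (inputs, config, master seed); per-stage
seeds are spawned deterministically from the master seed, and a manifest
with parameters, seeds and output checksums is written for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._utils import child_seed
from . import io as vio
from .anova import (NestedAnova, fit_full_model, mean_expression_diagnostics,
                    pairwise_apportionments)
from .normalize import normalize_individuals, individual_design, variance_stabilize
from .permutation import de_genes_pairwise, mean_apportionment_pvalues
from .qc import ReplicatePairingQC
from .selection import SelectionProfileClassifier, directional_structure_check
from .simulate import SelectionRegime, SimulationConfig, generate_dataset
from .structure import (kmeans_profiles, pc_trait_correlations, pca_individuals,
                        population_distance_tree)

log = logging.getLogger("varapport")


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    design_path: str | None = None
    simulate: SimulationConfig | None = None
    regimes: list = field(default_factory=list)
    pseudocount: float = 1.0
    covariates: tuple = ("mapped_reads", "rin")
    drop_unpaired: bool = True
    n_permutations: int = 1000
    genes_per_permutation: int = 100
    n_artificial: int = 10_000
    mean_pvalue_permutations: int = 200
    fdr: float = 0.05
    kmeans_k: int = 2
    output_dir: str = "varapport_out"
    seed: int = 0

    def validate(self):
        has_paths = self.counts_path is not None and self.design_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValueError(
                "exactly one of (counts_path+design_path, simulate) must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        regimes = [SelectionRegime(**r) for r in raw.pop("regimes", [])]
        cfg = cls(**raw, regimes=regimes,
                  simulate=SimulationConfig(**sim) if sim else None)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": {}, "seed": config.seed, "outputs": {}}
    results: dict = {"output_dir": out}
    stage_names = []

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed after stages "
                    f"{stage_names}: {exc}"
                ) from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
            stage_names.append(name)
            log.info("stage %s done in %.2fs", name, time.time() - t0)

        return wrap

    # --- input -------------------------------------------------------------
    @stage("input")
    def _input():
        if config.simulate is not None:
            sim_cfg = config.simulate
            sim_cfg.seed = child_seed(config.seed, 0)
            dataset = generate_dataset(sim_cfg, config.regimes)
            results["counts"] = dataset.counts
            results["design"] = dataset.design
            results["truth"] = dataset.truth
            dataset.truth.to_csv(out / "truth.tsv", sep="\t")
        else:
            results["counts"] = vio.read_counts(config.counts_path)
            results["design"] = vio.read_design(config.design_path)
        vio.check_counts_match_design(results["counts"], results["design"])

    # --- normalization + QC --------------------------------------------------
    @stage("qc")
    def _qc():
        counts, design = results["counts"], results["design"]
        expr = variance_stabilize(counts, pseudocount=config.pseudocount)
        qc = ReplicatePairingQC().fit(expr.T, design)
        qc.report().to_csv(out / "replicate_qc.tsv", sep="\t")
        (out / "library_tree.nwk").write_text(qc.tree_newick_ + "\n")
        if config.drop_unpaired and qc.dropped_individuals_:
            counts, design = qc.filter(counts, design)
            log.info("dropped unpaired individuals: %s", qc.dropped_individuals_)
        results["qc"] = qc
        results["counts_qc"], results["design_qc"] = counts, design
        results["expr"] = variance_stabilize(counts, pseudocount=config.pseudocount)
        results["expr_individual"] = normalize_individuals(
            counts, design, pseudocount=config.pseudocount)
        results["design_individual"] = individual_design(design)

    # --- apportionment -------------------------------------------------------
    @stage("apportion")
    def _apportion():
        expr, design = results["expr"], results["design_qc"]
        fit = NestedAnova(covariates=config.covariates).fit(expr.T, design)
        results["anova"] = fit
        fit.apportionment_.to_csv(out / "apportionment.tsv", sep="\t")
        results["de_individual"] = fit.individual_de_tests(fdr=config.fdr)
        results["de_individual"].to_csv(out / "individual_de.tsv", sep="\t")
        results["pairwise"] = pairwise_apportionments(expr, design,
                                                      covariates=config.covariates)
        results["diagnostics"] = mean_expression_diagnostics(fit.apportionment_, fit)
        results["diagnostics"].to_csv(out / "mean_expression_diagnostics.tsv",
                                      sep="\t")
        traits = vio.design_traits(design)
        if traits:
            full = fit_full_model(expr, design, fdr=config.fdr, traits=traits)
            results["full_model"] = full
            full.eta2_.to_csv(out / "full_model_eta2.tsv", sep="\t")
            full.qvalues_.to_csv(out / "full_model_qvalues.tsv", sep="\t")

    # --- permutation nulls + selection ---------------------------------------
    @stage("selection")
    def _selection():
        expr, design = results["expr"], results["design_qc"]
        clf = SelectionProfileClassifier(
            n_permutations=config.n_permutations,
            genes_per_permutation=config.genes_per_permutation,
            n_artificial=config.n_artificial,
            covariates=config.covariates,
            random_state=child_seed(config.seed, 1),
        ).fit(expr.T, design, X_individual=results["expr_individual"].T)
        results["selection"] = clf
        clf.calls_.to_csv(out / "selection_calls.tsv", sep="\t")
        clf.summary_.to_csv(out / "selection_summary.tsv", sep="\t")
        results["mean_pvalues"] = mean_apportionment_pvalues(
            expr, design, counts=results["counts_qc"],
            n_perm=config.mean_pvalue_permutations,
            seed=child_seed(config.seed, 2), covariates=config.covariates,
            pseudocount=config.pseudocount,
        )
        with open(out / "mean_apportionment_pvalues.json", "w") as fh:
            json.dump(results["mean_pvalues"], fh, indent=2)
        results["de_pairwise"] = de_genes_pairwise(
            expr, design, n_perm=config.n_permutations,
            genes_per_perm=config.genes_per_permutation,
            seed=child_seed(config.seed, 3), covariates=config.covariates,
        )

    # --- structure -----------------------------------------------------------
    @stage("structure")
    def _structure():
        expr_ind = results["expr_individual"]
        design_ind = results["design_individual"]
        pca = pca_individuals(expr_ind.T)
        results["pca"] = pca
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        traits = vio.design_traits(design_ind)
        if traits:
            report = pc_trait_correlations(pca.scores, design_ind,
                                           n_pcs=min(5, pca.scores.shape[1]),
                                           traits=traits)
            results["pc_traits"] = report
            report.to_csv(out / "pc_trait_correlations.tsv", sep="\t", index=False)
        tree = population_distance_tree(results["pairwise"])
        results["population_tree"] = tree
        (out / "population_tree.nwk").write_text(tree.newick + "\n")
        tree.distances.to_csv(out / "population_distances.tsv", sep="\t")
        directional = results["selection"].calls_.query("directional").index
        if len(directional) >= 2:
            check = directional_structure_check(expr_ind, design_ind, directional)
            results["directional_structure"] = check
            (out / "directional_tree.nwk").write_text(check["newick"] + "\n")
            km = kmeans_profiles(expr_ind, design_ind, gene_set=directional,
                                 k=min(config.kmeans_k, len(directional)),
                                 seed=child_seed(config.seed, 4))
            results["kmeans"] = km
            km["group_profiles"].to_csv(out / "kmeans_group_profiles.tsv", sep="\t")

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.yaml":
            manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    results["manifest"] = manifest
    return results
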