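"""End-to-end orchestration: simulate/load -> prep -> classes -> concordance
-> cluster -> features -> model -> HPTR, under one seeded config.

The global seed fans out to per-stage generators through a documented
counter scheme: stage i draws from ``SeedSequence((seed, stage_index))``, so
stages are reproducible independently of one another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dielomix import io as dio
from dielomix.abundance_model import (
    feature_protein_partial_correlations,
    fit_protein_models,
)
from dielomix.coexpr_clustering import build_joint_matrix, cluster_enrichment, consensus_cluster
from dielomix.expression_compare import (
    assign_correlation_classes,
    permutation_class_test,
    pooled_correlations,
    zscore_profiles,
)
from dielomix.hptr import identify_hptr, refit_excluding_hptr
from dielomix.pathway_concordance import pathway_concordance
from dielomix.proteome_prep import (
    filter_peptides,
    normalize_and_rollup,
    presence_absence,
    progressive_differential,
)
from dielomix.seqfeatures import assemble_feature_table
from dielomix.synthdata import SimulationConfig, simulate_study, write_study

logger = logging.getLogger("dielomix")

STAGES = (
    "simulate",
    "proteome",
    "classes",
    "concordance",
    "cluster",
    "features",
    "model",
    "hptr",
)

STAGE_SEED_INDEX = {name: i + 10 for i, name in enumerate(STAGES)}


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    seed: int = 0
    outdir: str = "dielomix_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulation: dict | None = None
    paths: dict | None = None
    # stage parameters
    n_permutations: int = 10000
    n_boot: int = 1000
    reference_timepoint: str = "T3"
    cluster_k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    cluster_fixed_k: int | None = None
    cluster_n_iter: int = 50
    cluster_subsample: float = 0.8
    cluster_max_genes: int = 500
    hptr_min_models: int = 2
    cv_folds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulation is None and self.paths is None:
            raise PipelineConfigError(
                "config needs either a 'simulation' block or data 'paths'"
            )
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence((self.seed, STAGE_SEED_INDEX[stage])).generate_state(1)[0]
            % (2**31)
        )


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.stage_seed("simulate")})
        bundle = simulate_study(sim)
        return bundle
    p = config.paths
    from dielomix.synthdata import StudyBundle

    records = dio.read_gene_records(
        p["cds"], p.get("utr5"), p.get("utr3"), p.get("protein_fasta")
    )
    mrna = dio.read_expression_tsv(p["mrna"])
    peptides = dio.read_peptides_tsv(p["peptides"], p["peptide_samples"])
    pathways = dio.read_gmt(p["gmt"]) if "gmt" in p else {}
    return StudyBundle(
        config=None, records=records, truth=None, mrna=mrna, protein=None,
        peptides=peptides, pathways=pathways,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    logger.info("pipeline start: stages=%s seed=%d", config.stages, config.seed)

    bundle = _load_inputs(config)
    if config.simulation is not None and "simulate" in config.stages:
        write_study(bundle, outdir / "simulated")

    protein_tp = None
    if "proteome" in config.stages:
        filtered = filter_peptides(bundle.peptides)
        protein_tp = normalize_and_rollup(filtered, level="timepoint")
        protein_reps = normalize_and_rollup(filtered, level="biorep")
        presence = presence_absence(bundle.peptides)
        diff = progressive_differential(protein_reps)
        protein_tp.data.rename_axis("protein_id").to_csv(
            outdir / "protein_abundance.tsv", sep="\t"
        )
        diff.to_csv(outdir / "progressive_differential.tsv", sep="\t", index=False)
        summary["proteome"] = {
            "n_proteins_quantified": int(protein_tp.data.shape[0]),
            "n_present_all_timepoints": len(presence["all"]),
            "n_differential_calls": int(len(diff)),
        }
    elif bundle.protein is not None:
        protein_tp = bundle.protein
    if protein_tp is None:
        raise PipelineConfigError("downstream stages need protein abundances")

    mrna = bundle.mrna
    shared = mrna.data.index.intersection(protein_tp.data.index)
    mrna_s = mrna.subset_genes(shared)
    prot_s = protein_tp.subset_genes(shared)

    profiles = None
    if "classes" in config.stages:
        profiles = zscore_profiles(mrna_s, prot_s)
        classes = assign_correlation_classes(profiles)
        pooled = pooled_correlations(
            mrna_s, prot_s, reference_timepoint=config.reference_timepoint
        )
        null = permutation_class_test(
            profiles,
            n_perm=config.n_permutations,
            seed=config.stage_seed("classes"),
        )
        classes.rename_axis("gene_id").to_csv(outdir / "correlation_classes.tsv", sep="\t")
        (outdir / "class_null.json").write_text(
            json.dumps(
                {
                    "observed": null.observed_counts,
                    "null_mean": null.null_mean,
                    "p": null.p_values,
                    "n_permutations": null.n_permutations,
                },
                indent=1,
            )
        )
        fractions = (classes["class"].value_counts() / len(classes)).to_dict()
        summary["classes"] = {
            "n_genes": int(len(classes)),
            "fractions": fractions,
            "pooled_spearman": pooled.pooled_rs,
            "logratio_spearman": pooled.logratio_rs,
            "class_p": null.p_values,
        }

    if "concordance" in config.stages and bundle.pathways:
        conc = pathway_concordance(mrna_s, prot_s, bundle.pathways)
        conc.table.rename_axis("pathway").to_csv(outdir / "concordance.tsv", sep="\t")
        concordant = conc.table[
            (conc.table["cs"] > 0)
            & (conc.table["es_mrna"] > 0)
            & (conc.table["es_protein"] > 0)
        ]
        summary["concordance"] = {
            "n_pathways_scored": int(len(conc.table)),
            "n_concordant_positive": int(len(concordant)),
        }

    if "cluster" in config.stages:
        joint = build_joint_matrix(mrna_s, prot_s)
        if len(joint) > config.cluster_max_genes:
            variances = joint.var(axis=1)
            joint = joint.loc[
                variances.sort_values(ascending=False).index[: config.cluster_max_genes]
            ]
        clust = consensus_cluster(
            joint,
            k_range=config.cluster_k_range,
            n_iter=config.cluster_n_iter,
            subsample=config.cluster_subsample,
            fixed_k=config.cluster_fixed_k,
            seed=config.stage_seed("cluster"),
        )
        clust.labels.rename_axis("gene_id").to_csv(outdir / "clusters.tsv", sep="\t")
        enr = cluster_enrichment(clust.labels, bundle.pathways) if bundle.pathways else pd.DataFrame()
        if len(enr):
            enr.to_csv(outdir / "cluster_enrichment.tsv", sep="\t", index=False)
        summary["cluster"] = {
            "chosen_k": int(clust.chosen_k),
            "n_quality_clusters": int(
                (clust.within_cluster_correlation >= 0.75).sum()
            ),
        }

    feature_table = None
    if "features" in config.stages:
        feature_table = assemble_feature_table(bundle.records, mrna=mrna_s)
        feature_table.values.rename_axis("gene_id").to_csv(
            outdir / "features.tsv", sep="\t"
        )
        feature_table.metadata.rename_axis("feature").to_csv(
            outdir / "feature_metadata.tsv", sep="\t"
        )
        summary["features"] = {
            "n_features": int(feature_table.values.shape[1]),
            "n_incomplete_genes": int(feature_table.incomplete.sum()),
        }

    evaluation = None
    if "model" in config.stages:
        if feature_table is None:
            raise PipelineConfigError("'model' stage requires the 'features' stage")
        seed = config.stage_seed("model")
        pcors = feature_protein_partial_correlations(
            feature_table.values.loc[~feature_table.incomplete],
            mrna_s,
            prot_s,
            n_boot=config.n_boot,
            seed=seed,
        )
        pcors.partial.rename_axis("feature").to_csv(
            outdir / "partial_correlations.tsv", sep="\t"
        )
        evaluation = fit_protein_models(
            feature_table, mrna_s, prot_s, folds=config.cv_folds, seed=seed
        )
        evaluation.residuals.rename_axis("gene_id").to_csv(
            outdir / "model_residuals.tsv", sep="\t"
        )
        summary["model"] = {
            "r2_resub": evaluation.r2_resub,
            "r2_cv": evaluation.r2_cv,
        }

    if "hptr" in config.stages:
        if evaluation is None:
            raise PipelineConfigError("'hptr' stage requires the 'model' stage")
        hptr = identify_hptr(evaluation, min_models=config.hptr_min_models)
        refit = refit_excluding_hptr(
            feature_table,
            mrna_s,
            prot_s,
            evaluation,
            hptr,
            folds=config.cv_folds,
            seed=config.stage_seed("hptr"),
        )
        rows = [
            {"gene_id": g, "tail": "+", "n_models_flagged": int(hptr.n_models_flagged[g])}
            for g in sorted(hptr.hptr_plus)
        ] + [
            {"gene_id": g, "tail": "-", "n_models_flagged": int(hptr.n_models_flagged[g])}
            for g in sorted(hptr.hptr_minus)
        ]
        pd.DataFrame(rows).to_csv(outdir / "hptr_genes.tsv", sep="\t", index=False)
        summary["hptr"] = {
            "n_hptr": len(hptr.hptr_genes),
            "n_hptr_plus": len(hptr.hptr_plus),
            "n_hptr_minus": len(hptr.hptr_minus),
            "delta_r2_cv": refit.delta_r2_cv,
            "mean_relative_improvement": refit.mean_relative_improvement,
            "refit_p": refit.p_value,
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    manifest = {
        "config": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
        },
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline done: %s", outdir / "summary.json")
    return summary
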