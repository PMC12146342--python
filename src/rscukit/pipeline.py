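"""End-to-end orchestration: weighting -> RSCU -> batch adjustment ->
PCA -> cluster-number heuristics -> four clusterers -> validation ->
best-method selection -> codon-wise group statistics.

One analysis covers one strain-set x one tissue x one healthy/disease
gene-set pairing.  Every weighted profile is identified as
``<sample_id>:<set label>``, so the "tissue state" of a profile (which
gene set weighted it) is the primary reference labeling for cluster
validation, with the embryonic stage as the second.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batch import adjust_batch_effects, infer_batches
from .cluster import (
    ClusterAssignment,
    agglomerative_cluster,
    dbscan_cluster,
    evaluate_clustering,
    heuristic_scan,
    kmeans_cluster,
    linkage_to_newick,
    select_best_method,
    spectral_cluster,
)
from .codons import load_cds_collection, read_gene_list, standard_genetic_code
from .pca import (
    describe_samples,
    fit_pca,
    loading_report,
    nucleotide_preference,
    select_codon_features,
    standardize,
)
from .rscu import (
    classify_external_usage,
    classify_representation,
    rscu_values,
    summarize_group,
)
from .rscu import RSCUProfile, rscu_matrix, rscu_profile
from .stats import compare_groups
from .weighting import (
    GeneSet,
    filter_samples,
    read_expression_tsv,
    read_metadata_tsv,
    restrict_to_gene_set,
    weighted_codon_usage,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, filters, thresholds and seed for one analysis run."""

    fasta: str
    tpm: str
    metadata: str
    healthy_genes: str
    disease_genes: str
    blacklist: str | None = None
    tissue: str = "liver"
    strains: list[str] | None = None
    rscu_hi: float = 1.5
    rscu_lo: float = 0.5
    var_threshold: float = 0.80
    component_cap: int = 5
    loading_cutoff: float = 0.2
    score_threshold: float = 5.0
    alpha: float = 0.05
    k_min: int = 2
    k_max: int = 10
    merge_singleton_batches: bool = False
    seed: int = 0
    outdir: str = "rscukit_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_analysis(config: PipelineConfig) -> dict:
    """Execute the full analysis and write TSV/JSON reports plus a manifest.

    Returns the report bundle as a dict (also what the JSON files contain).
    Deterministic for a fixed config and seed.  Stage failures surface as
    :class:`StageError`; outputs of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    code = standard_genetic_code()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
    }

    def stage_done(name: str, **info):
        manifest["stages"].append({"name": name, **info})
        logger.info("stage %s done: %s", name, info)

    # ---- load inputs -----------------------------------------------------
    try:
        blacklist = read_gene_list(config.blacklist) if config.blacklist else set()
        counts = load_cds_collection(config.fasta, blacklist)
        tpm = read_expression_tsv(config.tpm)
        metadata = read_metadata_tsv(config.metadata)
        healthy = GeneSet("healthy", frozenset(read_gene_list(config.healthy_genes)))
        disease = GeneSet("disease", frozenset(read_gene_list(config.disease_genes)))
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    stage_done(
        "load",
        n_cds=len(counts),
        n_blacklisted=len(blacklist),
        tpm_shape=list(tpm.shape),
        n_samples=len(metadata),
    )

    # ---- sample filtering ------------------------------------------------
    try:
        samples = filter_samples(metadata, config.tissue, config.strains)
        samples = [s for s in samples if s in tpm.columns]
        if not samples:
            raise ValueError("no filtered sample has a TPM column")
    except Exception as exc:
        raise StageError("filter_samples", str(exc)) from exc
    excluded = sorted(set(metadata["sample_id"]) - set(samples))
    stage_done("filter_samples", n_selected=len(samples), excluded=excluded)

    # ---- weighting (one profile per sample per gene set) -----------------
    try:
        profiles: list[RSCUProfile] = []
        state_of, stage_of, batch_of = {}, {}, {}
        meta_idx = metadata.set_index("sample_id")
        batches_by_sample = infer_batches(metadata)
        for gene_set in (healthy, disease):
            expr = restrict_to_gene_set(tpm, gene_set, set(counts))
            for s in samples:
                wp = weighted_codon_usage(
                    expr[s], counts, normalize=True,
                    sample_id=f"{s}:{gene_set.label}",
                )
                profiles.append(rscu_profile(wp, code, config.rscu_hi, config.rscu_lo))
                pid = wp.sample_id
                state_of[pid] = gene_set.label
                stage_of[pid] = int(meta_idx.loc[s, "stage"])
                batch_of[pid] = str(batches_by_sample[s])
    except Exception as exc:
        raise StageError("weighting", str(exc)) from exc
    stage_done("weighting", n_profiles=len(profiles))

    rscu = rscu_matrix(profiles)
    rscu.to_csv(outdir / "rscu.tsv", sep="\t")
    group_summaries = {
        label: summarize_group(
            [p for p in profiles if state_of[p.sample_id] == label], label
        )
        for label in ("healthy", "disease")
    }
    stage_done("rscu", shape=list(rscu.shape))

    # ---- batch adjustment ------------------------------------------------
    try:
        batches = pd.Series({pid: batch_of[pid] for pid in rscu.index})
        complete = rscu.columns[rscu.notna().all()]
        adjusted = rscu.copy()
        adjusted[complete] = adjust_batch_effects(
            rscu[complete], batches.loc[rscu.index],
            merge_singletons=config.merge_singleton_batches,
        )
    except Exception as exc:
        raise StageError("batch_adjust", str(exc)) from exc
    adjusted.to_csv(outdir / "rscu_adjusted.tsv", sep="\t")
    stage_done(
        "batch_adjust",
        n_batches=int(batches.nunique()),
        n_features_adjusted=int(len(complete)),
    )

    # ---- PCA -------------------------------------------------------------
    try:
        features = select_codon_features(adjusted)
        if features.isna().any().any():
            bad = sorted(features.columns[features.isna().any()])
            raise ValueError(f"undefined RSCU in feature columns {bad}")
        scaled, _, constant = standardize(features)
        model = fit_pca(scaled, config.var_threshold, config.component_cap)
        report = loading_report(model, config.loading_cutoff, code)
        descriptors = describe_samples(model, config.score_threshold, report=report)
    except Exception as exc:
        raise StageError("pca", str(exc)) from exc
    model.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pca_report = {
        "n_components": model.n_components,
        "explained_variance_ratio": [
            float(v) for v in model.explained_variance_ratio
        ],
        "constant_features": constant,
        "loadings": {
            pc: {c: float(v) for c, v in model.loadings[pc].items()}
            for pc in model.loadings.columns
        },
        "highlighted_amino_acids": report.highlighted,
        "high_loading_codons": report.raw,
        "nucleotide_preference": {
            pc: {
                sign: nucleotide_preference(codons) if codons else None
                for sign, codons in sets.items()
            }
            for pc, sets in report.raw.items()
        },
        "sample_descriptors": [
            {
                "sample_id": d.sample_id,
                "pc": d.pc,
                "score": d.score,
                "positive_codons": list(d.positive_codons),
                "negative_codons": list(d.negative_codons),
            }
            for d in descriptors
        ],
    }
    _json_dump(pca_report, outdir / "pca_report.json")
    stage_done("pca", k=model.n_components, n_descriptors=len(descriptors))

    # ---- heuristics ------------------------------------------------------
    try:
        n = model.scores.shape[0]
        k_hi = min(config.k_max, n - 1)
        heur = heuristic_scan(
            model.scores, range(config.k_min, k_hi + 1), seed=config.seed
        )
    except Exception as exc:
        raise StageError("heuristics", str(exc)) from exc
    heur_report = {
        "k_range": list(heur.k_range),
        "silhouette": heur.silhouette,
        "calinski_harabasz": heur.calinski_harabasz,
        "inertia": heur.inertia,
        "davies_bouldin": heur.davies_bouldin,
        "best_k": heur.best_k,
        "consensus_k": heur.consensus,
    }
    _json_dump(heur_report, outdir / "heuristics.json")
    stage_done("heuristics", consensus_k=heur.consensus)

    # ---- clustering ------------------------------------------------------
    k = heur.consensus
    assignments: dict[str, ClusterAssignment] = {}
    cluster_errors: dict[str, str] = {}
    for name, fn in (
        ("kmeans", lambda: kmeans_cluster(model.scores, k, seed=config.seed)),
        ("spectral", lambda: spectral_cluster(model.scores, k, seed=config.seed)),
        ("dbscan", lambda: dbscan_cluster(model.scores, model.n_components)),
        ("agglomerative", lambda: agglomerative_cluster(model.scores, k)),
    ):
        try:
            assignments[name] = fn()
        except Exception as exc:
            cluster_errors[name] = str(exc)
            logger.warning("clustering method %s failed: %s", name, exc)
    if not assignments:
        raise StageError("clustering", f"all methods failed: {cluster_errors}")
    if "agglomerative" in assignments:
        (outdir / "dendrogram.nwk").write_text(
            linkage_to_newick(
                assignments["agglomerative"].linkage_tree,
                [str(s) for s in model.scores.index],
            )
            + "\n"
        )
    labels_df = pd.DataFrame(
        {name: a.labels for name, a in assignments.items()}
    ).rename_axis("sample_id")
    labels_df.to_csv(outdir / "cluster_labels.tsv", sep="\t")
    stage_done("clustering", methods=sorted(assignments), errors=cluster_errors)

    # ---- validation & best method ---------------------------------------
    try:
        refs = {
            "tissue_state": pd.Series(state_of).loc[model.scores.index],
            "stage": pd.Series(stage_of).loc[model.scores.index],
        }
        evaluations = {
            name: {
                ref_name: evaluate_clustering(a, ref, ref_name)
                for ref_name, ref in refs.items()
            }
            for name, a in assignments.items()
        }
        best = select_best_method(evaluations)
    except Exception as exc:
        raise StageError("validation", str(exc)) from exc
    clustering_report = {
        "consensus_k": k,
        "methods": {
            name: {
                "parameters": a.parameters,
                "degenerate": a.degenerate,
                "evaluations": {
                    r: evaluations[name][r].as_dict() for r in evaluations[name]
                },
            }
            for name, a in assignments.items()
        },
        "failed_methods": cluster_errors,
        "best_method": best,
        "best_tissue_state_ari": evaluations[best]["tissue_state"].ari,
    }
    _json_dump(clustering_report, outdir / "clustering.json")
    stage_done("validation", best_method=best)

    # ---- statistics ------------------------------------------------------
    try:
        healthy_ids = [p for p in rscu.index if state_of[p] == "healthy"]
        disease_ids = [p for p in rscu.index if state_of[p] == "disease"]
        strata = pd.Series({pid: stage_of[pid] for pid in rscu.index})
        summary = compare_groups(
            rscu.loc[healthy_ids],
            rscu.loc[disease_ids],
            strata=strata,
            alpha=config.alpha,
            seed=config.seed,
        )
    except Exception as exc:
        raise StageError("statistics", str(exc)) from exc
    summary.to_frame().to_csv(outdir / "stats.tsv", sep="\t", index=False)
    stats_report = {
        "alpha": config.alpha,
        "n_comparisons": summary.n_comparisons,
        "n_tested": summary.n_tested,
        "n_significant": summary.n_significant,
        "fraction_significant": summary.fraction_significant,
        "stratum_contributions": summary.stratum_contributions(),
        "n_skipped": len(summary.skipped),
        "top_decile_effects": [
            {"codon": r.codon, "stratum": r.stratum, "d": r.d, "effect": r.effect}
            for r in summary.top_decile_effects()
        ],
    }
    _json_dump(stats_report, outdir / "stats_summary.json")
    stage_done(
        "statistics",
        n_tested=summary.n_tested,
        fraction_significant=round(summary.fraction_significant, 4),
    )

    representation = {
        label: {
            "classes": classify_representation(
                gs.mean, config.rscu_hi, config.rscu_lo
            ).to_dict(),
            "n": gs.n,
        }
        for label, gs in group_summaries.items()
    }
    _json_dump(representation, outdir / "representation.json")

    bundle = {
        "manifest": manifest,
        "pca": pca_report,
        "heuristics": heur_report,
        "clustering": clustering_report,
        "stats": stats_report,
        "representation": representation,
    }
    _json_dump(manifest, outdir / "manifest.json")
    return bundle


def compare_to_reference_usage(
    representation: dict, external_usage, code=None
) -> dict:
    """Compare study over/under codon classes with an external usage table.

    ``representation`` is the pipeline's per-group classification (the
    ``representation.json`` content); ``external_usage`` a 61+-codon table
    of nonnegative usage values.  Reports, per group, codons over- or
    underrepresented in the external table but not in the group, and vice
    versa.
    """
    code = code or standard_genetic_code()
    ext_classes = classify_external_usage(external_usage, code)
    ext = {
        "over": {c for c, v in ext_classes.items() if v == "over"},
        "under": {c for c, v in ext_classes.items() if v == "under"},
    }
    out: dict = {"external": {k: sorted(v) for k, v in ext.items()}, "groups": {}}
    for label, info in representation.items():
        grp = {
            "over": {c for c, v in info["classes"].items() if v == "over"},
            "under": {c for c, v in info["classes"].items() if v == "under"},
        }
        out["groups"][label] = {
            direction: {
                "external_only": sorted(ext[direction] - grp[direction]),
                "group_only": sorted(grp[direction] - ext[direction]),
                "shared": sorted(ext[direction] & grp[direction]),
            }
            for direction in ("over", "under")
        }
    return out
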