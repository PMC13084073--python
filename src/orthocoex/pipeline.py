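"""End-to-end orchestration of the comparative co-expression pipeline.

Stages: blocked NB-LRT differential expression in the ripening species
-> SOM expression patterns in every species (DEGs only for the ripening
species; the downregulated set is the union of its decreasing clusters)
-> bait assignment and bait-richest cluster selection in the panel
species -> orthogroup intersection -> annotation triage and bait
co-expression ranking. Given the same inputs and seed the whole run is
deterministic and the summary records every threshold applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aux_stats, baits, diffexpr, ortho_integrate, patterns
from .tables_io import (
    AnnotationTable,
    BaitHitTable,
    ExpressionMatrix,
    OrthogroupTable,
    SampleDesign,
    parse_blast_outfmt6,
    parse_orthogroups,
    read_annotations,
    read_design,
    read_expression_matrix,
    warn_unknown_species,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """In-memory bundle of everything one run consumes."""

    olive_species: str
    panel_species: list[str]
    counts: dict[str, ExpressionMatrix]
    tpm: dict[str, ExpressionMatrix]
    designs: dict[str, SampleDesign]
    og_table: OrthogroupTable
    bait_hits: BaitHitTable
    annotations: AnnotationTable


@dataclass
class RunParams:
    """Stage parameters; defaults mirror the study-stated values
    (FDR 0.01, 400 SOM nodes, 8 clusters)."""

    de: diffexpr.DEParams = field(default_factory=diffexpr.DEParams)
    patterns: patterns.PatternParams = field(default_factory=patterns.PatternParams)
    min_identity: float = 40.0
    min_bitscore: float = 100.0
    # panel species have no DE gate; near-flat profiles (log2 sd below
    # this) are excluded before pattern clustering, the usual variance
    # filter of co-expression analyses
    panel_min_profile_sd: float = 0.5
    annotation_rules: ortho_integrate.AnnotationClassRules = field(
        default_factory=ortho_integrate.AnnotationClassRules)
    seed: int = 42


@dataclass
class RunResult:
    de_table: pd.DataFrame
    olive_model: patterns.PatternModel
    panel_models: dict[str, patterns.PatternModel]
    selections: dict[str, baits.ClusterSelection]
    integration: ortho_integrate.IntegrationResult
    ranking: pd.DataFrame
    summary: dict


def load_fixture_dir(path, species: tuple[str, ...] | None = None) -> PipelineInputs:
    """Load a fixture directory as written by :func:`orthocoex.synth.write_fixtures`."""
    root = Path(path)
    if species is None:
        species = tuple(sorted(
            p.name[: -len("_design.tsv")] for p in root.glob("*_design.tsv")))
        # the ripening species is the one with an ordered, blocked design
        ordered = [sp for sp in species
                   if read_design(root / f"{sp}_design.tsv").is_ordered]
        if len(ordered) != 1:
            raise ValueError(
                f"expected exactly one ordered (ripening) design, found {ordered}")
        species = tuple(ordered + [sp for sp in species if sp not in ordered])
    olive, panel = species[0], list(species[1:])
    bait_map = pd.read_csv(root / "bait_map.tsv", sep="\t")
    qmap = dict(zip(bait_map["query_id"], bait_map["bait_name"]))
    hits = pd.concat(
        [parse_blast_outfmt6(root / f"{sp}_hits.outfmt6", qmap, sp).table
         for sp in species], ignore_index=True)
    og_table = parse_orthogroups(root / "Orthogroups.tsv")
    warn_unknown_species(og_table, species)
    return PipelineInputs(
        olive_species=olive,
        panel_species=panel,
        counts={sp: read_expression_matrix(root / f"{sp}_counts.tsv", "counts")
                for sp in species},
        tpm={sp: read_expression_matrix(root / f"{sp}_tpm.tsv", "TPM")
             for sp in species},
        designs={sp: read_design(root / f"{sp}_design.tsv") for sp in species},
        og_table=og_table,
        bait_hits=BaitHitTable(hits),
        annotations=read_annotations(root / "olive_annotations.tsv"),
    )


def run_all(inputs: PipelineInputs, params: RunParams | None = None) -> RunResult:
    params = params or RunParams()
    olive = inputs.olive_species
    summary: dict = {
        "olive_species": olive,
        "panel_species": inputs.panel_species,
        "seed": params.seed,
        "thresholds": {
            "fdr_alpha": params.de.alpha,
            "min_total_count": params.de.min_total_count,
            "dispersion_shrink_weight": params.de.dispersion_shrink_weight,
            "som_grid": [params.patterns.grid_rows, params.patterns.grid_cols],
            "som_epochs": params.patterns.epochs,
            "k_clusters": params.patterns.k_clusters,
            "direction_threshold": params.patterns.direction_threshold,
            "bait_min_identity": params.min_identity,
            "bait_min_bitscore": params.min_bitscore,
        },
    }

    # Stage 1: differential expression over ripening, blocked by cultivar.
    logger.info("stage diffexpr: %s", olive)
    de_table = _stage("diffexpr", diffexpr.nb_lrt_blocked,
                      inputs.counts[olive], inputs.designs[olive], params.de)
    degs = diffexpr.significant_genes(de_table, params.de.alpha)
    summary["n_genes_tested"] = int((de_table["status"] == "tested").sum())
    summary["n_degs"] = len(degs)

    # Stage 2: expression patterns. Olive: SOM over DEGs; the olive
    # "downregulated" set is the union of its decreasing clusters.
    som_params = params.patterns
    som_params.seed = params.seed
    olive_model = _stage("patterns:" + olive, patterns.fit_patterns,
                         inputs.tpm[olive], inputs.designs[olive], som_params, degs)
    down_clusters = [c for c, d in olive_model.cluster_direction.items()
                     if d == "decreasing"]
    olive_down = sorted(
        g for c in down_clusters for g in olive_model.genes_in_cluster(c))
    summary["n_down_degs"] = len(olive_down)
    summary["olive_cluster_directions"] = {
        str(k): v for k, v in olive_model.cluster_direction.items()}

    panel_models: dict[str, patterns.PatternModel] = {}
    selections: dict[str, baits.ClusterSelection] = {}
    panel_og_sets: dict[str, set[str]] = {}
    unmapped: dict[str, int] = {}
    for sp in inputs.panel_species:
        prof = patterns.condition_profiles(inputs.tpm[sp], inputs.designs[sp])
        sd = prof.values.std(axis=1, ddof=1)
        variable_genes = list(sd.index[sd >= params.panel_min_profile_sd])
        summary[f"n_variable_genes_{sp}"] = len(variable_genes)
        panel_models[sp] = _stage("patterns:" + sp, patterns.fit_patterns,
                                  inputs.tpm[sp], inputs.designs[sp], som_params,
                                  variable_genes)
        assignment = baits.assign_baits(
            inputs.bait_hits.for_species(sp),
            min_identity=params.min_identity, min_bitscore=params.min_bitscore)
        sel = _stage("select:" + sp, baits.select_bait_cluster,
                     assignment, panel_models[sp].gene_cluster, inputs.og_table)
        selections[sp] = sel
        panel_og_sets[sp], unmapped[sp] = ortho_integrate.genes_to_orthogroups(
            sel.candidate_genes, sp, inputs.og_table)
        summary[f"selection_{sp}"] = {
            "cluster": sel.selected_cluster,
            "bait_counts": {str(k): v for k, v in sel.bait_counts.items()},
            "n_candidate_genes": sel.n_candidate_genes,
            "n_candidate_orthogroups": sel.n_candidate_orthogroups,
        }

    # Stage 3: orthogroup intersection and triage.
    integration = _stage("integrate", ortho_integrate.intersect_candidates,
                         panel_og_sets, olive_down, olive, inputs.og_table)
    integration.n_unmapped.update(unmapped)
    integration.tiered_candidates = ortho_integrate.triage_by_annotation(
        integration.olive_candidate_genes, inputs.annotations,
        params.annotation_rules)
    integration.annotated_candidates = [
        g for g in integration.olive_candidate_genes
        if inputs.annotations.pfam(g)]

    olive_assignment = baits.assign_baits(
        inputs.bait_hits.for_species(olive),
        min_identity=params.min_identity, min_bitscore=params.min_bitscore)
    olive_profiles = patterns.condition_profiles(
        inputs.tpm[olive], inputs.designs[olive])
    ranking = ortho_integrate.rank_by_bait_coexpression(
        integration.olive_candidate_genes, olive_assignment.genes, olive_profiles)

    n_candidates = len(integration.olive_candidate_genes)
    summary["n_shared_orthogroups"] = len(integration.shared_orthogroups)
    summary["venn_counts"] = integration.venn_counts
    summary["n_olive_candidates"] = n_candidates
    summary["n_annotated_candidates"] = len(integration.annotated_candidates)
    summary["n_candidate_orthogroups"] = len({
        inputs.og_table.orthogroup_of(olive, g)
        for g in integration.olive_candidate_genes} - {None})
    summary["tier_counts"] = {
        k: len(v) for k, v in integration.tiered_candidates.items()}
    summary["candidate_reduction_ratio"] = (
        len(olive_down) / n_candidates if n_candidates else None)
    summary["empty_intersection"] = n_candidates == 0
    return RunResult(
        de_table=de_table, olive_model=olive_model, panel_models=panel_models,
        selections=selections, integration=integration, ranking=ranking,
        summary=summary,
    )


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def write_outputs(result: RunResult, outdir) -> None:
    """candidates.tsv, tiers.tsv, venn_counts.json and the run summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.de_table.to_csv(out / "de.tsv", sep="\t", index=False)
    result.ranking.to_csv(out / "candidates.tsv", sep="\t", index=False)
    tiers = pd.DataFrame(
        [(tier, g) for tier, genes in result.integration.tiered_candidates.items()
         for g in genes], columns=["tier", "gene_id"])
    tiers.to_csv(out / "tiers.tsv", sep="\t", index=False)
    with open(out / "venn_counts.json", "w") as fh:
        json.dump(result.integration.venn_counts, fh, indent=1, sort_keys=True)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
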