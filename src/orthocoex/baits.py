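"""Bait-gene assignment and co-expression cluster selection.

Known early-pathway enzymes ("baits") are located in each species'
assembly via pre-computed BLAST hit tables; per bait the best passing
hit is kept. The expression cluster holding the largest number of bait
genes is then selected as the cluster likely to carry the missing
pathway step, and every gene with that pattern becomes a candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .tables_io import BaitHitTable, OrthogroupTable

logger = logging.getLogger(__name__)


@dataclass
class BaitAssignment:
    """Per-bait best gene for one species (bait -> gene, bit score, identity)."""

    species: str
    assigned: dict[str, tuple[str, float, float]]
    unassigned: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.assigned.values()]


@dataclass
class ClusterSelection:
    """The bait-richest expression cluster of one species."""

    species: str
    selected_cluster: int
    bait_counts: dict[int, int]
    candidate_genes: list[str]
    n_candidate_genes: int
    n_candidate_orthogroups: int | None = None


def assign_baits(hits: BaitHitTable, min_identity: float = 40.0,
                 min_bitscore: float = 100.0) -> BaitAssignment:
    """Pick the best passing hit per bait.

    Best = maximal bit score; ties broken by higher percent identity,
    then lexicographically smallest gene id. Baits with no passing hit
    are reported unassigned.
    """
    df = hits.table
    species = df["species"].iloc[0] if len(df) else ""
    if len(df) and df["species"].nunique() > 1:
        raise ValueError("assign_baits expects hits filtered to one species")
    passing = df[(df["percent_identity"] >= min_identity) & (df["bit_score"] >= min_bitscore)]
    assigned: dict[str, tuple[str, float, float]] = {}
    for bait, grp in passing.groupby("bait_name", sort=True):
        best = grp.sort_values(
            ["bit_score", "percent_identity", "subject_gene_id"],
            ascending=[False, False, True], kind="mergesort",
        ).iloc[0]
        assigned[bait] = (best["subject_gene_id"], float(best["bit_score"]),
                          float(best["percent_identity"]))
    unassigned = sorted(set(df["bait_name"]) - set(assigned))
    if not assigned:
        logger.warning("no bait passed thresholds for species %r", species)
    return BaitAssignment(species=species, assigned=assigned, unassigned=unassigned)


def select_bait_cluster(assignment: BaitAssignment, gene_cluster: pd.Series,
                        og_table: OrthogroupTable | None = None,
                        top_n_clusters: int | None = None,
                        min_support_frac: float = 0.5) -> ClusterSelection:
    """Select the cluster(s) carrying the bait genes.

    ``selected_cluster`` is always the bait-richest cluster (ties to the
    lowest id, with a warning). The candidate set is the union of every
    cluster whose bait count reaches ``min_support_frac`` of the
    maximum: when the baits agree this is exactly the single richest
    cluster, and when a fixed-k codebook cut over-partitions one
    coherent pattern (splitting the baits across near-identical
    clusters) the supported siblings are included rather than lost.
    ``top_n_clusters`` overrides the support rule with a fixed union of
    the top-n bait-richest clusters. When an orthogroup table is
    supplied the distinct orthogroups the candidates span are counted.
    """
    counts: dict[int, int] = {}
    for bait, (gene, _, _) in assignment.assigned.items():
        if gene in gene_cluster.index:
            cid = int(gene_cluster.loc[gene])
            counts[cid] = counts.get(cid, 0) + 1
    if not counts:
        raise ValueError(
            f"no assigned bait maps to a clustered gene for species "
            f"{assignment.species!r}; cannot select a cluster"
        )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    best_count = ranked[0][1]
    if sum(1 for _, c in ranked if c == best_count) > 1:
        logger.warning(
            "bait-count tie between clusters %s for species %r; "
            "choosing the lowest id",
            [cid for cid, c in ranked if c == best_count], assignment.species)
    if top_n_clusters is not None:
        chosen = [cid for cid, _ in ranked[:max(top_n_clusters, 1)]]
    else:
        chosen = [cid for cid, c in ranked if c >= min_support_frac * best_count]
    genes = sorted(gene_cluster.index[gene_cluster.isin(chosen)])
    n_ogs = None
    if og_table is not None:
        ogs = {og_table.orthogroup_of(assignment.species, g) for g in genes}
        n_ogs = len(ogs - {None})
    return ClusterSelection(
        species=assignment.species,
        selected_cluster=chosen[0],
        bait_counts=counts,
        candidate_genes=genes,
        n_candidate_genes=len(genes),
        n_candidate_orthogroups=n_ogs,
    )
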