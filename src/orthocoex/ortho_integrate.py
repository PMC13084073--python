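"""Orthogroup-mediated intersection of candidate sets and annotation triage.

Each species contributes a set of candidate orthogroups (the bait
cluster for tissue-panel species; the downregulated DEG set for the
ripening species). Orthogroups present in every set are "shared"; the
ripening species' downregulated genes whose orthogroup is shared become
the final candidates, which are then partitioned by Pfam annotation
class (oxidase families first) and optionally ranked by co-expression
with the bait genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .tables_io import AnnotationTable, ExpressionMatrix, OrthogroupTable

#: Ordered Pfam term patterns (case-insensitive substring/regex); first
#: matching class wins. Oxidase families relevant to iridoid chemistry
#: come first, then the transferase families of the later pathway.
DEFAULT_ANNOTATION_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("cytochrome_p450", ("p450",)),
    ("2OG_FeII_dioxygenase", ("2og", "oxoglutarate", "diox_n", "2-odd")),
    ("multicopper_oxidase", ("cu-oxidase", "multicopper")),
    ("rieske_oxygenase", ("rieske", "ring_hydroxyl")),
    ("peroxidase", ("peroxidase",)),
    ("udp_glucosyltransferase", ("udpgt", "glycosyltransf", "glucosyltransf", "udp_glucos")),
    ("o_methyltransferase", ("methyltransf", r"\bomt", "o-methyltransferase")),
    ("polyphenol_oxidase", ("tyrosinase", "polyphenol", r"\bppo")),
)


@dataclass
class AnnotationClassRules:
    """Ordered (class name, Pfam term patterns) used for candidate triage."""

    rules: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_ANNOTATION_RULES

    def __post_init__(self) -> None:
        for name, patterns in self.rules:
            if not patterns:
                raise ValueError(f"annotation class {name!r} has no patterns")
        self._compiled = [
            (name, [re.compile(p, re.IGNORECASE) for p in patterns])
            for name, patterns in self.rules
        ]

    def classify(self, pfam_terms) -> str:
        """First matching class, else other_annotated / unannotated."""
        terms = list(pfam_terms)
        if not terms:
            return "unannotated"
        for name, patterns in self._compiled:
            if any(p.search(t) for p in patterns for t in terms):
                return name
        return "other_annotated"


@dataclass
class IntegrationResult:
    """Cross-species intersection plus olive-side candidates and tiers."""

    per_species_ogs: dict[str, set[str]]
    shared_orthogroups: set[str]
    venn_counts: dict[str, int]
    olive_candidate_genes: list[str]
    annotated_candidates: list[str] = field(default_factory=list)
    tiered_candidates: dict[str, list[str]] = field(default_factory=dict)
    n_unmapped: dict[str, int] = field(default_factory=dict)


def genes_to_orthogroups(genes, species: str,
                         og_table: OrthogroupTable) -> tuple[set[str], int]:
    """Orthogroups containing >= 1 of the genes; genes absent from the
    table are counted as unmapped."""
    ogs: set[str] = set()
    unmapped = 0
    for g in genes:
        og = og_table.orthogroup_of(species, g)
        if og is None:
            unmapped += 1
        else:
            ogs.add(og)
    return ogs, unmapped


def venn_region_counts(named_sets: dict[str, set[str]]) -> dict[str, int]:
    """Exclusive region sizes of a Venn diagram over the named sets.

    Keys are '+'-joined sorted name combinations; values sum to the
    union size.
    """
    names = sorted(named_sets)
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set().union(*(named_sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            counts["+".join(combo)] = len(inside - outside)
    return counts


def intersect_candidates(panel_og_sets: dict[str, set[str]],
                         olive_down_genes, olive_species: str,
                         og_table: OrthogroupTable) -> IntegrationResult:
    """Strict-AND intersection of candidate orthogroup sets.

    ``panel_og_sets`` maps each tissue-panel species to its candidate
    orthogroups; the olive set is derived from the downregulated genes.
    Final candidates are the olive genes whose orthogroup lies in the
    intersection of all sets. An empty intersection is a legal outcome.
    """
    if len(panel_og_sets) < 1:
        raise ValueError("need at least one panel species candidate set")
    olive_ogs, olive_unmapped = genes_to_orthogroups(
        olive_down_genes, olive_species, og_table)
    all_sets = dict(panel_og_sets)
    all_sets[olive_species] = olive_ogs
    shared = set.intersection(*all_sets.values()) if all_sets else set()
    venn = venn_region_counts(all_sets)
    olive_candidates = sorted(
        g for g in olive_down_genes
        if og_table.orthogroup_of(olive_species, g) in shared
    )
    return IntegrationResult(
        per_species_ogs=all_sets,
        shared_orthogroups=shared,
        venn_counts=venn,
        olive_candidate_genes=olive_candidates,
        n_unmapped={olive_species: olive_unmapped},
    )


def triage_by_annotation(candidates, annotation_table: AnnotationTable,
                         rules: AnnotationClassRules | None = None) -> dict[str, list[str]]:
    """Partition candidates into ordered annotation classes.

    Every candidate lands in exactly one tier: its first matching class,
    ``other_annotated`` if it has Pfam terms matching no class, or
    ``unannotated``.
    """
    rules = rules or AnnotationClassRules()
    tiers: dict[str, list[str]] = {name: [] for name, _ in rules.rules}
    tiers["other_annotated"] = []
    tiers["unannotated"] = []
    for gene in candidates:
        tiers[rules.classify(annotation_table.pfam(gene))].append(gene)
    return tiers


def rank_by_bait_coexpression(candidates, bait_genes,
                              profiles: ExpressionMatrix) -> pd.DataFrame:
    """Order candidates by descending mean Pearson r with the bait genes.

    A deterministic ordering aid on top of the tier lists; candidates or
    baits without profiles get rank-last NaN correlations.
    """
    prof = profiles.values
    baits = [b for b in bait_genes if b in prof.index]
    rows = []
    for gene in candidates:
        if gene in prof.index and baits:
            x = prof.loc[gene].to_numpy(dtype=float)
            rs = []
            for b in baits:
                y = prof.loc[b].to_numpy(dtype=float)
                if x.std() == 0 or y.std() == 0:
                    continue
                rs.append(float(np.corrcoef(x, y)[0, 1]))
            mean_r = float(np.mean(rs)) if rs else np.nan
        else:
            mean_r = np.nan
        rows.append({"gene_id": gene, "mean_bait_pearson": mean_r})
    out = pd.DataFrame(rows, columns=["gene_id", "mean_bait_pearson"])
    return out.sort_values(
        ["mean_bait_pearson", "gene_id"], ascending=[False, True],
        na_position="last", kind="mergesort",
    ).reset_index(drop=True)
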