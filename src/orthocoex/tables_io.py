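"""Domain tables and their plain-text readers/writers.

Everything the pipeline touches on disk is a tab-separated table:
expression matrices (genes x samples, first column the gene id), sample
design sheets, OrthoFinder-style ``Orthogroups.tsv``, BLAST tabular
(outfmt 6) hit lists, per-gene annotation sheets and metabolite AUC
tables. Parsed tables are held in small validated containers so that
downstream stages can rely on their invariants (unique ids, finite
values, non-negative counts, ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = ("counts", "TPM", "logTPM", "zscore")

BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class TableError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared unit.

    ``values`` is a DataFrame indexed by gene id with sample ids as
    columns. ``unit`` is one of ``counts | TPM | logTPM | zscore``; for
    a zscore matrix ``constant_rows`` flags genes whose profile was
    constant before standardization (those rows are all-zero and exempt
    from the mean-0 check).
    """

    values: pd.DataFrame
    unit: str
    constant_rows: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise TableError(f"unknown expression unit {self.unit!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TableError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise TableError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise TableError("expression values must be finite")
        if self.unit in ("counts", "TPM") and arr.size and arr.min() < 0:
            raise TableError(f"{self.unit} matrix contains negative values")
        if self.unit == "zscore" and arr.size:
            nonconst = ~self.values.index.isin(self.constant_rows)
            if nonconst.any():
                means = arr[nonconst].mean(axis=1)
                if np.abs(means).max() > 1e-9:
                    raise TableError("zscore rows must have mean 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(
            self.values.loc[keep], self.unit,
            frozenset(g for g in self.constant_rows if g in set(genes)),
        )


def read_expression_matrix(path, unit: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# SampleDesign
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Per-sample metadata: species, condition, optional order and block.

    ``table`` columns: sample_id, species, condition, condition_order
    (nullable int), block (nullable), replicate. Conditions may be
    ordered (ripening timepoints) or unordered (tissue panels); if any
    condition_order is set, all must be.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "species", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise TableError(f"design table missing columns {sorted(missing)}")
        if "condition_order" not in self.table.columns:
            self.table = self.table.assign(condition_order=pd.NA)
        if "block" not in self.table.columns:
            self.table = self.table.assign(block=pd.NA)
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise TableError(f"duplicate sample id {dup!r} in design")
        order = self.table["condition_order"]
        if order.notna().any() and order.isna().any():
            raise TableError("condition_order must be set for all samples or none")
        if order.notna().all():
            per_cond = self.table.groupby("condition")["condition_order"].nunique()
            if (per_cond > 1).any():
                bad = per_cond[per_cond > 1].index[0]
                raise TableError(f"condition {bad!r} has inconsistent condition_order")

    @property
    def is_ordered(self) -> bool:
        return bool(self.table["condition_order"].notna().all()) and len(self.table) > 0

    @property
    def has_block(self) -> bool:
        return bool(self.table["block"].notna().any())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def conditions_in_order(self) -> list[str]:
        """Condition labels, by condition_order when present else by first appearance."""
        if self.is_ordered:
            sub = self.table[["condition", "condition_order"]].drop_duplicates()
            return list(sub.sort_values(["condition_order", "condition"])["condition"])
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for_condition(self, condition: str) -> list[str]:
        sel = self.table["condition"] == condition
        return list(self.table.loc[sel, "sample_id"])

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        design_samples = set(self.sample_ids)
        matrix_samples = set(matrix.sample_ids)
        if design_samples != matrix_samples:
            raise TableError(
                "design/matrix sample mismatch: "
                f"{sorted(design_samples ^ matrix_samples)[:5]} ..."
            )


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    if "condition_order" in df.columns:
        df["condition_order"] = df["condition_order"].astype("Int64")
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OrthogroupTable
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupTable:
    """Orthogroup -> species -> member genes; the cross-species join key."""

    groups: dict[str, dict[str, list[str]]]
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for og, by_species in self.groups.items():
            for sp, genes in by_species.items():
                for g in genes:
                    key = (sp, g)
                    if key in seen:
                        raise TableError(
                            f"gene {g!r} of species {sp!r} listed in both "
                            f"{seen[key]!r} and {og!r}"
                        )
                    seen[key] = og
        self._gene_to_og = {sp: {} for sp in self.species}
        for (sp, g), og in seen.items():
            self._gene_to_og.setdefault(sp, {})[g] = og

    def orthogroup_of(self, species: str, gene: str) -> str | None:
        return self._gene_to_og.get(species, {}).get(gene)

    def members(self, orthogroup: str, species: str) -> list[str]:
        return self.groups.get(orthogroup, {}).get(species, [])

    @property
    def n_memberships(self) -> int:
        return sum(len(v) for sp in self.groups.values() for v in sp.values())


def parse_orthogroups(path) -> OrthogroupTable:
    """Parse the OrthoFinder ``Orthogroups.tsv`` dialect.

    First column: orthogroup id; remaining columns: species; cells:
    comma+space separated gene lists, possibly empty. Duplicate
    orthogroup ids and genes listed under two orthogroups for one
    species are hard errors.
    """
    groups: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableError("orthogroup table needs >= 2 columns")
        species = tuple(header[1:])
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            og = cells[0]
            if og in groups:
                raise TableError(f"duplicate orthogroup id {og!r}")
            cells = cells[1:] + [""] * (len(species) - len(cells) + 1)
            groups[og] = {
                sp: [tok for tok in cell.split(", ") if tok]
                for sp, cell in zip(species, cells)
            }
    return OrthogroupTable(groups, species)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og, by_species in table.groups.items():
            cells = [", ".join(by_species.get(sp, [])) for sp in table.species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BaitHitTable
# ---------------------------------------------------------------------------

@dataclass
class BaitHitTable:
    """Best-hit candidates linking named bait enzymes to assembly genes.

    ``table`` columns: bait_name, species, subject_gene_id,
    percent_identity, alignment_length, e_value, bit_score.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "bait_name", "species", "subject_gene_id", "percent_identity",
            "alignment_length", "e_value", "bit_score",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise TableError(f"bait hit table missing columns {sorted(missing)}")
        if len(self.table):
            if (self.table["bit_score"] < 0).any():
                raise TableError("bit_score must be >= 0")
            pid = self.table["percent_identity"]
            if ((pid < 0) | (pid > 100)).any():
                raise TableError("percent_identity must lie in [0, 100]")

    def for_species(self, species: str) -> "BaitHitTable":
        return BaitHitTable(self.table[self.table["species"] == species].reset_index(drop=True))


def parse_blast_outfmt6(path, bait_names: dict[str, str], species: str) -> BaitHitTable:
    """Parse 12-column BLAST tabular output and label hits with bait names.

    Rows whose query id is absent from ``bait_names`` are dropped (count
    logged). Malformed numeric fields raise with the offending line number.
    """
    records = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise TableError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            row = dict(zip(BLAST6_COLUMNS, parts))
            if row["qseqid"] not in bait_names:
                dropped += 1
                continue
            try:
                records.append({
                    "bait_name": bait_names[row["qseqid"]],
                    "species": species,
                    "subject_gene_id": row["sseqid"],
                    "percent_identity": float(row["pident"]),
                    "alignment_length": int(row["length"]),
                    "e_value": float(row["evalue"]),
                    "bit_score": float(row["bitscore"]),
                })
            except ValueError as exc:
                raise TableError(f"{path}: line {lineno}: malformed numeric field ({exc})") from exc
    if dropped:
        logger.info("dropped %d hits with query ids not in bait map", dropped)
    columns = ["bait_name", "species", "subject_gene_id", "percent_identity",
               "alignment_length", "e_value", "bit_score"]
    return BaitHitTable(pd.DataFrame(records, columns=columns))


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """gene id -> {pfam terms, kegg terms}; term sets may be empty."""

    annotations: dict[str, dict[str, frozenset[str]]]

    def pfam(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, {}).get("pfam", frozenset())

    def kegg(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, {}).get("kegg", frozenset())

    def term_map(self, namespace: str) -> dict[str, frozenset[str]]:
        return {g: terms.get(namespace, frozenset()) for g, terms in self.annotations.items()}


def read_annotations(path) -> AnnotationTable:
    """Read a TSV with columns gene_id, pfam, kegg (comma-separated terms)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise TableError(f"duplicate gene id {dup!r} in annotation table")
    ann = {}
    for row in df.itertuples(index=False):
        ann[row.gene_id] = {
            "pfam": frozenset(t for t in str(row.pfam).split(",") if t),
            "kegg": frozenset(t for t in str(row.kegg).split(",") if t),
        }
    return AnnotationTable(ann)


def write_annotations(table: AnnotationTable, path) -> None:
    rows = [
        {"gene_id": g, "pfam": ",".join(sorted(t["pfam"])), "kegg": ",".join(sorted(t["kegg"]))}
        for g, t in table.annotations.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "pfam", "kegg"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MetaboliteTable
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteTable:
    """Per-(species, compound, timepoint) chromatographic peak areas (AUC)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"species", "compound", "timepoint_order", "auc", "n_replicates"}
        missing = required - set(self.table.columns)
        if missing:
            raise TableError(f"metabolite table missing columns {sorted(missing)}")
        if len(self.table):
            if (self.table["auc"] < 0).any():
                raise TableError("AUC values must be >= 0")
            key = self.table[["species", "compound", "timepoint_order"]]
            if key.duplicated().any():
                raise TableError("(species, compound, timepoint) must be unique")


def read_metabolites(path) -> MetaboliteTable:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "compound": str})
    return MetaboliteTable(df)


def write_metabolites(table: MetaboliteTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def warn_unknown_species(og_table: OrthogroupTable, known_species) -> None:
    """Warn about orthogroup columns never referenced by any design."""
    unknown = [sp for sp in og_table.species if sp not in set(known_species)]
    if unknown:
        warnings.warn(
            f"orthogroup table has species columns with no design: {unknown}; "
            "they are retained but ignored downstream",
            stacklevel=2,
        )
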