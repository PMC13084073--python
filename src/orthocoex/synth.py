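"""Synthetic multi-species benchmark with a planted co-regulated pathway.

The generator emulates the discovery setting end to end: an olive-like
ripening design (6 cultivar blocks x 5 ordered timepoints), two
tissue-panel species, an orthology table linking them, a planted
co-regulated pathway module shared across all species, bait genes
inside that module, one unbaited "target enzyme" orthogroup annotated
as a 2OG-Fe(II) dioxygenase, decoy oxidase annotations on background
genes, and metabolite time-courses that decay with maturation. All
randomness flows from a single seed; every artifact can be written in
exactly the external formats the readers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import (
    AnnotationTable,
    BaitHitTable,
    ExpressionMatrix,
    MetaboliteTable,
    OrthogroupTable,
    SampleDesign,
    write_annotations,
    write_design,
    write_expression_matrix,
    write_metabolites,
    write_orthogroups,
)

_TISSUE_POOL = ("leaf", "flower", "stem", "root", "cambium")
_BAIT_POOL = ("GES", "G8H", "8HGO", "ISY", "IO", "7DLGT", "OMES", "ISP")
# Plausible Pfam labels for the bait enzymes (terpene synthase, P450s,
# dehydrogenases, a UDP glucosyltransferase).
_BAIT_PFAM = {
    "GES": "Terpene_synth_C", "G8H": "p450", "8HGO": "ADH_zinc_N",
    "ISY": "Epimerase", "IO": "p450", "7DLGT": "UDPGT",
    "OMES": "p450", "ISP": "Epimerase",
}
TARGET_PFAM_TERMS = ("2OG-FeII_Oxy", "DIOX_N")
_DECOY_OXIDASE_POOL = (
    "p450", "Cu-oxidase_3", "Peroxidase", "Rieske", "UDPGT",
    "Methyltransf_2", "Tyrosinase", "2OG-FeII_Oxy",
)
_GENERIC_PFAM_POOL = (
    "PK_Tyr_Ser-Thr", "WD40", "LRR_1", "Myb_DNA-binding", "RRM_1",
    "ABC_tran", "Helicase_C", "zf-C2H2",
)
_KEGG_MODULE_POOL = tuple(f"M{i:05d}" for i in range(1, 11))
PLANTED_KEGG_MODULE = "M_planted_pathway"


@dataclass
class SynthConfig:
    """Benchmark shape. Defaults are the study-like conditions.

    Three species (one olive-like time course, two tissue panels),
    2 500 orthogroups / 6 000 genes per species, a 40-orthogroup planted
    module containing 6 bait orthogroups and one unbaited target, NB
    counts with dispersion 0.2, and a 4-fold planted effect size.
    """

    seed: int = 42
    species: tuple[str, ...] = ("olive", "jasmine", "ash")
    n_orthogroups: int = 2500
    genes_per_species: int = 6000
    duplication_prob: float = 0.05
    loss_prob: float = 0.1
    module_size_ogs: int = 40
    n_bait_ogs: int = 6
    olive_blocks: int = 6
    olive_timepoints: int = 5
    olive_reps: int = 1
    panel_tissues: int = 4
    panel_reps: int = 3
    panel_off_tissue: tuple[str, ...] = ("flower", "root")
    target_copies: int = 2              # target OG is a small paralog family
    nb_dispersion: float = 0.2
    mean_log_expression: tuple[float, float] = (4.0, 1.5)  # (mu, sigma), ln scale
    module_mean_log_expression: tuple[float, float] = (5.0, 1.0)
    effect_size: float = 4.0
    background_smooth_frac: float = 0.7
    background_smooth_sd: float = 0.7   # ln-scale sd of trend coefficients
    background_loading_sd: float = 0.6  # panel low-rank tissue covariance
    background_idio_sd: float = 0.15
    block_effect_sd: float = 0.25       # ln-scale cultivar effects
    depth_sd: float = 0.2               # ln-scale library depth spread
    annotation_coverage: float = 0.6
    decoy_oxidase_rate: float = 0.02
    metabolite_noise: float = 0.15
    n_metabolite_compounds: int = 4     # decreasing compounds; one increasing added

    def __post_init__(self) -> None:
        if not self.n_bait_ogs < self.module_size_ogs:
            raise ValueError("n_bait_ogs must be < module_size_ogs")
        for p in (self.duplication_prob, self.loss_prob,
                  self.background_smooth_frac, self.annotation_coverage,
                  self.decoy_oxidase_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def olive_species(self) -> str:
        return self.species[0]

    @property
    def panel_species(self) -> tuple[str, ...]:
        return self.species[1:]

    @property
    def bait_names(self) -> tuple[str, ...]:
        return _BAIT_POOL[: self.n_bait_ogs]


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery."""

    planted_ogs: list[str]
    bait_ogs: list[str]
    bait_names: list[str]
    target_og: str
    module_genes: dict[str, list[str]]   # species -> planted-module genes
    target_genes: dict[str, list[str]]   # species -> target-orthogroup genes
    genes: dict[str, list[str]]          # species -> all gene ids
    decoy_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


@dataclass
class SynthData:
    """Everything one benchmark instance produced."""

    config: SynthConfig
    og_table: OrthogroupTable
    truth: GroundTruth
    counts: dict[str, ExpressionMatrix]
    tpm: dict[str, ExpressionMatrix]
    designs: dict[str, SampleDesign]
    bait_hits: BaitHitTable
    annotations: AnnotationTable
    metabolites: MetaboliteTable


# ---------------------------------------------------------------------------
# Orthology
# ---------------------------------------------------------------------------

def simulate_orthology(config: SynthConfig) -> tuple[OrthogroupTable, GroundTruth]:
    """Populate orthogroups with per-species copy number 0/1/2.

    Copy number is 0 with probability ``loss_prob`` and 2 with
    probability ``duplication_prob``; planted-module orthogroups are
    forced to keep >= 1 copy in every species. Genes beyond the
    orthogroup members are species-specific singletons absent from the
    table.
    """
    rng = np.random.default_rng([config.seed, 1])
    og_ids = [f"OG{i:07d}" for i in range(config.n_orthogroups)]
    u = rng.random((config.n_orthogroups, len(config.species)))
    copy_number = np.ones_like(u, dtype=int)
    copy_number[u < config.loss_prob] = 0
    copy_number[(u >= config.loss_prob)
                & (u < config.loss_prob + config.duplication_prob)] = 2

    planted_idx = np.sort(rng.choice(config.n_orthogroups,
                                     size=config.module_size_ogs, replace=False))
    copy_number[planted_idx] = np.maximum(copy_number[planted_idx], 1)
    bait_pick = np.sort(rng.choice(config.module_size_ogs,
                                   size=config.n_bait_ogs, replace=False))
    bait_idx = planted_idx[bait_pick]
    non_bait = np.setdiff1d(planted_idx, bait_idx)
    target_idx = int(rng.choice(non_bait))
    # the target is a conserved paralog family (cf. duplicated pathway
    # enzymes), not a fragile single-copy orthogroup
    copy_number[target_idx] = config.target_copies

    groups: dict[str, dict[str, list[str]]] = {og: {} for og in og_ids}
    genes: dict[str, list[str]] = {}
    for s, sp in enumerate(config.species):
        counter = 0
        sp_genes: list[str] = []
        for i, og in enumerate(og_ids):
            members = []
            for _ in range(copy_number[i, s]):
                gid = f"{sp}_g{counter:05d}"
                counter += 1
                members.append(gid)
            groups[og][sp] = members
            sp_genes.extend(members)
        while counter < config.genes_per_species:
            sp_genes.append(f"{sp}_g{counter:05d}")
            counter += 1
        genes[sp] = sp_genes

    planted_ogs = [og_ids[i] for i in planted_idx]
    truth = GroundTruth(
        planted_ogs=planted_ogs,
        bait_ogs=[og_ids[i] for i in bait_idx],
        bait_names=list(config.bait_names),
        target_og=og_ids[target_idx],
        module_genes={
            sp: [g for i in planted_idx for g in groups[og_ids[i]][sp]]
            for sp in config.species
        },
        target_genes={sp: list(groups[og_ids[target_idx]][sp]) for sp in config.species},
        genes=genes,
    )
    return OrthogroupTable(groups, tuple(config.species)), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _olive_design(config: SynthConfig) -> SampleDesign:
    rows = []
    sp = config.olive_species
    for b in range(1, config.olive_blocks + 1):
        for t in range(1, config.olive_timepoints + 1):
            for r in range(1, config.olive_reps + 1):
                rows.append({
                    "sample_id": f"{sp}_cv{b}_t{t}_r{r}", "species": sp,
                    "condition": f"t{t}", "condition_order": t,
                    "block": f"cv{b}", "replicate": r,
                })
    df = pd.DataFrame(rows)
    df["condition_order"] = df["condition_order"].astype("Int64")
    return SampleDesign(df)


def _panel_design(config: SynthConfig, sp: str) -> SampleDesign:
    tissues = _TISSUE_POOL[: config.panel_tissues]
    rows = [
        {"sample_id": f"{sp}_{tis}_r{r}", "species": sp, "condition": tis,
         "condition_order": pd.NA, "block": pd.NA, "replicate": r}
        for tis in tissues for r in range(1, config.panel_reps + 1)
    ]
    df = pd.DataFrame(rows)
    df["condition_order"] = df["condition_order"].astype("Int64")
    return SampleDesign(df)


def _draw_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mu)
    return rng.negative_binomial(r, p)


def simulate_expression(config: SynthConfig,
                        truth: GroundTruth) -> tuple[dict, dict, dict]:
    """NB counts per species with the planted module's archetypes.

    Olive-like: planted genes decrease monotonically over timepoints
    (total fold change = ``effect_size``, per-gene rate jitter), with
    per-gene multiplicative cultivar effects; background genes are flat
    or follow random smooth (linear + quadratic) maturation trends.
    Panel species: planted genes are high in all tissues except a
    designated off tissue; background tissue effects are drawn from a
    low-rank model (two canonical tissue contrasts per species plus
    idiosyncratic noise), mimicking the dominant covariance structure
    of real tissue panels. Planted-module genes draw their baseline
    from the well-expressed ``module_mean_log_expression`` regime -
    detectable expression is a premise of guilt-by-association. TPM is
    derived by column scaling to 1e6.
    """
    rng = np.random.default_rng([config.seed, 2])
    log_effect = np.log(config.effect_size)
    counts: dict[str, ExpressionMatrix] = {}
    tpm: dict[str, ExpressionMatrix] = {}
    designs: dict[str, SampleDesign] = {}
    mu_ln, sd_ln = config.mean_log_expression

    for sp in config.species:
        gene_list = truth.genes[sp]
        G = len(gene_list)
        module = np.isin(gene_list, truth.module_genes[sp])
        design = _olive_design(config) if sp == config.olive_species \
            else _panel_design(config, sp)
        designs[sp] = design
        tab = design.table
        conds = design.conditions_in_order()
        C = len(conds)
        cond_idx = tab["condition"].map({c: i for i, c in enumerate(conds)}).to_numpy()

        base = rng.normal(mu_ln, sd_ln, size=G)
        mod_mu, mod_sd = config.module_mean_log_expression
        base[module] = rng.normal(mod_mu, mod_sd, size=module.sum())
        effects = np.zeros((G, C))
        smooth = (~module) & (rng.random(G) < config.background_smooth_frac)
        if sp == config.olive_species:
            s = np.linspace(-0.5, 0.5, C)
            # planted decline: full drop = effect_size for every gene,
            # with per-gene curvature ("at different rates")
            gamma = rng.uniform(0.7, 1.3, size=module.sum())
            frac = np.linspace(0.0, 1.0, C)[None, :] ** gamma[:, None]
            effects[module] = -log_effect * (frac - frac.mean(axis=1, keepdims=True))
            a = rng.normal(0, config.background_smooth_sd, size=smooth.sum())
            b = rng.normal(0, config.background_smooth_sd, size=smooth.sum())
            quad = s ** 2 - (s ** 2).mean()
            effects[smooth] = np.outer(a, 2 * s) + np.outer(b, quad)
        else:
            off = config.panel_off_tissue[
                (config.species.index(sp) - 1) % len(config.panel_off_tissue)]
            arche = np.full(C, +log_effect / 2.0)
            arche[conds.index(off)] = -log_effect / 2.0
            jitter = rng.normal(0, 0.1, size=(module.sum(), C))
            effects[module] = arche[None, :] + jitter
            basis = rng.normal(0, 1, size=(2, C))
            basis -= basis.mean(axis=1, keepdims=True)
            basis /= np.linalg.norm(basis, axis=1, keepdims=True)
            loadings = rng.normal(0, config.background_loading_sd,
                                  size=(smooth.sum(), 2))
            idio = rng.normal(0, config.background_idio_sd, size=(smooth.sum(), C))
            effects[smooth] = loadings @ basis + idio

        n_samples = len(tab)
        log_mu = base[:, None] + effects[:, cond_idx]
        if design.has_block:
            blocks = sorted(tab["block"].astype(str).unique())
            block_idx = tab["block"].astype(str).map(
                {b: i for i, b in enumerate(blocks)}).to_numpy()
            block_eff = rng.normal(0, config.block_effect_sd, size=(G, len(blocks)))
            log_mu = log_mu + block_eff[:, block_idx]
        depth = rng.lognormal(0, config.depth_sd, size=n_samples)
        mu = np.exp(log_mu) * depth[None, :]
        y = _draw_counts(rng, mu, config.nb_dispersion).astype(float)

        cdf = pd.DataFrame(y, index=gene_list, columns=design.sample_ids)
        counts[sp] = ExpressionMatrix(cdf, "counts")
        colsum = cdf.sum(axis=0).replace(0, 1.0)
        tpm[sp] = ExpressionMatrix(cdf / colsum * 1e6, "TPM")
    return counts, tpm, designs


# ---------------------------------------------------------------------------
# Baits and annotations
# ---------------------------------------------------------------------------

def simulate_baits_and_annotations(
        config: SynthConfig, truth: GroundTruth,
        og_table: OrthogroupTable) -> tuple[BaitHitTable, AnnotationTable]:
    """High-scoring bait hits per species plus olive gene annotations.

    Each bait orthogroup yields one strong hit per species (and a couple
    of sub-threshold noise hits). Olive annotations: target genes carry
    the 2OG-Fe(II) dioxygenase Pfam terms, bait genes their enzyme
    family's term, planted genes a shared KEGG module label; decoy
    oxidase terms are sprinkled on background genes at
    ``decoy_oxidase_rate`` and ``annotation_coverage`` of background
    genes get generic terms.
    """
    rng = np.random.default_rng([config.seed, 3])
    records = []
    for sp in config.species:
        for bait, og in zip(truth.bait_names, truth.bait_ogs):
            members = og_table.members(og, sp)
            if not members:
                continue
            records.append({
                "bait_name": bait, "species": sp, "subject_gene_id": members[0],
                "percent_identity": float(rng.uniform(55, 95)),
                "alignment_length": int(rng.integers(200, 600)),
                "e_value": float(10.0 ** -rng.uniform(50, 150)),
                "bit_score": float(rng.uniform(300, 900)),
            })
            for _ in range(2):  # sub-threshold noise hits
                decoy = truth.genes[sp][int(rng.integers(len(truth.genes[sp])))]
                records.append({
                    "bait_name": bait, "species": sp, "subject_gene_id": decoy,
                    "percent_identity": float(rng.uniform(20, 35)),
                    "alignment_length": int(rng.integers(50, 200)),
                    "e_value": float(10.0 ** -rng.uniform(1, 5)),
                    "bit_score": float(rng.uniform(30, 90)),
                })
    hits = BaitHitTable(pd.DataFrame(records))

    sp = config.olive_species
    bait_gene_terms = {}
    for bait, og in zip(truth.bait_names, truth.bait_ogs):
        for g in og_table.members(og, sp):
            bait_gene_terms[g] = _BAIT_PFAM[bait]
    target_set = set(truth.target_genes[sp])
    module_set = set(truth.module_genes[sp])
    ann: dict[str, dict[str, frozenset[str]]] = {}
    decoys = []
    for g in truth.genes[sp]:
        pfam: set[str] = set()
        kegg: set[str] = set()
        if g in target_set:
            pfam.update(TARGET_PFAM_TERMS)
        elif g in bait_gene_terms:
            pfam.add(bait_gene_terms[g])
        elif g in module_set:
            if rng.random() < config.annotation_coverage:
                pfam.add(str(rng.choice(_GENERIC_PFAM_POOL)))
        else:
            if rng.random() < config.decoy_oxidase_rate:
                pfam.add(str(rng.choice(_DECOY_OXIDASE_POOL)))
                decoys.append(g)
            elif rng.random() < config.annotation_coverage:
                pfam.add(str(rng.choice(_GENERIC_PFAM_POOL)))
        if g in module_set:
            kegg.add(PLANTED_KEGG_MODULE)
        elif rng.random() < 0.3:
            kegg.add(str(rng.choice(_KEGG_MODULE_POOL)))
        ann[g] = {"pfam": frozenset(pfam), "kegg": frozenset(kegg)}
    truth.decoy_genes = decoys
    return hits, AnnotationTable(ann)


# ---------------------------------------------------------------------------
# Metabolites
# ---------------------------------------------------------------------------

def simulate_metabolites(config: SynthConfig, truth: GroundTruth) -> MetaboliteTable:
    """Decaying AUC trajectories per cultivar, plus one increasing compound.

    Series are indexed by cultivar (the grouping unit the percent-of-
    maximum scaling averages over); all compounds decay with maturation
    except an OME-like compound that accumulates.
    """
    rng = np.random.default_rng([config.seed, 4])
    cultivars = [f"cv{b}" for b in range(1, config.olive_blocks + 1)]
    compounds = [f"iridoid_{i + 1}" for i in range(config.n_metabolite_compounds)]
    rows = []
    T = config.olive_timepoints
    for cp, sign in [(c, -1.0) for c in compounds] + [("ome_like", +1.0)]:
        rate = rng.uniform(0.3, 0.8)
        for cv in cultivars:
            amp = rng.lognormal(10, 0.5)
            for t in range(1, T + 1):
                noise = np.exp(rng.normal(0, config.metabolite_noise)) \
                    if config.metabolite_noise > 0 else 1.0
                rows.append({
                    "species": cv, "compound": cp, "timepoint_order": t,
                    "auc": amp * np.exp(sign * rate * (t - 1)) * noise,
                    "n_replicates": 1,
                })
    return MetaboliteTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# One-call generation and fixture writing
# ---------------------------------------------------------------------------

def generate(config: SynthConfig | None = None) -> SynthData:
    config = config or SynthConfig()
    og_table, truth = simulate_orthology(config)
    counts, tpm, designs = simulate_expression(config, truth)
    hits, annotations = simulate_baits_and_annotations(config, truth, og_table)
    metabolites = simulate_metabolites(config, truth)
    return SynthData(config=config, og_table=og_table, truth=truth,
                     counts=counts, tpm=tpm, designs=designs,
                     bait_hits=hits, annotations=annotations,
                     metabolites=metabolites)


def write_fixtures(data: SynthData, outdir) -> Path:
    """Write the benchmark in the external formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_orthogroups(data.og_table, out / "Orthogroups.tsv")
    for sp in data.config.species:
        write_expression_matrix(data.counts[sp], out / f"{sp}_counts.tsv")
        write_expression_matrix(data.tpm[sp], out / f"{sp}_tpm.tsv")
        write_design(data.designs[sp], out / f"{sp}_design.tsv")
        _write_outfmt6(data.bait_hits.for_species(sp), out / f"{sp}_hits.outfmt6")
    with open(out / "bait_map.tsv", "w") as fh:
        fh.write("query_id\tbait_name\n")
        for bait in data.truth.bait_names:
            fh.write(f"{bait}_query\t{bait}\n")
    write_annotations(data.annotations, out / "olive_annotations.tsv")
    write_metabolites(data.metabolites, out / "metabolites.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        fh.write(data.truth.to_json())
    return out


def _write_outfmt6(hits: BaitHitTable, path) -> None:
    with open(path, "w") as fh:
        for r in hits.table.itertuples(index=False):
            qlen = r.alignment_length
            fh.write("\t".join(map(str, [
                f"{r.bait_name}_query", r.subject_gene_id,
                f"{r.percent_identity:.1f}", qlen, max(int(qlen * 0.1), 0), 0,
                1, qlen, 1, qlen, f"{r.e_value:.2e}", f"{r.bit_score:.1f}",
            ])) + "\n")


def bait_query_map(bait_names) -> dict[str, str]:
    return {f"{b}_query": b for b in bait_names}
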