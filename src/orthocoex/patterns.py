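"""Expression-pattern discovery with a batch self-organizing map.

Genes are summarized as condition-mean log2(TPM+1) profiles, row
Z-scored, and mapped onto a rectangular SOM grid (default 20 x 20 = 400
nodes). Codebook vectors are then hierarchically clustered (Ward on
Euclidean distances) and cut into k expression patterns (default 8);
genes inherit the cluster of their best-matching unit. For ordered
designs each cluster is labeled increasing / decreasing / flat by the
Spearman correlation of its mean profile with the condition rank.

The SOM is the batch variant: every epoch assigns all genes to their
nearest node and replaces each codebook vector by the Gaussian
neighborhood-weighted mean of the assigned profiles. With a fixed seed
the whole stage is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .tables_io import ExpressionMatrix, SampleDesign, TableError


@dataclass
class PatternParams:
    """SOM grid / training schedule and codebook clustering knobs."""

    grid_rows: int = 20
    grid_cols: int = 20
    epochs: int = 100
    initial_radius: float | None = None  # default max(grid)/2
    final_radius: float = 1.0
    init: str = "pca"
    seed: int = 0
    k_clusters: int = 8
    linkage: str = "ward"
    distance: str = "euclidean"
    direction_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < self.k_clusters or self.k_clusters < 1:
            raise ValueError("need grid_rows*grid_cols >= k_clusters >= 1")
        if self.init not in ("pca", "random"):
            raise ValueError("init must be 'pca' or 'random'")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def radius0(self) -> float:
        return self.initial_radius if self.initial_radius is not None \
            else max(self.grid_rows, self.grid_cols) / 2.0


@dataclass
class PatternModel:
    """Trained SOM codebook plus node/gene cluster assignments."""

    codebook: np.ndarray                      # nodes x conditions
    conditions: list[str]
    gene_ids: list[str]
    gene_bmu: np.ndarray                      # gene -> node index
    node_cluster: np.ndarray                  # node -> cluster id (1..k)
    gene_cluster: pd.Series                   # gene id -> cluster id
    cluster_direction: dict[int, str] = field(default_factory=dict)
    quantization_error_history: list[float] = field(default_factory=list)

    def genes_in_cluster(self, cluster_id: int) -> list[str]:
        return list(self.gene_cluster.index[self.gene_cluster == cluster_id])


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def condition_profiles(expr: ExpressionMatrix, design: SampleDesign) -> ExpressionMatrix:
    """Mean log2(TPM+1) per gene and condition, conditions in design order."""
    if expr.unit != "TPM":
        raise TableError("condition_profiles expects a TPM matrix")
    design.check_matches(expr)
    logtpm = np.log2(expr.values + 1.0)
    cols = {}
    for cond in design.conditions_in_order():
        samples = design.samples_for_condition(cond)
        if not samples:
            raise TableError(f"condition {cond!r} has no samples")
        cols[cond] = logtpm[samples].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols), "logTPM")


def zscore_rows(profiles: ExpressionMatrix) -> ExpressionMatrix:
    """Row-standardize profiles: (x - mean)/sd with sd over n-1.

    Constant rows become all-zero and are flagged in ``constant_rows``.
    """
    if profiles.values.shape[1] < 2:
        raise TableError("zscore_rows needs >= 2 conditions")
    arr = profiles.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] <= 1e-12
    z = np.where(constant[:, None], 0.0, (arr - mean) / np.where(constant[:, None], 1.0, sd))
    flags = frozenset(np.asarray(profiles.gene_ids, dtype=object)[constant])
    return ExpressionMatrix(
        pd.DataFrame(z, index=profiles.values.index, columns=profiles.values.columns),
        "zscore", flags,
    )


# ---------------------------------------------------------------------------
# SOM
# ---------------------------------------------------------------------------

def _grid_coordinates(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _pca_init(data: np.ndarray, params: PatternParams) -> np.ndarray:
    """Spread nodes over the plane of the first two principal axes."""
    mean = data.mean(axis=0)
    centered = data - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scales = s / max(np.sqrt(len(data)), 1.0)
    codebook = np.tile(mean, (params.n_nodes, 1))
    axes_along = [np.linspace(-2, 2, params.grid_rows), np.linspace(-2, 2, params.grid_cols)]
    coords = _grid_coordinates(params.grid_rows, params.grid_cols).astype(int)
    for axis in range(min(2, vt.shape[0])):
        vec = vt[axis]
        if vec[np.argmax(np.abs(vec))] < 0:  # deterministic sign
            vec = -vec
        pos = axes_along[axis][coords[:, axis]]
        codebook += np.outer(pos * scales[axis], vec)
    return codebook


def train_som(zscores: ExpressionMatrix, params: PatternParams):
    """Train a batch SOM on Z-profiles; returns (codebook, gene_bmu, qe_history).

    Per epoch: each gene is assigned its best-matching unit (minimal
    Euclidean distance, ties to the lowest node index), then every
    codebook vector is set to the Gaussian neighborhood-weighted mean of
    the assigned profiles (sigma = radius/2, truncated at grid distance
    >= radius). The radius decays linearly from ``initial_radius`` over
    the first 80% of epochs and is then held at ``final_radius``: the
    classic two-phase schedule, whose convergence phase at the default
    final radius of 1 reduces to per-node mean updates (so the
    quantization error is non-increasing there). Training stops early
    once assignments are stable at the final radius.
    """
    data = zscores.values.to_numpy(dtype=float)
    if data.size == 0:
        raise TableError("train_som: empty input")
    n_genes = data.shape[0]
    if n_genes < params.n_nodes:
        warnings.warn(
            f"fewer genes ({n_genes}) than SOM nodes ({params.n_nodes}); "
            "codebook will be underdetermined", stacklevel=2)
    if params.init == "pca":
        codebook = _pca_init(data, params)
    else:
        rng = np.random.default_rng(params.seed)
        idx = rng.choice(n_genes, size=params.n_nodes, replace=n_genes < params.n_nodes)
        codebook = data[idx].copy()

    coords = _grid_coordinates(params.grid_rows, params.grid_cols)
    grid_d2 = cdist(coords, coords, "sqeuclidean")
    decay_epochs = max(int(round(0.8 * params.epochs)), 1)
    qe_history: list[float] = []
    prev_bmu = None
    bmu = np.zeros(n_genes, dtype=int)
    for epoch in range(params.epochs):
        frac = min(epoch / decay_epochs, 1.0)
        radius = params.radius0 + (params.final_radius - params.radius0) * frac
        d2 = cdist(data, codebook, "sqeuclidean")
        bmu = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        qe_history.append(float(np.sqrt(d2[np.arange(n_genes), bmu]).mean()))
        if frac >= 1.0 and prev_bmu is not None and np.array_equal(bmu, prev_bmu):
            break
        prev_bmu = bmu.copy()
        sigma = max(radius / 2.0, 1e-6)
        h = np.exp(-grid_d2 / (2.0 * sigma ** 2))
        h[grid_d2 >= radius ** 2] = 0.0
        np.fill_diagonal(h, 1.0)
        counts = np.bincount(bmu, minlength=params.n_nodes).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, data)
        denom = h @ counts
        occupied = denom > 0
        codebook = np.where(occupied[:, None], (h @ sums) / np.where(
            occupied, denom, 1.0)[:, None], codebook)
    return codebook, bmu, qe_history


def cluster_codebook(codebook: np.ndarray, gene_bmu: np.ndarray,
                     params: PatternParams, gene_ids) -> tuple[np.ndarray, pd.Series]:
    """Agglomerative clustering of codebook vectors cut into k clusters.

    Genes inherit the cluster of their best-matching unit. Cluster ids
    are 1..k as produced by the dendrogram cut.
    """
    n_nodes = codebook.shape[0]
    if params.k_clusters > n_nodes:
        raise ValueError("k_clusters cannot exceed the number of nodes")
    if params.k_clusters == n_nodes:
        node_cluster = np.arange(1, n_nodes + 1)
    else:
        tree = linkage(codebook, method=params.linkage, metric=params.distance)
        node_cluster = fcluster(tree, t=params.k_clusters, criterion="maxclust")
    gene_cluster = pd.Series(node_cluster[gene_bmu], index=list(gene_ids), name="cluster")
    return node_cluster, gene_cluster


def label_cluster_direction(gene_cluster: pd.Series, profiles: ExpressionMatrix,
                            design: SampleDesign,
                            threshold: float = 0.3) -> dict[int, str]:
    """Label clusters increasing/decreasing/flat along the condition order.

    The cluster-mean profile is correlated (Spearman) against condition
    rank; |rho| <= threshold is 'flat'.
    """
    if not design.is_ordered:
        raise TableError(
            "direction labels require ordered conditions (condition_order unset)")
    conds = design.conditions_in_order()
    ranks = np.arange(len(conds))
    prof = profiles.values[conds]
    labels: dict[int, str] = {}
    for cid in sorted(gene_cluster.unique()):
        genes = gene_cluster.index[gene_cluster == cid]
        mean_profile = prof.loc[genes].mean(axis=0).to_numpy()
        if np.allclose(mean_profile, mean_profile[0]):
            labels[int(cid)] = "flat"
            continue
        rho = spearmanr(mean_profile, ranks).statistic
        if rho > threshold:
            labels[int(cid)] = "increasing"
        elif rho < -threshold:
            labels[int(cid)] = "decreasing"
        else:
            labels[int(cid)] = "flat"
    return labels


def fit_patterns(tpm: ExpressionMatrix, design: SampleDesign,
                 params: PatternParams, genes=None) -> PatternModel:
    """Profiles -> Z-scores -> SOM -> codebook clustering (-> directions)."""
    expr = tpm.subset_genes(genes) if genes is not None else tpm
    profiles = condition_profiles(expr, design)
    z = zscore_rows(profiles)
    # constant genes carry no pattern; keep them out of the map
    keep = [g for g in z.gene_ids if g not in z.constant_rows]
    z = z.subset_genes(keep)
    codebook, bmu, qe = train_som(z, params)
    node_cluster, gene_cluster = cluster_codebook(codebook, bmu, params, z.gene_ids)
    directions: dict[int, str] = {}
    if design.is_ordered:
        directions = label_cluster_direction(
            gene_cluster, profiles, design, params.direction_threshold)
    return PatternModel(
        codebook=codebook,
        conditions=list(profiles.values.columns),
        gene_ids=list(z.gene_ids),
        gene_bmu=bmu,
        node_cluster=node_cluster,
        gene_cluster=gene_cluster,
        cluster_direction=directions,
        quantization_error_history=qe,
    )
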