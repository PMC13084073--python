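"""Supporting statistics: term over-representation, correlation, PCA QC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, spearmanr

from .diffexpr import bh_adjust
from .tables_io import ExpressionMatrix


@dataclass
class CorrelationRecord:
    """A single pairwise correlation (Spearman or Pearson)."""

    pair: tuple[str, str]
    method: str
    rho: float | None
    n: int


def ora_hypergeometric(selected_genes, universe_genes,
                       term_map: dict[str, frozenset[str] | set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    For each term with >= 1 universe gene, the upper-tail probability
    P(X >= k) of drawing k term genes in a selection of size n from a
    universe of N genes containing K term genes; BH-adjusted across
    terms. The selection must be a subset of the universe.
    """
    universe = set(universe_genes)
    selected = set(selected_genes)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:5]}")
    by_term: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in universe:
            continue
        for t in terms:
            by_term.setdefault(t, set()).add(gene)
    N, n = len(universe), len(selected)
    rows = []
    for term in sorted(by_term):
        members = by_term[term]
        K = len(members)
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term": term, "k_selected_with_term": k, "n_selected": n,
            "K_universe_with_term": K, "N_universe": N, "p_value": min(p, 1.0),
        })
    out = pd.DataFrame(rows, columns=[
        "term", "k_selected_with_term", "n_selected",
        "K_universe_with_term", "N_universe", "p_value"])
    out["padj"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out


def metabolite_gene_spearman(gene_profile, metabolite_profile,
                             pair=("gene", "metabolite")) -> CorrelationRecord:
    """Spearman rho between two aligned ordered profiles (average-rank ties).

    A constant input leaves rho undefined; it is reported as None.
    """
    x = np.asarray(gene_profile, dtype=float)
    y = np.asarray(metabolite_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("profiles must be equal-length 1-d arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(pair=pair, method="spearman", rho=None, n=len(x))
    rho = float(spearmanr(x, y).statistic)
    return CorrelationRecord(pair=pair, method="spearman", rho=rho, n=len(x))


def pearson_coexpression(profile_a, profile_b, pair=("a", "b")) -> CorrelationRecord:
    x = np.asarray(profile_a, dtype=float)
    y = np.asarray(profile_b, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("profiles must be equal-length with n >= 3")
    if x.std() == 0 or y.std() == 0:
        return CorrelationRecord(pair=pair, method="pearson", rho=None, n=len(x))
    return CorrelationRecord(
        pair=pair, method="pearson", rho=float(np.corrcoef(x, y)[0, 1]), n=len(x))


def pca_variance_explained(logtpm: ExpressionMatrix) -> np.ndarray:
    """Variance fractions of the principal components across samples.

    Samples are the observations; genes are centered; fractions are
    non-increasing and sum to 1.
    """
    x = logtpm.values.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    x = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return np.zeros(len(var))
    return var / total
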