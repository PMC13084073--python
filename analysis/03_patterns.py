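#!/usr/bin/env python
"""Expression-pattern discovery in every species.

Olive: the DEGs' condition-mean log2(TPM+1) profiles are Z-scored,
mapped on a 20x20 batch SOM, the codebook Ward-clustered into 8
patterns, and each pattern labeled increasing/decreasing/flat along
ripening. Panel species: the same, over all genes passing a profile
variance filter (no replicated time course exists there, so no DE gate).
Writes gene->cluster tables and codebooks per species.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from orthocoex import diffexpr, patterns
from orthocoex.tables_io import read_design, read_expression_matrix

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
parser.add_argument("--de", type=Path, default=Path("results/de_olive.tsv"))
parser.add_argument("--out", type=Path, default=Path("results/patterns"))
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--min-profile-sd", type=float, default=0.5)
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
species = sorted(p.name[: -len("_design.tsv")]
                 for p in args.fixtures.glob("*_design.tsv"))
params = patterns.PatternParams(seed=args.seed)

for sp in species:
    tpm = read_expression_matrix(args.fixtures / f"{sp}_tpm.tsv", "TPM")
    design = read_design(args.fixtures / f"{sp}_design.tsv")
    if design.is_ordered:  # the ripening species: cluster the DEGs
        de = pd.read_csv(args.de, sep="\t")
        genes = diffexpr.significant_genes(de)
        note = f"{len(genes)} DEGs"
    else:  # tissue panel: variance-filtered genes
        prof = patterns.condition_profiles(tpm, design)
        sd = prof.values.std(axis=1, ddof=1)
        genes = list(sd.index[sd >= args.min_profile_sd])
        note = f"{len(genes)} variable genes"
    model = patterns.fit_patterns(tpm, design, params, genes)
    pd.DataFrame({"gene_id": model.gene_ids, "node": model.gene_bmu,
                  "cluster": model.gene_cluster.to_numpy()}).to_csv(
        args.out / f"{sp}_gene_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(model.codebook, columns=model.conditions).to_csv(
        args.out / f"{sp}_codebook.tsv", sep="\t", index_label="node")
    with open(args.out / f"{sp}_directions.json", "w") as fh:
        json.dump({str(k): v for k, v in model.cluster_direction.items()}, fh)
    sizes = model.gene_cluster.value_counts().sort_index()
    print(f"{sp}: SOM over {note}; cluster sizes "
          f"{sizes.to_dict()}"
          + (f"; directions {model.cluster_direction}" if model.cluster_direction else ""))
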