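#!/usr/bin/env python
"""Locate the pathway-carrying cluster in each tissue-panel species.

Known early-pathway enzymes (baits) are mapped to assembly genes via
their best BLAST hits; the expression cluster(s) holding the baits
become that species' candidate gene set.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from orthocoex import baits
from orthocoex.tables_io import parse_blast_outfmt6, parse_orthogroups, read_design

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
parser.add_argument("--patterns", type=Path, default=Path("results/patterns"))
parser.add_argument("--out", type=Path, default=Path("results/selections"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
bait_map = pd.read_csv(args.fixtures / "bait_map.tsv", sep="\t")
qmap = dict(zip(bait_map["query_id"], bait_map["bait_name"]))
og_table = parse_orthogroups(args.fixtures / "Orthogroups.tsv")

species = sorted(p.name[: -len("_design.tsv")]
                 for p in args.fixtures.glob("*_design.tsv"))
for sp in species:
    if read_design(args.fixtures / f"{sp}_design.tsv").is_ordered:
        continue  # the ripening species is gated by DE, not by baits
    hits = parse_blast_outfmt6(args.fixtures / f"{sp}_hits.outfmt6", qmap, sp)
    assignment = baits.assign_baits(hits)
    clusters = pd.read_csv(args.patterns / f"{sp}_gene_clusters.tsv",
                           sep="\t").set_index("gene_id")["cluster"]
    sel = baits.select_bait_cluster(assignment, clusters, og_table)
    with open(args.out / f"{sp}.json", "w") as fh:
        json.dump({"species": sp, "selected_cluster": sel.selected_cluster,
                   "bait_counts": {str(k): v for k, v in sel.bait_counts.items()},
                   "n_candidate_genes": sel.n_candidate_genes,
                   "n_candidate_orthogroups": sel.n_candidate_orthogroups,
                   "candidate_genes": sel.candidate_genes}, fh, indent=1)
    print(f"{sp}: baits per cluster {sel.bait_counts} -> "
          f"{sel.n_candidate_genes} candidate genes "
          f"({sel.n_candidate_orthogroups} orthogroups)")
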