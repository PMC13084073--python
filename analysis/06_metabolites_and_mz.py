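#!/usr/bin/env python
"""Metabolite profile scaling and theoretical EIC targets.

Scales each compound's AUC time-course to percent of its per-cultivar
maximum and averages across cultivars (the usual way to compare decay
kinetics on one axis), and prints the theoretical negative-mode adduct
m/z windows of the pathway standards used for chromatogram extraction.
"""

import argparse
from pathlib import Path

import pandas as pd

from orthocoex.mz import eic_window, scale_metabolite_profiles
from orthocoex.tables_io import read_metabolites

PATHWAY_STANDARDS = [
    ("7-deoxy-loganic acid", "C16H24O9", "M-H"),
    ("7-epi-loganic acid", "C16H24O10", "M-H"),
    ("7-epi-loganin", "C17H26O10", "M+formate"),
    ("7-deoxy-loganin", "C17H26O9", "M+formate"),
    ("oleoside-11-methyl ester", "C17H24O11", "M-H"),
    ("OME glucoside", "C23H34O16", "M+formate"),
    ("ligstroside", "C25H32O12", "M-H"),
    ("oleuropein", "C25H32O13", "M-H"),
]

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
parser.add_argument("--out", type=Path, default=Path("results/metabolites"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
profiles = scale_metabolite_profiles(read_metabolites(args.fixtures / "metabolites.tsv"))
profiles.per_species.to_csv(args.out / "scaled_per_species.tsv", sep="\t", index=False)
profiles.summary.to_csv(args.out / "scaled_summary.tsv", sep="\t", index=False)

print("cross-cultivar mean percent-of-maximum AUC:")
wide = profiles.summary.pivot(index="compound", columns="timepoint_order",
                              values="mean_pct").round(1)
print(wide.to_string())

print("\ntheoretical EIC targets (+/- 0.05):")
rows = []
for name, formula, adduct in PATHWAY_STANDARDS:
    w = eic_window(formula, adduct)
    rows.append({"compound": name, "formula": formula, "adduct": adduct,
                 "mz": w.center, "low": round(w.low, 4), "high": round(w.high, 4)})
    print(f"  [{adduct}]- {name} ({formula}): {w.center:.4f}")
pd.DataFrame(rows).to_csv(args.out / "eic_targets.tsv", sep="\t", index=False)
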