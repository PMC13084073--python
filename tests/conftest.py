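import numpy as np
import pandas as pd
import pytest

from orthocoex import pipeline, synth
from orthocoex.tables_io import ExpressionMatrix, SampleDesign


def make_design(conditions, reps=1, blocks=None, ordered=True, species="x"):
    """Small design-table builder used across the suite."""
    rows = []
    block_list = blocks or [None]
    for b in block_list:
        for i, cond in enumerate(conditions, start=1):
            for r in range(1, reps + 1):
                sid = f"{species}_{b or 'nb'}_{cond}_r{r}"
                rows.append({
                    "sample_id": sid, "species": species, "condition": cond,
                    "condition_order": i if ordered else pd.NA,
                    "block": b if b is not None else pd.NA, "replicate": r,
                })
    df = pd.DataFrame(rows)
    df["condition_order"] = df["condition_order"].astype("Int64")
    return SampleDesign(df)


def counts_matrix(values, gene_ids=None, sample_ids=None):
    arr = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=gene_ids, columns=sample_ids), "counts")


def inputs_from_synth(data: synth.SynthData) -> pipeline.PipelineInputs:
    return pipeline.PipelineInputs(
        olive_species=data.config.olive_species,
        panel_species=list(data.config.panel_species),
        counts=data.counts, tpm=data.tpm, designs=data.designs,
        og_table=data.og_table, bait_hits=data.bait_hits,
        annotations=data.annotations,
    )


def run_benchmark(config: synth.SynthConfig):
    data = synth.generate(config)
    result = pipeline.run_all(inputs_from_synth(data), pipeline.RunParams(seed=config.seed))
    return data, result


def target_recovered(data: synth.SynthData, result: pipeline.RunResult) -> bool:
    """Planted-truth oracle: any target-orthogroup olive gene in the
    dioxygenase tier of the triaged candidate list."""
    tier = set(result.integration.tiered_candidates.get("2OG_FeII_dioxygenase", []))
    return bool(set(data.truth.target_genes[data.config.olive_species]) & tier)


@pytest.fixture(scope="session")
def default_benchmark():
    """One full pipeline run on the default benchmark (seed 42)."""
    return run_benchmark(synth.SynthConfig(seed=42))


@pytest.fixture(scope="session")
def recovery_sweep():
    """Recovery flag and run summary for seeds 1..20 on default conditions."""
    outcomes = []
    for seed in range(1, 21):
        data, result = run_benchmark(synth.SynthConfig(seed=seed))
        outcomes.append({
            "seed": seed,
            "recovered": target_recovered(data, result),
            "summary": result.summary,
        })
    return outcomes


@pytest.fixture()
def small_synth_config():
    """A scaled-down benchmark for structural (non-statistical) checks."""
    return synth.SynthConfig(
        seed=7, n_orthogroups=250, genes_per_species=700,
        module_size_ogs=15, n_bait_ogs=5)
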