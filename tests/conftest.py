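import numpy as np
import pandas as pd
import pytest

from translatome.io import CountMatrix
from translatome.pipeline import analyze
from translatome.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small default-condition simulated experiment with ground truth."""
    cfg = SimConfig(n_genes=400, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def analyzed(small_experiment):
    """Full DE -> combine -> classify outputs on the small experiment."""
    cm, truth = small_experiment
    results, combined, table = analyze(cm)
    return cm, truth, results, combined, table


def make_count_matrix(counts, genotypes, treatments, gene_ids=None, extra=None):
    """Hand-build a CountMatrix from a 2-D array and per-sample design."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {"genotype": genotypes, "treatment": treatments},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if extra:
        for k, v in extra.items():
            meta[k] = v
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return CountMatrix(counts=df, sample_meta=meta)
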