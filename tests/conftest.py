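import numpy as np
import pytest

from grnfidelity.ensemble import (
    SearchConfig,
    build_all_ensembles,
    edge_statistics,
    sample_networks,
)
from grnfidelity.fidelity import records_from_stats, score_records
from grnfidelity.synthetic import make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12-gene noisy benchmark with one planted 3-gene module."""
    return make_dataset(n_genes=12, n_modules=1, module_size=3,
                        noise_sd=0.05, coverage=0.8, n_decoys=6, seed=42)


@pytest.fixture(scope="session")
def small_inference(small_dataset):
    """Light Phase-1 inference on the 12 core genes (shared, ~5 s)."""
    ds = small_dataset
    cfg = SearchConfig(k_max=2, ensemble_cap=60, attempt_budget=200)
    core = ds.expression.subset(ds.truth.genes)
    ensembles = build_all_ensembles(core, cfg, seed=7)
    networks = sample_networks(ensembles, n_networks=500, seed=8)
    stats = edge_statistics(networks)
    return ds, ensembles, networks, stats


@pytest.fixture(scope="session")
def scored_records(small_inference):
    ds, _ens, _nets, stats = small_inference
    return score_records(records_from_stats(stats, ann=ds.annotations), w=1.0)
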