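import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One small coupled simulation shared by read-only tests."""
    from epilink.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        seed=0,
        n_contigs=2,
        contig_length=150_000,
        n_genes=30,
        n_true_dmrs=12,
        n_true_degs=15,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    from epilink.annotation import derive_features, detect_cgi

    ds = small_dataset
    cgis = [
        iv
        for g in ds.genome.values()
        if not g.is_spike_in
        for iv in detect_cgi(g)
    ]
    lengths = {c: len(g) for c, g in ds.genome.items()}
    return derive_features(ds.genes, cgis, lengths)


@pytest.fixture()
def genomic_methylomes(small_dataset):
    return {
        s: df[df["contig"] != "lambda_spike"]
        for s, df in small_dataset.methylomes.items()
    }


def bh_oracle(p):
    """Literal Benjamini-Hochberg: sort, n*p/rank, cumulative minimum."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
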