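"""Shared fixtures: tiny deterministic communities and tables."""

from functools import reduce

import numpy as np
import pandas as pd
import pytest

import ednanet as en


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[10, 0, 3, 7], [0, 5, 5, 5], [1, 2, 3, 4]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3", "s4"],
        dtype=np.int64,
    )


@pytest.fixture
def toy_table(toy_counts) -> en.OtuTable:
    return en.OtuTable(counts=toy_counts, marker="M1")


def make_index(values: np.ndarray, otus=None, samples=None) -> en.IndexTable:
    """Wrap a raw value matrix as an IndexTable."""
    m, n = values.shape
    otus = otus or [f"O{i}" for i in range(m)]
    samples = samples or [f"s{j}" for j in range(n)]
    df = pd.DataFrame(values, index=otus, columns=samples)
    return en.IndexTable(values=df, provenance={o: () for o in otus})


def simulate_index(params: en.CommunityParams) -> tuple[en.IndexTable, en.SyntheticTruth]:
    """Full observation path: community -> reads -> filter -> ensemble index."""
    truth = en.generate_community(params)
    tables = en.sample_reads(truth)
    idx = reduce(
        en.ensemble_index,
        [en.index_from_table(en.prevalence_filter(t)) for t in tables],
    )
    return idx, truth


@pytest.fixture
def small_null_index() -> en.IndexTable:
    """Independent-OTU community (no gradients, no planted pairs)."""
    params = en.CommunityParams(
        n_otus=15, n_samples=40, n_env_gradients=0, planted_edges=(), seed=42
    )
    idx, _ = simulate_index(params)
    return idx
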