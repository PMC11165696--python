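import itertools

import numpy as np
import pandas as pd
import pytest

from gutsem import ClrArray


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table():
    """Six samples x five genera with varied depths and structural zeros."""
    return pd.DataFrame(
        [
            [40, 30, 20, 10, 0],
            [35, 35, 15, 10, 5],
            [60, 20, 10, 5, 5],
            [10, 10, 40, 30, 10],
            [5, 15, 45, 25, 10],
            [12, 8, 50, 20, 10],
        ],
        index=[f"S{i}" for i in range(6)],
        columns=[f"g{i}" for i in range(5)],
    )


def synthetic_clr_array(
    rng, n_case=30, n_control=30, n_taxa=8, n_instances=64, shift=None, noise=1.0
):
    """ClrArray built directly from Gaussian draws, case samples first.

    ``shift`` maps taxon index -> mean offset added to case samples; rows are
    re-centered so the CLR identity holds.
    """
    n = n_case + n_control
    values = rng.normal(0.0, noise, size=(n_instances, n, n_taxa))
    if shift:
        for taxon, s in shift.items():
            values[:, :n_case, taxon] += s
    values -= values.mean(axis=2, keepdims=True)
    labels = np.r_[np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)]
    arr = ClrArray(
        values,
        sample_ids=[f"S{i}" for i in range(n)],
        taxa=[f"g{i}" for i in range(n_taxa)],
        prior=0.5,
    )
    return arr, labels


def brute_force_expected_richness(counts, n):
    """Enumerate every equally likely subsample of size n (tiny depths only)."""
    pool = [i for i, c in enumerate(counts) for _ in range(c)]
    richness = [
        len({pool[i] for i in combo})
        for combo in itertools.combinations(range(len(pool)), n)
    ]
    return float(np.mean(richness))
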