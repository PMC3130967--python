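"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from groupica.datasets import EpochedDataset, GroupDataset


def amari_index(p: np.ndarray) -> float:
    """Amari performance index of a permutation-candidate matrix.

    Standard formula: for P = W_est @ A_true, measures how far P is from
    a scaled permutation; 0 means perfect separation. Independent of the
    ICA implementations under test.
    """
    p = np.abs(np.asarray(p, dtype=np.float64))
    n = p.shape[0]
    row = (p / p.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (p / p.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * n * (n - 1)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng: np.random.Generator, q: int = 4, samples: int = 8,
                 trials: int = 5, subject_id: str = "s0") -> EpochedDataset:
    return EpochedDataset(
        subject_id=subject_id,
        data=rng.standard_normal((q, samples * trials)),
        samples_per_epoch=samples,
        n_trials=trials,
        sampling_rate=250.0,
    )


@pytest.fixture
def small_dataset(rng) -> EpochedDataset:
    return make_dataset(rng)


@pytest.fixture
def small_group(rng) -> GroupDataset:
    return GroupDataset([make_dataset(rng, subject_id=f"s{i}") for i in range(3)])
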