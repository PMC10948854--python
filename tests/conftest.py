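import numpy as np
import pytest

from topolearn.datasets import CovariateSeries, ErpDataset
from topolearn.montage import Montage, biosemi64


@pytest.fixture(scope="session")
def montage64() -> Montage:
    return biosemi64()


@pytest.fixture(scope="session")
def montage16() -> Montage:
    """Small random-but-fixed montage for fast statistical tests."""
    rng = np.random.default_rng(2024)
    pos = rng.standard_normal((16, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(f"E{i:02d}" for i in range(16)), pos)


@pytest.fixture
def make_erps(montage16):
    """Factory for small average-referenced random ERP datasets."""

    def _make(n_subjects=8, n_times=20, seed=0, montage=None):
        montage = montage or montage16
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_subjects, montage.n_channels, n_times))
        data -= data.mean(axis=1, keepdims=True)
        return ErpDataset(
            data=data,
            sfreq=512.0,
            window_ms=(0.0, n_times * 1000.0 / 512.0),
            montage=montage,
            subject_ids=tuple(f"S{i:02d}" for i in range(n_subjects)),
        )

    return _make


@pytest.fixture
def make_covariate():
    def _make(subject_ids, seed=0, values=None):
        if values is None:
            values = np.random.default_rng(seed).standard_normal(len(subject_ids))
        return CovariateSeries(tuple(subject_ids), np.asarray(values, float))

    return _make
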