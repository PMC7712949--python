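import numpy as np
import pytest

from eegmodwt import CohortSpec, EEGRecord, Epoch


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort: 6 subjects/class, 30 s each (3 epochs/subject)."""
    return CohortSpec(n_subjects_per_class=6, duration=30.0, seed=42)


def make_record(data, fs=125.0, subject_id="S1", label="NC"):
    names = [f"ch{i + 1}" for i in range(np.atleast_2d(data).shape[0])]
    return EEGRecord(data=data, fs=fs, channel_names=names, subject_id=subject_id, label=label)


def make_epoch(data, fs=125.0, subject_id="S1", label="NC", epoch_index=0):
    data = np.atleast_2d(data)
    return Epoch(
        data=data,
        fs=fs,
        subject_id=subject_id,
        label=label,
        epoch_index=epoch_index,
        channel_names=[f"ch{i + 1}" for i in range(data.shape[0])],
    )


def hoeffding_brute(x, y):
    """Independent O(n^2) rank-counting oracle for Hoeffding's D."""
    n = len(x)

    def u(a):
        return 1.0 if a > 0 else (0.5 if a == 0 else 0.0)

    R = [1 + sum(u(x[i] - x[j]) for j in range(n) if j != i) for i in range(n)]
    S = [1 + sum(u(y[i] - y[j]) for j in range(n) if j != i) for i in range(n)]
    Q = [1 + sum(u(x[i] - x[j]) * u(y[i] - y[j]) for j in range(n) if j != i) for i in range(n)]
    d1 = sum((q - 1) * (q - 2) for q in Q)
    d2 = sum((r - 1) * (r - 2) * (s - 1) * (s - 2) for r, s in zip(R, S))
    d3 = sum((r - 2) * (s - 2) * (q - 1) for r, s, q in zip(R, S, Q))
    num = (n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3
    return 30.0 * num / (n * (n - 1) * (n - 2) * (n - 3) * (n - 4))
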