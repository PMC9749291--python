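import numpy as np
import pytest

from ctgmorse import CTGRecord, FHRSimConfig, simulate_cohort


@pytest.fixture
def clean_record() -> CTGRecord:
    """A 25-min defect-free record (flat-ish physiology, no artifacts)."""
    cfg = FHRSimConfig(
        duration_s=1500.0,
        dropout_per_10min=0.0,
        outlier_per_10min=0.0,
        spike_per_10min=0.0,
        edge_zero_probability=0.0,
        seed=3,
    )
    (rec, _label, ledger), = simulate_cohort(1, 0, cfg)
    assert ledger == []
    return rec


@pytest.fixture(scope="session")
def small_cohort():
    """30 normal + 10 distressed records with ledgered defects."""
    return simulate_cohort(30, 10, FHRSimConfig(seed=17))


def make_signal(values) -> np.ndarray:
    return np.asarray(values, dtype=float)
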