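import numpy as np
import pytest

from riboflux.tasep import GeneModel, SimConfig, simulate


@pytest.fixture(scope="session", autouse=True)
def warm_kernel():
    """Trigger the one-off numba compilation before any timed test."""
    m = GeneModel("warm", ("NNN",) * 4, alpha=0.5, lambdas=[1.0] * 4,
                  footprint=1)
    simulate(m, SimConfig(burn_in_steps=10, n_samples=10, sample_interval=2,
                          seed=0))


@pytest.fixture
def uniform_model():
    """50-codon gene, unit rates, low initiation (no interference)."""
    return GeneModel(
        "uniform", ("NNN",) * 50, alpha=1e-4, lambdas=np.ones(50)
    )


def batch_se(snapshot_indicator: np.ndarray, n_batches: int = 40) -> float:
    """Standard error of a snapshot-mean by the method of batch means."""
    n = snapshot_indicator.size
    k = n // n_batches
    if k < 1:
        return float(np.std(snapshot_indicator) / np.sqrt(max(n, 1)))
    trimmed = snapshot_indicator[: k * n_batches]
    means = trimmed.reshape(n_batches, k).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


@pytest.fixture
def se_estimator():
    return batch_se
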