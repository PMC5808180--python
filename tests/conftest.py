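import numpy as np
import pytest

from mvndfc import SimulationSpec, TimeSeriesMatrix, WindowConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def stationary_series():
    """A long stationary multi-ROI series with a known correlation target."""
    rng = np.random.default_rng(42)
    p = 6
    target = 0.5 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p))).astype(float)
    chol = np.linalg.cholesky(target)
    x = rng.standard_normal((240, p)) @ chol.T
    return TimeSeriesMatrix(x), target


@pytest.fixture(scope="session")
def small_cohort():
    """A quick low-dimensional two-group cohort for protocol-level tests."""
    spec = SimulationSpec(
        n_rois=8, n_volumes=60, n_per_group=5, mean_effect=0.5, noise_sd=0.3, seed=3
    )
    return simulate_cohort(spec)


@pytest.fixture
def default_window():
    return WindowConfig(width=50, step=8)
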