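import numpy as np
import pytest

from popcurv import response_model as rm
from popcurv.curvature_inference import FitConfig
from popcurv.pipeline import constant_curvature_rates


@pytest.fixture(scope="session")
def small_gains():
    """Rank-1 shared gain plus weak private gain for a 12-unit population."""
    return rm.GainCovariance.shared(12, 0.09, 0.01, rank=1)


@pytest.fixture(scope="session")
def study_gains():
    """Generator-default gain structure at the recovery-study size."""
    return rm.GainCovariance.shared(30, 0.09, 0.01, rank=1)


@pytest.fixture(scope="session")
def fast_fit_config():
    """Reduced-budget optimizer settings used throughout the test suite."""
    return FitConfig(n_iter=300, lr=0.03, n_mc=2, n_outer=5, n_inner=1,
                     window=100)


def make_dataset(gains, n_frames=7, d_star=1.5, curvature_deg=90.0,
                 n_trials=30, seed=0):
    """Simulated spike counts from a constant-curvature ground truth."""
    rates = constant_curvature_rates(gains, n_frames, d_star, curvature_deg,
                                     seed=seed)
    return rates, rm.simulate(rates, gains, n_trials, seed=seed + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
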