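import numpy as np
import pytest

from sero import (
    FitConfig,
    LinePhantomConfig,
    SchemeConfig,
    generate_direct_scheme,
    generate_line_phantom,
    generate_sero_scheme,
    generate_slice_shift_scheme,
    predict_signal,
)


@pytest.fixture(scope="session")
def study_config() -> SchemeConfig:
    """The reference acquisition configuration (75 mm FOV on a 1.5 mm grid,
    1000 shots at 150 ms spacing, four b-values, 1.5 s rejection threshold)."""
    return SchemeConfig(seed=20260922)


@pytest.fixture(scope="session")
def sero_scheme(study_config):
    return generate_sero_scheme(study_config)


@pytest.fixture(scope="session")
def direct_scheme(study_config):
    return generate_direct_scheme(study_config.with_(k=1))


@pytest.fixture(scope="session")
def shift_scheme(study_config):
    return generate_slice_shift_scheme(study_config)


@pytest.fixture(scope="session")
def small_config() -> SchemeConfig:
    """A reduced grid for solver tests: 12 positions, 3-voxel slices,
    150 shots.  The rejection threshold scales with the smaller FOV (the
    steady-state mean TR here is n*dt/k = 0.6 s)."""
    return SchemeConfig(n=12, k=3, m=150, min_mean_tr=0.4, seed=7)


@pytest.fixture(scope="session")
def small_sero_scheme(small_config):
    return generate_sero_scheme(small_config)


@pytest.fixture(scope="session")
def smooth_phantom():
    """A heavily softened line phantom (every edge smoothed)."""
    return generate_line_phantom(
        LinePhantomConfig(n=50, smooth_width=3, smooth_prob=1.0, seed=11)
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_line_phantom(
        LinePhantomConfig(n=small_config.n, smooth_width=2, smooth_prob=1.0, seed=5)
    )


@pytest.fixture(scope="session")
def small_noiseless(small_phantom, small_sero_scheme):
    return predict_signal(small_phantom, small_sero_scheme)


@pytest.fixture()
def fast_fit_config() -> FitConfig:
    return FitConfig(lam=0.0)
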