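import numpy as np
import pytest

from glymph_alps import (
    build_phantom,
    default_phantom_spec,
    eigen_scalars,
    fit_tensor,
    generate_cohort,
    make_gradient_table,
    simulate_signal,
)


@pytest.fixture(scope="session")
def gtab30():
    return make_gradient_table(30, 1000.0, 1)


@pytest.fixture(scope="session")
def phantom_spec():
    return default_phantom_spec()


@pytest.fixture(scope="session")
def noiseless_maps(gtab30, phantom_spec):
    """Factory: noiseless phantom -> fitted scalar maps, cached per pvs_weight."""
    cache = {}

    def _make(pvs_weight=0.0):
        if pvs_weight not in cache:
            spec = phantom_spec.replace(pvs_weight=pvs_weight)
            fld = build_phantom(spec)
            dwi = simulate_signal(fld, gtab30, s0=1000.0, noise_sigma=0.0)
            cache[pvs_weight] = (fld, eigen_scalars(fit_tensor(dwi, "wls")))
        return cache[pvs_weight]

    return _make


@pytest.fixture(scope="session")
def cohort_df():
    return generate_cohort(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
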