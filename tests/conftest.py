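import numpy as np
import pytest

from frocdwi import (EllipsoidLesion, FrocParams, PhantomSpec,
                     generate_parameter_maps, simulate_dwi_series,
                     breast_14b_protocol)


@pytest.fixture(scope="session")
def protocol():
    """The bundled 14-b-value breast protocol."""
    return breast_14b_protocol()


@pytest.fixture(scope="session")
def lesion_params():
    """The printed SSEPI lesion parameter set used for round-trip checks."""
    return FrocParams(D=0.85, beta=0.73, mu=3.5)


@pytest.fixture()
def small_phantom_spec():
    """A 16x16x4 phantom with one centered lesion and an air slab."""
    lesion = EllipsoidLesion(center=(10, 8, 1.5), semi_axes=(3.0, 3.0, 1.2),
                             params=FrocParams(D=0.73, beta=0.77, mu=3.39),
                             s0=1.1)
    return PhantomSpec(grid_shape=(16, 16, 4), lesions=(lesion,),
                       air_fraction=0.25, noise_sigma=0.0, seed=7)


@pytest.fixture()
def noiseless_phantom(small_phantom_spec, protocol):
    maps = generate_parameter_maps(small_phantom_spec)
    series = simulate_dwi_series(maps, protocol, 0.0, seed=7)
    return maps, series


def random_froc_params(rng, beta_max=0.95):
    """A valid random FROC parameter set inside the fitting bounds."""
    return FrocParams(
        D=float(rng.uniform(0.3, 2.5)),
        beta=float(rng.uniform(0.4, beta_max)),
        mu=float(rng.uniform(1.0, 12.0)),
    )
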