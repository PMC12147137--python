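import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import paragest as pg

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg():
    return pg.SpectrometerConfig()


@pytest.fixture(scope="session")
def library():
    return pg.default_library()


@pytest.fixture(scope="session")
def protocol(library):
    return pg.build_default_protocol(library.offsets)


@pytest.fixture(scope="session")
def dy_sample(library):
    return pg.generate_sample(["Dy"], [1.0], library)


@pytest.fixture(scope="session")
def singles_dictionary(library, protocol):
    """14-entry dictionary: every lanthanide alone at unit concentration."""
    return pg.build_dictionary(library, {1}, [1.0], protocol)


def random_sample(rng, n_pools, library):
    """A random small mixture with perturbed exchange parameters."""
    names = rng.choice(library.names, size=n_pools, replace=False)
    pools = []
    for name in names:
        base = library[name]
        pools.append(
            pg.LanthanidePoolParams(
                name=base.name,
                delta_omega=float(rng.uniform(-30, 16)),
                f=float(rng.uniform(5e-4, 0.01)),
                k_ex=float(rng.uniform(100, 2000)),
                t1_free=float(rng.uniform(0.8, 2.0)),
                t2_free=float(rng.uniform(0.1, 0.7)),
                t1_bound=float(rng.uniform(0.8, 2.0)),
                t2_bound=float(rng.uniform(0.005, 0.05)),
            )
        )
    conc = tuple(float(c) for c in rng.uniform(0.3, 2.0, size=n_pools))
    return pg.Sample(pools=tuple(pools), concentrations=conc)
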