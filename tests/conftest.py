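import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nichecentroid as nc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def spec5():
    return nc.GridSpec(n_rows=5, n_cols=5, x_origin=0.0, y_origin=5.0,
                       cell_size=1.0, crs_id="local")


@pytest.fixture
def constant_stack():
    """Two 10x10 layers, value 5 everywhere, no nodata."""
    spec = nc.GridSpec(n_rows=10, n_cols=10, x_origin=0.0, y_origin=10.0,
                       cell_size=1.0, crs_id="local")
    values = np.full((2, 10, 10), 5.0)
    return nc.EnvStack(spec=spec, layer_names=["a", "b"], values=values)


@pytest.fixture
def random_stack():
    """A 20x20 3-layer stack of seeded noise with a few nodata holes."""
    rng = np.random.default_rng(42)
    spec = nc.GridSpec(n_rows=20, n_cols=20, x_origin=0.0, y_origin=20.0,
                       cell_size=1.0, crs_id="local")
    values = rng.normal(size=(3, 20, 20))
    values[1, 3, 7] = spec.nodata
    values[2, 15, 2] = spec.nodata
    return nc.EnvStack(spec=spec, layer_names=["a", "b", "c"], values=values)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact seeded virtual species shared across tests."""
    cfg = nc.SyntheticConfig(n_rows=80, n_cols=80, seed=123)
    return nc.simulate(cfg)


def plot_distances(bundle):
    """True distances at the bundle's plot cells (brute-force lookup)."""
    from nichecentroid.io_geo import point_to_cell

    cells = [point_to_cell(bundle.stack.spec, x, y) for x, y in bundle.plots.xy]
    return np.array([bundle.true_distance.values[c] for c in cells])
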