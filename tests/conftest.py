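import numpy as np
import pytest

import pfacalc as pf


@pytest.fixture(scope="session")
def packaged_table():
    return pf.load_observations("packaged")


@pytest.fixture(scope="session")
def frozen():
    return pf.frozen_model()


@pytest.fixture(scope="session")
def geometry():
    return pf.ElectrodeGeometry()


@pytest.fixture(scope="session")
def study_map(geometry):
    """Analytic field map at the highest applied voltage of the study."""
    return pf.analytic_field(geometry, 1490.0)


@pytest.fixture(scope="session")
def numeric_map(geometry):
    """One finite-difference solve, shared across tests (the slow fixture)."""
    return pf.numeric_field(geometry, 1490.0, grid_spacing=0.05, domain_size=14.0)


@pytest.fixture(scope="session")
def probe_points(geometry):
    """Probe grid within 2 mm of the origin, excluding a 0.1 mm shell
    around the electrodes."""
    xs = np.linspace(-2.0, 2.0, 81)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    a = geometry.radius
    half = geometry.center_distance / 2
    keep = (
        (np.hypot(X, Y) <= 2.0)
        & (np.hypot(X - half, Y) > a + 0.1)
        & (np.hypot(X + half, Y) > a + 0.1)
    )
    return X[keep], Y[keep]
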