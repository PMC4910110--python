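import numpy as np
import pytest

import polarsite as ps


@pytest.fixture
def two_state():
    """Minimal polarizable manifold: E = (0, 1) eV, mu_01 = (1,0,0) e·Å."""
    dip = np.zeros((2, 2, 3))
    dip[0, 1, 0] = dip[1, 0, 0] = 1.0
    return ps.StateManifold(energies=[0.0, 1.0], dipoles=dip, charge=0.0)


@pytest.fixture(scope="session")
def reference_site():
    return ps.reference_site(seed=0)


@pytest.fixture(scope="session")
def reference_baths():
    """Small Ox/Red pair of reference bath trajectories (session-shared)."""
    spec = ps.reference_bath_spec(seed=0, n_frames=4000, dt=0.25)
    return ps.generate_bath(spec, "Ox"), ps.generate_bath(spec, "Red"), spec


def make_gaps(x, dt=1.0, ensemble="Ox"):
    x = np.asarray(x, float)
    return ps.GapSeries(ensemble=ensemble, times=np.arange(x.size) * dt, x=x)
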