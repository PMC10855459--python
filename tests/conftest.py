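import numpy as np
import pytest

from plugmd.fixtures import equilibrated_water_box
from plugmd.integrators import integrate_nve


@pytest.fixture(scope="session")
def water64_nve():
    """Shared 64-water surrogate NVE run: 1 ps equilibration at 300 K,
    then 10 ps of velocity Verlet at dt = 0.2 fs (0.6 nm cutoff)."""
    system, model = equilibrated_water_box(64, seed=1, T=300.0,
                                           equil_ps=1.0, cutoff=0.6)
    traj, records = integrate_nve(system, model, dt=2e-4, n_steps=50000,
                                  save_every=2500, record_every=10)
    return system, model, traj, records


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
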