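import numpy as np
import pytest

from cryoprepro.simulate import SimulationSpec, simulate_dataset
from cryoprepro.stack_io import ParticleStack


@pytest.fixture(scope="session")
def sim_small():
    """One modest simulated dataset shared by read-only tests."""
    spec = SimulationSpec(size=64, n_views=6, n_particles=80, snr=0.05, seed=3)
    stack, clean, truth = simulate_dataset(spec)
    return {"spec": spec, "stack": stack, "clean": clean, "truth": truth}


@pytest.fixture()
def random_stack():
    rng = np.random.default_rng(42)
    return ParticleStack(rng.normal(size=(12, 16, 16)).astype(np.float32), 1.3)


@pytest.fixture()
def smooth_image():
    """Compact smooth test image: structure well inside the field of view."""
    c = (32 - 1) / 2.0
    yy, xx = np.mgrid[0:32, 0:32]
    return (
        np.exp(-(((xx - c - 3) / 4.0) ** 2 + ((yy - c + 2) / 3.0) ** 2))
        + 0.5 * np.exp(-(((xx - c + 5) / 3.0) ** 2 + ((yy - c - 4) / 5.0) ** 2))
    )
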