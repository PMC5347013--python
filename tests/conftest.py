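import numpy as np
import pytest

from nksearch import ModelParams, place_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def warm_kernels():
    """Touch every numba kernel once so per-test timings are compile-free."""
    import nksearch as nk

    p = ModelParams(n_k=1, n_t0=1, n_o=3, n_b=1, L=15.0, D_acc=4.0, delta=2.0)
    scene = place_scene(p, 0)
    nk.run_simulation(scene, 1, t_max=0.5)
    nk.bd_run(scene, 1e-3, 1, t_max=0.1)
    nk.bd_disk_exit(1.0, 1.0, 0.01, 2, 1)
    nk.sample_disk_exit(1.0, 1.0, 1, size=2)
    return True


@pytest.fixture
def small_params():
    """A cheap but non-trivial continuous configuration."""
    return ModelParams(n_k=5, n_t0=5, n_o=30, L=20.0)
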