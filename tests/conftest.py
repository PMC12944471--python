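import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qcmap import AcquisitionContext, default_three_tube_phantom, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ctx_iso1mm():
    """Acquisition context on a 1 mm isotropic grid (kernel extent 7)."""
    return AcquisitionContext(spacing_mm=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_phantom():
    """Small three-tube phantom realisation shared across tests.

    48^3 at 1 mm so the 8 mm kernel realises a 7-voxel extent; noise-free
    variants are derived per test from the same spec.
    """
    spec = default_three_tube_phantom(seed=7, noise_sd=0.02, grid=48, spacing_mm=1.0)
    ctx = AcquisitionContext(spacing_mm=spec.spacing_mm)
    s_plus, s_minus, truth = simulate(spec, ctx)
    return spec, ctx, s_plus, s_minus, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
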