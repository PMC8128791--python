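import numpy as np
import pytest

from bctopt import (
    build_phantom, build_protocol, generate_spectrum, make_recipe,
    material_for_mixture, simulate_dose,
)


@pytest.fixture(scope="session")
def spectrum():
    return generate_spectrum()


@pytest.fixture(scope="session")
def filling_lean():
    """Least-dense study filling (12.5% glandularity)."""
    return material_for_mixture(make_recipe(0.125))

@pytest.fixture(scope="session")
def filling_dense():
    """Densest study filling (87.5% glandularity)."""
    return material_for_mixture(make_recipe(0.875))


@pytest.fixture(scope="session")
def small_phantom(filling_lean):
    return build_phantom("small", filling=filling_lean, voxel_spacing_mm=3.0)


@pytest.fixture(scope="session")
def small_dose_map(small_phantom, spectrum):
    """One moderately converged transport shared across tests."""
    protocol = build_protocol(25.0, 80.0)
    return simulate_dose(small_phantom, protocol, spectrum,
                         n_histories=60_000, seed=11)
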