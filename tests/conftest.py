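import numpy as np
import pytest

from memdeform.synthetic import (BilayerSpec, InclusionSpec,
                                 generate_trajectory, make_deformation_field)


@pytest.fixture(scope="session")
def flat_bilayer():
    """Noiseless flat bilayer at full system size (325 lipids/leaflet), 1 frame."""
    spec = BilayerSpec(n_frames=1, noise_sigma=0.0)
    return generate_trajectory(spec, seed=42)


@pytest.fixture(scope="session")
def small_tilted_system():
    """Small bilayer with a rigid 50°-tilted helix, 20 frames, mild noise."""
    spec = BilayerSpec(n_lipids_per_leaflet=60, n_frames=20, noise_sigma=1.0)
    inc = InclusionSpec(prescribed_tilt=50.0, azimuth=30.0)
    return generate_trajectory(spec, inc, seed=7)


@pytest.fixture(scope="session")
def gaussian_well_field():
    return make_deformation_field("radial_gaussian", amplitude=12.0,
                                  width=30.0, center=(75.0, 75.0))
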