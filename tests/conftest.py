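import numpy as np
import pytest

from calyxnano.synth import SyntheticClusterSpec, generate_synaptic_cluster


@pytest.fixture(scope="session")
def two_nc_spec():
    """Cluster with two well-separated planted nanoclusters, low noise."""
    return SyntheticClusterSpec(
        n_localizations=2000,
        disc_radius=150.0,
        axial_thickness=60.0,
        nanocluster_centers=((-75.0, 0.0), (75.0, 0.0)),
        nanocluster_radius=40.0,
        enrichment_factor=5.0,
        background_fraction=0.0,
        noise_sigma_xy=5.0,
        noise_sigma_z=10.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def two_nc_cluster(two_nc_spec):
    return generate_synaptic_cluster(two_nc_spec)


@pytest.fixture(scope="session")
def uniform_spec():
    """Homogeneous disc cluster (no planted structure)."""
    return SyntheticClusterSpec(
        n_localizations=1500,
        disc_radius=150.0,
        axial_thickness=60.0,
        nanocluster_centers=(),
        nanocluster_radius=0.0,
        enrichment_factor=1.0,
        background_fraction=0.0,
        noise_sigma_xy=0.0,
        noise_sigma_z=0.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
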