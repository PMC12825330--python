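import pytest

from shellcount import PhantomConfig, VoxelGeometry, generate_phantom

UNIT_GEOMETRY = VoxelGeometry(dx=1.0, dy=1.0, dz=1.0)


@pytest.fixture
def unit_geometry():
    """1 µm isotropic voxels: physical volume equals voxel count."""
    return UNIT_GEOMETRY


@pytest.fixture
def binned_geometry():
    """The 50%-binned grid of the standard acquisition."""
    from shellcount.phantom import BINNED_GEOMETRY

    return BINNED_GEOMETRY


@pytest.fixture(scope="session")
def small_phantom():
    """One modest phantom shared across read-only tests (~150 nuclei)."""
    cfg = PhantomConfig(
        volume_shape=(60, 128, 128), n_nuclei=150, transduction_prob=0.8, seed=3
    )
    return generate_phantom(cfg)
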