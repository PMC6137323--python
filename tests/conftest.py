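import numpy as np
import pytest

from cristamorph.volume_io import Compartment, LabelVolume


def digitized_sphere(radius_vox: int, voxel_size_A: float = 10.0,
                     code: int = int(Compartment.ICS)) -> LabelVolume:
    """Sphere of the given voxel radius, centred on a voxel centre."""
    n = 2 * radius_vox + 12
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
    grid = np.where(r2 < radius_vox ** 2, code, 0).astype(np.uint8)
    return LabelVolume(grid, voxel_size_A, provenance="synthetic sphere")


@pytest.fixture
def sphere30():
    return digitized_sphere(30)


@pytest.fixture
def width_params():
    """One large-footprint lamella whose 10/50/90% stations all sit on the
    width plateau - the fixture for width-recovery checks."""
    from cristamorph.phantom import PhantomParams

    def make(width_A, seed=1, voxel_size_A=10.0):
        return PhantomParams(radius_nm=140.0, n_cristae=1, lumen_width_A=width_A,
                             apex_angle_deg=78.0, junction_width_A=280.0,
                             crista_jitter_frac=0.0, apex_jitter_deg=0.0,
                             crista_lateral_halfwidth_A=900.0, crista_depth_frac=0.95,
                             voxel_size_A=voxel_size_A, seed=seed, n_granules=0)

    return make


@pytest.fixture
def recovery_params():
    """Phantom parameters for deterministic single-condition recovery tests."""
    from cristamorph.phantom import PhantomParams

    def make(**overrides):
        base = dict(radius_nm=100.0, n_cristae=2, lumen_width_A=140.0,
                    apex_angle_deg=78.0, junction_width_A=280.0,
                    crista_jitter_frac=0.0, apex_jitter_deg=0.0,
                    cristae_volume_fraction_target=0.12,
                    voxel_size_A=10.0, seed=1, n_granules=0)
        base.update(overrides)
        return PhantomParams(**base)

    return make
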