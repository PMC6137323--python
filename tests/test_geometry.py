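import numpy as np
import pytest

from cristamorph import geometry as g
from cristamorph.volume_io import Compartment, LabelVolume

from conftest import digitized_sphere

ICS = int(Compartment.ICS)


class TestCompartmentVolume:
    def test_cube(self):
        grid = np.zeros((20, 20, 20), np.uint8)
        grid[5:15, 5:15, 5:15] = ICS
        vol = LabelVolume(grid, 10.0)
        assert g.compartment_volume(vol, ICS) == pytest.approx(1.0e6)

    def test_absent_code_is_zero(self, sphere30):
        assert g.compartment_volume(sphere30, Compartment.GRANULE) == 0.0

    def test_sphere_within_1pct_of_closed_form(self, sphere30):
        expected = 4 / 3 * np.pi * 300.0 ** 3
        assert g.compartment_volume(sphere30, ICS) == pytest.approx(expected, rel=0.01)


class TestSurface:
    def test_sphere_mesh_watertight_genus0_area(self, sphere30):
        mesh = g.extract_surface(sphere30, ICS)
        assert mesh.is_watertight
        assert mesh.euler_number == 2  # genus 0
        assert mesh.area == pytest.approx(4 * np.pi * 300.0 ** 2, rel=0.03)

    def test_mesh_volume_agrees_with_voxel_count(self, sphere30):
        mesh = g.extract_surface(sphere30, ICS)
        assert g.mesh_enclosed_volume(mesh) == pytest.approx(
            g.compartment_volume(sphere30, ICS), rel=0.02)

    def test_single_voxel_closed_mesh(self):
        grid = np.zeros((9, 9, 9), np.uint8)
        grid[4, 4, 4] = ICS
        mesh = g.extract_surface(LabelVolume(grid, 10.0), ICS)
        assert mesh.is_watertight
        assert g.mesh_enclosed_volume(mesh) == pytest.approx(1000.0, rel=0.5)

    def test_two_blobs_two_components(self):
        grid = np.zeros((24, 24, 24), np.uint8)
        grid[3:7, 3:7, 3:7] = ICS
        grid[14:19, 14:19, 14:19] = ICS
        mesh = g.extract_surface(LabelVolume(grid, 10.0), ICS)
        assert len(mesh.split(only_watertight=False)) == 2

    def test_empty_mask_raises(self, sphere30):
        with pytest.raises(ValueError):
            g.extract_surface(sphere30, Compartment.MOM)

    def test_area_scaling_law(self, sphere30):
        mesh1 = g.extract_surface(sphere30, ICS)
        doubled = LabelVolume(sphere30.grid, 20.0)
        mesh2 = g.extract_surface(doubled, ICS)
        assert mesh2.area == pytest.approx(4 * mesh1.area, rel=1e-6)

    def test_error_shrinks_with_resolution(self):
        """Relative surface-area error decreases as the sphere is sampled finer."""
        errs = []
        for r in (6, 12, 24):
            vol = digitized_sphere(r)
            err = abs(g.extract_surface(vol, ICS).area / (4 * np.pi * (r * 10.0) ** 2) - 1)
            errs.append(err)
        assert errs[0] > errs[1] > errs[2]


class TestInterfaceDistance:
    def test_parallel_planes(self):
        grid = np.zeros((20, 16, 16), np.uint8)
        grid[5] = Compartment.IBM
        grid[10] = Compartment.MOM
        mean, sd, n = g.interface_distance(LabelVolume(grid, 10.0),
                                           Compartment.IBM, Compartment.MOM)
        assert mean == pytest.approx(50.0)
        assert sd == pytest.approx(0.0)

    def test_concentric_shells(self):
        n = 72
        zz, yy, xx = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2
        r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        grid = np.zeros((n, n, n), np.uint8)
        grid[(r >= 24.5) & (r < 25.5)] = Compartment.IBM
        grid[(r >= 29.5) & (r < 30.5)] = Compartment.MOM
        mean, sd, _ = g.interface_distance(LabelVolume(grid, 10.0),
                                           Compartment.IBM, Compartment.MOM)
        assert mean == pytest.approx(50.0, abs=4.0)

    def test_identical_masks_zero(self, sphere30):
        mean, sd, _ = g.interface_distance(sphere30, ICS, ICS)
        assert mean == 0.0 and sd == 0.0

    def test_absent_code_raises(self, sphere30):
        with pytest.raises(ValueError):
            g.interface_distance(sphere30, ICS, Compartment.MOM)


class TestCentralCrop:
    def test_identity(self, sphere30):
        out = g.central_crop(sphere30, 1.0)
        assert np.array_equal(out.grid, sphere30.grid)
        assert out.meta["cropped"] is False

    def test_slice_arithmetic(self):
        grid = np.zeros((100, 4, 4), np.uint8)
        grid[np.arange(100) % 7 == 0] = ICS
        out = g.central_crop(LabelVolume(grid, 10.0), 0.6)
        assert out.shape == (60, 4, 4)
        assert np.array_equal(out.grid, grid[20:80])
        assert out.meta["crop_z"] == (20, 80)

    def test_too_small_crop_raises(self):
        vol = LabelVolume(np.full((3, 3, 3), ICS, np.uint8), 10.0)
        with pytest.raises(ValueError):
            g.central_crop(vol, 0.1)
        with pytest.raises(ValueError):
            g.central_crop(vol, 0.0)
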