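import numpy as np
import pytest
from scipy import ndimage

from cristamorph.phantom import (CohortJitter, PhantomParams, PlacementError,
                                 apply_missing_wedge, condition_preset,
                                 generate_cohort, generate_phantom)
from cristamorph.volume_io import Compartment, LabelVolume

C = Compartment
CONN26 = np.ones((3, 3, 3), bool)


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self, recovery_params):
        p = recovery_params(voxel_size_A=15.0)
        v1, g1 = generate_phantom(p)
        v2, g2 = generate_phantom(p)
        assert np.array_equal(v1.grid, v2.grid)
        assert [c.lumen_width_A for c in g1.cristae] == [c.lumen_width_A for c in g2.cristae]

    def test_zero_cristae(self, recovery_params):
        vol, gt = generate_phantom(recovery_params(n_cristae=0, voxel_size_A=15.0))
        assert vol.count(C.CRISTA_MEMBRANE) == 0
        assert vol.count(C.ICS) == 0
        assert gt.cristae == []

    def test_ground_truth_counts_match_grid_exactly(self, recovery_params):
        vol, gt = generate_phantom(recovery_params(n_granules=3, voxel_size_A=15.0))
        counts = np.bincount(vol.grid.ravel(), minlength=7)
        for code in range(7):
            assert gt.voxel_counts[code] == counts[code]

    def test_compartment_nesting_membranes_closed(self, recovery_params):
        """No matrix or ICS voxel may touch background without crossing a
        membrane: the shells are closed before any wedge is applied."""
        vol, _ = generate_phantom(recovery_params(voxel_size_A=15.0))
        bg_dil = ndimage.binary_dilation(vol.grid == C.BACKGROUND, CONN26)
        assert not (bg_dil & (vol.grid == C.MATRIX)).any()
        assert not (bg_dil & (vol.grid == C.ICS)).any()

    def test_lumen_components_match_crista_count(self, recovery_params):
        vol, gt = generate_phantom(recovery_params(n_cristae=2, voxel_size_A=10.0))
        _, n = ndimage.label(vol.grid == C.ICS, structure=CONN26)
        assert n == len(gt.cristae) == 2

    def test_realized_width_by_direct_voxel_count(self, recovery_params):
        """Slab thickness counted along the lamella normal equals the nominal
        lumen width within a voxel (brute-force check on the grid)."""
        p = recovery_params(lumen_width_A=120.0, voxel_size_A=10.0)
        vol, gt = generate_phantom(p)
        lab, _ = ndimage.label(vol.grid == C.ICS, structure=CONN26)
        for k, ct in zip(range(1, len(gt.cristae) + 1), gt.cristae):
            vox = np.argwhere(lab == k)
            # lamellae are stacked along z: thickness = z-column run length
            cols = {}
            for z, y, x in vox:
                cols.setdefault((y, x), []).append(z)
            runs = [len(zs) for zs in cols.values()]
            thickness = np.percentile(runs, 90) * vol.voxel_size_A
            assert thickness == pytest.approx(ct.lumen_width_A, abs=vol.voxel_size_A)

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_phantom(PhantomParams(radius_nm=600.0, voxel_size_A=10.0))

    def test_overfull_placement_errors_with_achieved_count(self):
        params = PhantomParams(radius_nm=60.0, n_cristae=6, lumen_width_A=140.0,
                               crista_lateral_halfwidth_A=200.0,
                               voxel_size_A=15.0, seed=0, n_granules=0)
        with pytest.raises(PlacementError) as err:
            generate_phantom(params)
        assert err.value.achieved < err.value.requested == 6

    def test_tube_shape(self):
        p = PhantomParams(shape="tube", radius_nm=80.0, length_nm=320.0,
                          n_cristae=2, voxel_size_A=15.0, seed=3, n_granules=0,
                          cristae_volume_fraction_target=0.08)
        vol, gt = generate_phantom(p)
        assert vol.count(C.MOM) > 0 and len(gt.cristae) >= 1
        ext = [np.ptp(ax) for ax in np.nonzero(vol.grid == C.MOM)]
        assert ext[2] > 1.5 * ext[0]  # elongated along x


class TestPresets:
    def test_control_values(self):
        p = condition_preset("control")
        assert p.lumen_width_A == 120.0
        assert p.apex_angle_deg == 78.0
        assert p.junction_width_A == 290.0
        assert p.mim_mom_gap_A == 138.0
        assert p.radius_nm == 290.0

    def test_patient_values(self):
        p = condition_preset("patient")
        assert p.lumen_width_A == 164.0
        assert p.apex_angle_deg == 105.0
        assert p.junction_width_A == 261.0
        assert p.mim_mom_gap_A == 129.0
        assert p.radius_nm == 245.0

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="control.*patient"):
            condition_preset("ctrl")

    def test_patient_has_fewer_cristae(self):
        assert condition_preset("patient").n_cristae < condition_preset("control").n_cristae

    def test_volume_fraction_targets_realized(self):
        fracs = {}
        for name, target in (("control", 0.08), ("patient", 0.04)):
            p = condition_preset(name, radius_scale=0.5, voxel_size_A=15.0, seed=4)
            vol, gt = generate_phantom(p)
            c = gt.voxel_counts
            frac = (c[3] + c[4]) / c[5]
            assert frac == pytest.approx(target, rel=0.30)
            fracs[name] = frac
        assert fracs["patient"] < fracs["control"]


class TestCohort:
    def test_identical_seeds_identical_cohorts(self):
        p = condition_preset("control", radius_scale=0.4, voxel_size_A=20.0)
        a = generate_cohort(p, 3, seed=5)
        b = generate_cohort(p, 3, seed=5)
        for (va, _), (vb, _) in zip(a, b):
            assert np.array_equal(va.grid, vb.grid)

    def test_zero_jitter_repeats_nominals(self):
        p = condition_preset("control", radius_scale=0.4, voxel_size_A=20.0)
        zero = CohortJitter(radius_sigma_log=0, gap_sigma_log=0, junction_sigma_log=0,
                            lumen_width_frac=0, apex_deg=0, depth_frac=0,
                            fraction_sigma_log=0)
        cohort = generate_cohort(p, 3, jitter=zero, seed=5)
        for _, gt in cohort:
            assert gt.params.radius_nm == p.radius_nm
            assert gt.params.lumen_width_A == p.lumen_width_A
            assert gt.params.apex_angle_deg == p.apex_angle_deg

    def test_reported_dispersion_jitter_recovers_width_cv(self):
        """With the reported SD/mean jitters, the realized nominal lumen widths
        have CV ~ 32/120 (sampling error at n=40)."""
        p = condition_preset("control", radius_scale=0.4, voxel_size_A=20.0)
        jit = CohortJitter.reported_dispersion("control")
        rng_widths = []
        for _, gt in generate_cohort(p, 40, jitter=jit, seed=11):
            rng_widths.append(gt.params.lumen_width_A)
        cv = np.std(rng_widths, ddof=1) / np.mean(rng_widths)
        assert cv == pytest.approx(32 / 120, abs=0.08)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_cohort(condition_preset("control"), 0)


@pytest.fixture(scope="module")
def shell():
    n = 80
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
    grid = np.zeros((n, n, n), np.uint8)
    grid[(r >= 30) & (r < 33)] = C.MOM
    grid[r < 30] = C.MATRIX
    return LabelVolume(grid, 10.0)


class TestMissingWedge:

    def test_full_tilt_range_is_identity(self, shell):
        out = apply_missing_wedge(shell, 90.0)
        assert np.array_equal(out.grid, shell.grid)

    def test_polar_caps_eroded_equator_intact(self, shell):
        """A +-70 deg tilt range leaves membranes with near-axial normals
        unresolved: the spherical shell loses its polar caps only."""
        out = apply_missing_wedge(shell, 70.0)
        removed = (shell.grid == C.MOM) & (out.grid == C.BACKGROUND)
        assert removed.sum() > 0
        c = (shell.shape[0] - 1) / 2
        z_removed = np.abs(np.argwhere(removed)[:, 0] - c)
        assert z_removed.min() > 20          # all removals near the poles
        kept = out.grid == C.MOM
        z_kept = np.abs(np.argwhere(kept)[:, 0] - c)
        assert (z_kept < 10).sum() > 0       # equatorial band intact

    def test_non_membrane_codes_untouched(self, shell):
        for half in (40.0, 70.0, 89.0):
            out = apply_missing_wedge(shell, half)
            assert (out.grid == C.MATRIX).sum() == (shell.grid == C.MATRIX).sum()

    def test_invalid_angle(self, shell):
        with pytest.raises(ValueError):
            apply_missing_wedge(shell, 0.0)
        with pytest.raises(ValueError):
            apply_missing_wedge(shell, 95.0)
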