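"""Hemodynamic map tests with brute-force oracles and closed forms."""

import numpy as np
import pytest

from aortaflow import geometry as geo
from aortaflow import hemodynamics as hd
from aortaflow.constants import DEFAULT_CONSTANTS, PhysicalConstants
from aortaflow.errors import DataError, ParameterError
from conftest import make_field


def _line_setup(n=21, v_par=0.15, nt=20, frame_ms=50.0):
    """Single column of voxels on a straight 1 mm centerline."""
    cl = geo.Centerline(
        points=np.column_stack([np.zeros(n), np.zeros(n), np.arange(n, dtype=float)]),
        tangents=np.tile([0.0, 0.0, 1.0], (n, 1)),
        arc_length=np.arange(n, dtype=float),
    )
    mask = np.zeros((1, 1, n), bool)
    mask[0, 0, :] = True
    vel = np.zeros((1, 1, n, nt, 3))
    vel[..., 2] = v_par
    fld = make_field(vel, frame_duration=frame_ms)
    asn = geo.assign_voxels(mask, cl, (1, 1, 1))
    return fld, cl, asn


class TestForwardReverseFlow:
    def test_constant_parallel_velocity_closed_form(self):
        # 0.15 m/s for a full 1 s cycle through 1 mm^2 -> 0.15 mL/cycle
        fld, cl, asn = _line_setup(v_par=0.15, nt=20, frame_ms=50.0)
        ff, rf = hd.forward_reverse_flow(fld, asn, cl)
        assert np.allclose(ff[0, 0, :], 0.15)
        assert np.allclose(rf[0, 0, :], 0.0)

    def test_sign_flip_swaps_maps_exactly(self, candy_pipeline):
        iso = candy_pipeline["iso"]
        asn = candy_pipeline["assignment"]
        cl = candy_pipeline["centerline"]
        flipped = iso.copy_with(velocity=-iso.velocity)
        ff, rf = candy_pipeline["ff"], candy_pipeline["rf"]
        ff2, rf2 = hd.forward_reverse_flow(flipped, asn, cl)
        assert np.array_equal(ff[asn.mask], rf2[asn.mask])
        assert np.array_equal(rf[asn.mask], ff2[asn.mask])

    def test_zero_mean_sinusoid_balances(self):
        nt = 8
        fld, cl, asn = _line_setup(v_par=0.0, nt=nt)
        fld.velocity[..., 2] = 0.2 * np.sin(2 * np.pi * np.arange(nt) / nt)
        ff, rf = hd.forward_reverse_flow(fld, asn, cl)
        assert np.allclose(ff[asn.mask], rf[asn.mask])

    def test_band_flux_matches_stroke_volume(self, candy_pipeline):
        # conservation through a geometric 1 mm cross-section of the
        # ascending limb: summed FF equals the analytic stroke volume
        spec = candy_pipeline["spec"]
        truth = candy_pipeline["truth"]
        iso = candy_pipeline["iso"]
        mask = candy_pipeline["mask_iso"]
        ff = np.nan_to_num(candy_pipeline["ff"])
        rf = np.nan_to_num(candy_pipeline["rf"])
        dt_s = iso.frame_duration / 1000.0
        sv = np.clip(truth.flow_rate[0], 0, None).sum() * dt_s
        zw = np.arange(iso.grid_shape[2]) * iso.spacing[2] + iso.origin[2]
        xw = np.arange(iso.grid_shape[0]) * iso.spacing[0] + iso.origin[0]
        k = int(np.argmin(np.abs(zw - (spec.margin + spec.radius + 25.0))))
        band = np.zeros(iso.grid_shape, bool)
        band[:, :, k] = True
        band &= mask
        band[xw > spec.margin + spec.radius + spec.arch_radius] = False
        assert ff[band].sum() == pytest.approx(sv, rel=0.05)
        assert rf[band].sum() < 0.01 * ff[band].sum()

    def test_requires_isotropic_grid(self):
        fld, cl, asn = _line_setup()
        fld.spacing = (1.0, 1.0, 2.0)
        with pytest.raises(DataError):
            hd.forward_reverse_flow(fld, asn, cl)


class TestStasis:
    @pytest.mark.parametrize("speed, expected", [(0.05, 100.0), (0.5, 0.0)])
    def test_uniform_speed(self, speed, expected):
        vel = np.zeros((2, 2, 2, 10, 3))
        vel[..., 0] = speed
        assert np.allclose(hd.stasis_map(make_field(vel)), expected)

    def test_fractional_count(self):
        vel = np.zeros((1, 1, 1, 20, 3))
        vel[..., :, 0] = 0.5
        vel[0, 0, 0, :5, 0] = 0.05  # 5 of 20 frames slow
        assert hd.stasis_map(make_field(vel))[0, 0, 0] == pytest.approx(25.0)

    def test_matches_brute_force_on_random_fields(self, rng):
        vel = rng.normal(0, 0.12, (4, 5, 3, 7, 3))
        fld = make_field(vel)
        result = hd.stasis_map(fld)
        for idx in np.ndindex(4, 5, 3):
            count = 0
            for t in range(7):
                if np.sqrt(np.sum(vel[idx + (t,)] ** 2)) < 0.1:
                    count += 1
            assert result[idx] == pytest.approx(100.0 * count / 7, abs=1e-10)


class TestKineticEnergy:
    def test_single_frame_unit_speed(self):
        vel = np.zeros((1, 1, 1, 1, 3))
        vel[..., 0] = 1.0
        ke = hd.kinetic_energy_map(make_field(vel))
        assert ke[0, 0, 0] == pytest.approx(0.53)  # 0.5*1060*1e-9 J = 0.53 uJ

    def test_zero_field(self):
        assert np.all(hd.kinetic_energy_map(make_field(np.zeros((2, 2, 2, 3, 3)))) == 0)

    def test_quadratic_scaling(self, rng):
        vel = rng.normal(0, 0.3, (3, 3, 3, 5, 3))
        k1 = hd.kinetic_energy_map(make_field(vel))
        k2 = hd.kinetic_energy_map(make_field(2 * vel))
        assert np.allclose(k2, 4 * k1)

    def test_matches_brute_force_loop(self, rng):
        vel = rng.normal(0, 0.4, (3, 4, 2, 6, 3))
        result = hd.kinetic_energy_map(make_field(vel))
        rho, dv = 1060.0, 1e-9
        for idx in np.ndindex(3, 4, 2):
            total = 0.0
            for t in range(6):
                total += 0.5 * rho * dv * np.sum(vel[idx + (t,)] ** 2)
            assert result[idx] == pytest.approx(total * 1e6, rel=1e-12)

    def test_phantom_truth_agreement(self, candy_forward):
        _, fld, truth = candy_forward
        ke = hd.kinetic_energy_map(fld, truth.mask)
        assert np.allclose(ke[truth.mask], truth.kinetic_energy[truth.mask], rtol=1e-9)


class TestPeakVelocity:
    def test_single_frame_is_speed(self, rng):
        vel = rng.normal(0, 0.5, (3, 3, 3, 1, 3))
        fld = make_field(vel)
        pv = hd.peak_velocity_map(fld, np.array([0]))
        assert np.allclose(pv, np.linalg.norm(vel[..., 0, :], axis=-1))

    def test_adding_slower_frame_never_decreases(self, rng):
        vel = rng.normal(0, 0.5, (3, 3, 3, 4, 3))
        fld = make_field(vel)
        p1 = hd.peak_velocity_map(fld, np.array([0, 1, 2]))
        p2 = hd.peak_velocity_map(fld, np.array([0, 1, 2, 3]))
        assert np.all(p2 >= p1)

    def test_phantom_poiseuille_peak_recovered(self, candy_pipeline):
        iso = candy_pipeline["iso"]
        mask = candy_pipeline["mask_iso"]
        truth = candy_pipeline["truth"]
        systole = hd.detect_systole(iso, mask)
        pv = hd.peak_velocity_map(iso, systole, mask)
        assert np.nanmax(pv) == pytest.approx(truth.peak_speed, rel=0.03)

    def test_empty_frame_subset_rejected(self, rng):
        fld = make_field(rng.normal(0, 0.5, (2, 2, 2, 3, 3)))
        with pytest.raises(ParameterError):
            hd.peak_velocity_map(fld, np.array([], dtype=int))


class TestDetectSystole:
    def test_half_sine_window_in_first_40_percent(self, candy_pipeline):
        frames = hd.detect_systole(candy_pipeline["iso"], candy_pipeline["mask_iso"])
        assert frames.max() <= int(0.4 * candy_pipeline["iso"].n_frames)

    def test_constant_flow_selects_all_frames(self):
        vel = np.zeros((2, 2, 2, 6, 3))
        vel[..., 2] = 0.4
        fld = make_field(vel)
        frames = hd.detect_systole(fld, np.ones((2, 2, 2), bool))
        assert np.array_equal(frames, np.arange(6))

    def test_window_contains_global_peak(self, rng):
        vel = rng.normal(0, 0.1, (3, 3, 3, 12, 3))
        fld = make_field(vel)
        mask = np.ones((3, 3, 3), bool)
        frames = hd.detect_systole(fld, mask)
        peak = int(np.argmax(fld.speed()[mask].mean(axis=0)))
        assert peak in frames

    def test_zero_field_warns_returns_all(self):
        fld = make_field(np.zeros((2, 2, 2, 4, 3)))
        with pytest.warns(UserWarning):
            frames = hd.detect_systole(fld, np.ones((2, 2, 2), bool))
        assert len(frames) == 4


class TestProjections:
    def test_single_slice_projection_is_identity(self, rng):
        m = np.full((4, 4, 3), np.nan)
        m[:, :, 1] = rng.uniform(0, 1, (4, 4))
        assert np.allclose(hd.mean_projection(m, "z"), m[:, :, 1])
        assert np.allclose(hd.mip_projection(m, 2), m[:, :, 1])

    def test_constant_map_projects_constant_over_silhouette(self):
        m = np.full((4, 4, 4), np.nan)
        m[1:3, 1:3, :] = 0.7
        proj = hd.mean_projection(m, "z")
        assert np.allclose(proj[1:3, 1:3], 0.7)
        assert np.isnan(proj[0, 0])

    def test_mean_never_exceeds_mip(self, rng):
        m = rng.uniform(0, 2, (5, 5, 5))
        m[rng.uniform(size=(5, 5, 5)) < 0.3] = np.nan
        mean_p = hd.mean_projection(m, 0)
        mip_p = hd.mip_projection(m, 0)
        ok = np.isfinite(mean_p)
        assert np.all(mean_p[ok] <= mip_p[ok] + 1e-12)


class TestRegionalSummary:
    def _toy_labels(self):
        labels = np.full((2, 5, 1), -1, int)
        labels[0, :, 0] = 0
        labels[1, :, 0] = 1
        return geo.RegionLabels(labels=labels, boundaries=np.array([1.0, 2, 3, 4]))

    def test_hand_computed_region_mean(self, rng):
        labels = self._toy_labels()
        m = rng.uniform(0, 1, (2, 5, 1))
        out = hd.regional_summary({"ff": m}, labels)
        assert out.loc[out.region == "LVOT", "ff"].item() == pytest.approx(m[0, :, 0].mean())
        assert out.loc[out.region == "AAo", "ff"].item() == pytest.approx(m[1, :, 0].mean())

    def test_uniform_map_gives_uniform_means(self):
        labels = self._toy_labels()
        out = hd.regional_summary({"stasis": np.full((2, 5, 1), 42.0)}, labels)
        assert np.allclose(out.loc[out.region.isin(["LVOT", "AAo"]), "stasis"], 42.0)

    def test_empty_region_is_missing_not_zero(self):
        labels = self._toy_labels()
        out = hd.regional_summary({"ke": np.ones((2, 5, 1))}, labels)
        assert np.isnan(out.loc[out.region == "DDAo", "ke"].item())

    def test_means_bounded_by_extremes(self, rng):
        labels = self._toy_labels()
        m = rng.uniform(0, 3, (2, 5, 1))
        out = hd.regional_summary({"rf": m, "peak_velocity": m}, labels)
        for region, sel in (("LVOT", m[0, :, 0]), ("AAo", m[1, :, 0])):
            row = out[out.region == region]
            assert sel.min() <= row["rf"].item() <= sel.max()
            assert row["peak_velocity"].item() == pytest.approx(sel.max())


class TestReynolds:
    def test_closed_form(self):
        # Re = 1060 * 1.5 * 0.028 / 0.0035 = 12720
        mask = np.zeros((1, 1, 3), bool)
        mask[0, 0, :] = True
        asn = geo.VoxelPlaneAssignment(
            mask=mask,
            voxel_index=np.argwhere(mask),
            point_index=np.array([0, 1, 2]),
            axial_distance=np.zeros(3),
        )
        pv = np.array([[[0.5, 1.5, 0.4]]])
        d = np.array([30.0, 28.0, 30.0])
        re = hd.reynolds_number(pv, asn, d)
        assert re == pytest.approx(1060 * 1.5 * 0.028 / 0.0035, rel=1e-12)

    def test_viscosity_scaling(self):
        mask = np.ones((1, 1, 2), bool)
        asn = geo.VoxelPlaneAssignment(
            mask=mask, voxel_index=np.argwhere(mask),
            point_index=np.array([0, 1]), axial_distance=np.zeros(2),
        )
        pv = np.array([[[1.0, 0.5]]])
        d = np.array([20.0, 20.0])
        r1 = hd.reynolds_number(pv, asn, d)
        r2 = hd.reynolds_number(pv, asn, d, PhysicalConstants(viscosity=7.0e-3))
        assert r2 == pytest.approx(r1 / 2)

    def test_zero_velocity_gives_zero(self):
        mask = np.ones((1, 1, 2), bool)
        asn = geo.VoxelPlaneAssignment(
            mask=mask, voxel_index=np.argwhere(mask),
            point_index=np.array([0, 1]), axial_distance=np.zeros(2),
        )
        assert hd.reynolds_number(np.zeros((1, 1, 2)), asn, np.array([20.0, 20.0])) == 0.0


class TestInterpolation:
    def test_constant_field_preserved(self):
        vel = np.full((8, 8, 8, 3, 3), 0.3)
        fld = make_field(vel, spacing=(2.4, 2.4, 2.4))
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        iso, mask_iso = hd.interpolate_isotropic(fld, mask)
        assert iso.spacing == (1.0, 1.0, 1.0)
        assert np.allclose(iso.velocity, 0.3, atol=1e-9)

    def test_linear_field_reproduced(self):
        # cubic splines reproduce polynomials up to degree 3 away from the
        # grid boundary (the edge extension perturbs the last few voxels)
        nz = 12
        z = np.arange(nz) * 2.0
        vel = np.zeros((6, 6, nz, 2, 3))
        vel[..., 2] = (0.01 * z)[None, None, :, None]
        fld = make_field(vel, spacing=(2.0, 2.0, 2.0))
        mask = np.zeros((6, 6, nz), bool)
        mask[1:5, 1:5, 2:10] = True
        iso, _ = hd.interpolate_isotropic(fld, mask)
        zw = np.arange(iso.grid_shape[2]) * 1.0 + iso.origin[2]
        mid = iso.velocity[3, 3, :, 0, 2]
        inner = (zw >= 6) & (zw <= 16)
        assert np.allclose(mid[inner], 0.01 * zw[inner], atol=1e-4)

    def test_lumen_volume_roughly_preserved(self, candy_pipeline):
        spec = candy_pipeline["spec"]
        truth = candy_pipeline["truth"]
        mask_iso = candy_pipeline["mask_iso"]
        vol_acq = truth.mask.sum() * np.prod(spec.spacing)
        vol_iso = mask_iso.sum() * 1.0
        assert vol_iso == pytest.approx(vol_acq, rel=0.05)

    def test_empty_mask_rejected(self):
        fld = make_field(np.zeros((4, 4, 4, 2, 3)))
        with pytest.raises(DataError):
            hd.interpolate_isotropic(fld, np.zeros((4, 4, 4), bool))


def test_stasis_phantom_truth_exact(candy_forward):
    _, fld, truth = candy_forward
    stasis = hd.stasis_map(fld, truth.mask)
    assert np.array_equal(stasis[truth.mask], truth.stasis[truth.mask])
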