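"""Scan-plane planning: mask PCA, plane fits, saturation band, quality
factor, display-slice resampling."""

import numpy as np
import pytest

from spineplan.errors import (DegenerateMaskError, InsufficientDiscsError,
                              InsufficientPointsError, OutOfBoundsError)
from spineplan.geometry import angle_between_lines, rotation_about_axis
from spineplan.heatmaps import Candidate
from spineplan.labeling import DiscTemplate, LabelAssignment
from spineplan.planning import (ScanPlane, disc_principal_axes,
                                fit_long_axis_planes, place_saturation_band,
                                quality_factor, select_display_slice,
                                transverse_plane_for_disc)


def _ellipsoid_mask(semis, shape=(48, 48, 48), spacing=1.0, rot=None):
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    pts = (idx - center) * spacing
    if rot is not None:
        pts = pts @ rot  # world -> body frame is R^T x
    return np.sum((pts / np.asarray(semis)) ** 2, axis=-1) <= 1.0


class TestPrincipalAxes:
    def test_axis_aligned_ellipsoid_normal(self):
        mask = _ellipsoid_mask((20, 15, 4))
        axes = disc_principal_axes(mask, (1, 1, 1))
        assert angle_between_lines(axes.axes[2], [0, 0, 1]) < 1.0
        assert axes.variances[0] > axes.variances[1] > axes.variances[2]
        assert not axes.isotropic

    def test_ball_flags_isotropy(self):
        mask = _ellipsoid_mask((10, 10, 10))
        axes = disc_principal_axes(mask, (1, 1, 1))
        assert axes.isotropic

    def test_rotated_ellipsoid_recovers_normal(self):
        rot = rotation_about_axis([1, 0, 0], 10.0)
        mask = _ellipsoid_mask((20, 15, 4), rot=rot)
        axes = disc_principal_axes(mask, (1, 1, 1))
        true_normal = rot @ np.array([0.0, 0.0, 1.0])
        assert angle_between_lines(axes.axes[2], true_normal) < 1.0

    def test_tiny_mask_rejected(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2, 2, 2] = True
        with pytest.raises(DegenerateMaskError):
            disc_principal_axes(mask, (1, 1, 1))

    def test_axes_orthonormal(self):
        mask = _ellipsoid_mask((18, 12, 5))
        axes = disc_principal_axes(mask, (1, 1, 1)).axes
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-9)


class TestTransversePlane:
    def test_untilted_disc_gets_axial_normal(self, default_phantom):
        _, (label_vol, _, truth) = default_phantom
        mask = label_vol.mask("disc_L3/4")
        axes = disc_principal_axes(mask, label_vol.spacing, label_vol.origin)
        plane = transverse_plane_for_disc(mask, axes, label_vol.spacing,
                                          label_vol.origin)
        assert angle_between_lines(plane.normal, [0, 0, 1]) < 0.5

    def test_tilted_disc_normal_recovered(self, default_phantom):
        _, (label_vol, _, truth) = default_phantom
        for lv in ("L1/2", "L5/S1"):   # 16 degree tilt levels
            mask = label_vol.mask(f"disc_{lv}")
            axes = disc_principal_axes(mask, label_vol.spacing,
                                       label_vol.origin)
            plane = transverse_plane_for_disc(mask, axes, label_vol.spacing,
                                              label_vol.origin)
            err = angle_between_lines(plane.normal, truth.disc_normals[lv])
            assert err < 1.5

    def test_center_in_posterior_decile(self, default_phantom):
        _, (label_vol, _, truth) = default_phantom
        mask = label_vol.mask("disc_L3/4")
        axes = disc_principal_axes(mask, label_vol.spacing, label_vol.origin)
        plane = transverse_plane_for_disc(mask, axes, label_vol.spacing,
                                          label_vol.origin)
        ys = label_vol.index_to_world(np.argwhere(mask))[:, 1]
        assert plane.center[1] <= np.quantile(ys, 0.10)

    def test_frames_orthonormal(self, default_phantom):
        _, (label_vol, _, truth) = default_phantom
        mask = label_vol.mask("disc_L2/3")
        axes = disc_principal_axes(mask, label_vol.spacing, label_vol.origin)
        plane = transverse_plane_for_disc(mask, axes, label_vol.spacing,
                                          label_vol.origin)
        u, v = plane.in_plane_axes
        assert abs(np.dot(u, v)) < 1e-9
        assert abs(np.dot(u, plane.normal)) < 1e-9
        assert abs(np.linalg.norm(np.cross(u, v)) - 1) < 1e-9


class TestLongAxisPlanes:
    def test_straight_spine_axis_aligned(self):
        centers = np.array([[0.0, 0.0, z] for z in (0, 35, 70, 105)])
        sag, cor = fit_long_axis_planes(centers)
        np.testing.assert_allclose(sag.normal, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(sag.center, centers.mean(axis=0))
        np.testing.assert_allclose(cor.normal, [0, 1, 0], atol=1e-9)

    def test_lateral_lean_matches_tls_oracle(self):
        rng = np.random.default_rng(3)
        lean = rotation_about_axis([0, 1, 0], 5.0)
        centers = np.stack([lean @ np.array([0.0, 3.0 * np.sin(z / 40.0), z])
                            for z in np.linspace(0, 140, 6)])
        sag, cor = fit_long_axis_planes(centers)
        # independent total-least-squares via SVD
        q = centers - centers.mean(axis=0)
        long_oracle = np.linalg.svd(q, full_matrices=False)[2][0]
        long_fit = np.cross(sag.normal, cor.normal)
        assert angle_between_lines(long_fit, long_oracle) < 0.5

    def test_mirror_symmetry_invariance(self):
        rng = np.random.default_rng(4)
        centers = np.stack([[0.0, float(rng.normal(0, 4)), 35.0 * i]
                            for i in range(5)])
        mirrored = centers * np.array([-1.0, 1.0, 1.0])
        sag_a, _ = fit_long_axis_planes(centers)
        sag_b, _ = fit_long_axis_planes(mirrored)
        np.testing.assert_allclose(sag_a.normal, sag_b.normal, atol=1e-9)
        np.testing.assert_allclose(sag_a.center, sag_b.center, atol=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientPointsError):
            fit_long_axis_planes(np.array([[0.0, 0.0, 0.0]]))


def _axis_plane(center, normal, u, v, extent):
    return ScanPlane(center=center, normal=normal, in_plane_axes=(u, v),
                     extent=extent)


class TestSaturationBand:
    def _disc_mask(self):
        mask = np.zeros((40, 60, 40), bool)
        mask[10:30, 40:54, 10:30] = True  # anterior-most voxel at y=53
        return mask

    def test_offset_arithmetic_axis_aligned(self):
        mask = self._disc_mask()
        cor = _axis_plane((0, 0, 0), [0, 1, 0], [1, 0, 0], [0, 0, 1],
                          (60.0, 60.0))
        band = place_saturation_band(mask, cor, (1, 1, 1), (0, 0, 0),
                                     offset_distance=10.0, thickness=30.0)
        assert band.center[1] == pytest.approx(53.0 + 10.0 + 15.0)
        np.testing.assert_allclose(band.normal, [0, 1, 0])

    def test_band_never_contains_disc_voxels(self):
        mask = self._disc_mask()
        cor = _axis_plane((0, 0, 0), [0, 1, 0], [1, 0, 0], [0, 0, 1],
                          (60.0, 60.0))
        band = place_saturation_band(mask, cor, (1, 1, 1), (0, 0, 0),
                                     offset_distance=5.0, thickness=20.0)
        pts = np.argwhere(mask).astype(float)
        s = pts @ band.normal
        near = np.dot(band.center, band.normal) - band.thickness / 2
        assert np.all(s < near)

    def test_tilted_coronal_normal_copied_exactly(self):
        mask = self._disc_mask()
        n = rotation_about_axis([0, 0, 1], 8.0) @ np.array([0.0, 1.0, 0.0])
        u = rotation_about_axis([0, 0, 1], 8.0) @ np.array([1.0, 0.0, 0.0])
        cor = _axis_plane((0, 0, 0), n, u, [0, 0, 1], (60.0, 60.0))
        band = place_saturation_band(mask, cor, (1, 1, 1), (0, 0, 0))
        assert abs(np.dot(band.normal, n) - 1.0) < 1e-9

    def test_band_exiting_volume_reports_feasible_offset(self):
        mask = self._disc_mask()
        cor = _axis_plane((0, 0, 0), [0, 1, 0], [1, 0, 0], [0, 0, 1],
                          (60.0, 60.0))
        with pytest.raises(OutOfBoundsError, match="feasible"):
            place_saturation_band(
                mask, cor, (1, 1, 1), (0, 0, 0), offset_distance=10.0,
                thickness=30.0,
                world_bounds=(np.zeros(3), np.array([40.0, 60.0, 40.0])))


def _assignment(labels, points):
    mapping = {lab: (None if p is None else Candidate(np.asarray(p, float),
                                                      200.0, lab))
               for lab, p in zip(labels, points)}
    return LabelAssignment(mapping=mapping, matching_error=0.0)


class TestQualityFactor:
    def _template(self):
        pts = [(0.0, 0.0, -35.0 * i) for i in range(5)]
        labels = tuple(f"D{i}" for i in range(5))
        return DiscTemplate.from_positions(labels, pts), pts, labels

    def test_perfect_geometry_scores_one(self):
        t, pts, labels = self._template()
        assert quality_factor(_assignment(labels, pts), t) == \
               pytest.approx(1.0, abs=1e-12)

    def test_one_missing_scales_by_fraction(self):
        t, pts, labels = self._template()
        pts = list(pts)
        pts[2] = None
        assert quality_factor(_assignment(labels, pts), t) == \
               pytest.approx(0.8, abs=1e-12)

    def test_monotone_in_spacing_deviation(self):
        t, pts, labels = self._template()
        prev = 1.1
        for eps in (0.0, 1.0, 2.0, 4.0, 8.0):
            pts_dev = [(0.0, 0.0, -(35.0 + eps) * i) for i in range(5)]
            qf = quality_factor(_assignment(labels, pts_dev), t)
            assert 0.0 <= qf <= 1.0
            assert qf < prev or eps == 0.0
            prev = qf

    def test_single_disc_raises(self):
        t, pts, labels = self._template()
        only = [pts[0]] + [None] * 4
        with pytest.raises(InsufficientDiscsError):
            quality_factor(_assignment(labels, only), t)


class TestDisplaySlice:
    def test_axis_aligned_plane_equals_array_slice(self, default_phantom):
        _, (_, image, _) = default_phantom
        i0 = image.shape[0] // 2
        center = image.index_to_world(
            [i0, (image.shape[1] - 1) / 2, (image.shape[2] - 1) / 2])
        plane = _axis_plane(center, [1, 0, 0], [0, 1, 0], [0, 0, 1],
                            ((image.shape[1] - 1) * image.spacing[1],
                             (image.shape[2] - 1) * image.spacing[2]))
        ds = select_display_slice(image, plane, spacing=image.spacing[1])
        assert ds.coverage == 1.0
        np.testing.assert_allclose(ds.image, image.voxels[i0], atol=1e-4)

    def test_tilted_plane_matches_independent_interpolator(self,
                                                           default_phantom):
        from scipy.interpolate import RegularGridInterpolator
        _, (_, image, _) = default_phantom
        rot = rotation_about_axis([1, 0, 0], 5.0)
        plane = ScanPlane(center=image.world_center(),
                          normal=rot @ np.array([1.0, 0.0, 0.0]),
                          in_plane_axes=(rot @ np.array([0.0, 1.0, 0.0]),
                                         rot @ np.array([0.0, 0.0, 1.0])),
                          extent=(60.0, 60.0))
        ds = select_display_slice(image, plane, spacing=1.5)
        axes = [image.origin[a] + image.spacing[a] * np.arange(image.shape[a])
                for a in range(3)]
        interp = RegularGridInterpolator(axes, image.voxels.astype(float),
                                         bounds_error=False, fill_value=0.0)
        nu, nv = ds.image.shape
        iu = (np.arange(nu) - (nu - 1) / 2) * 1.5
        iv = (np.arange(nv) - (nv - 1) / 2) * 1.5
        pts = (plane.center[None, None]
               + iu[:, None, None] * plane.in_plane_axes[0]
               + iv[None, :, None] * plane.in_plane_axes[1])
        expected = interp(pts.reshape(-1, 3)).reshape(nu, nv)
        assert np.max(np.abs(ds.image - expected)) < 1e-6

    def test_grazing_plane_reports_partial_coverage(self, default_phantom):
        _, (_, image, _) = default_phantom
        lo, hi = image.world_bounds()
        plane = _axis_plane(hi - 1.0, [1, 0, 0], [0, 1, 0], [0, 0, 1],
                            (80.0, 80.0))
        ds = select_display_slice(image, plane, spacing=1.5)
        assert 0.0 < ds.coverage < 1.0

    def test_png_export_round_trip_shape(self, default_phantom, tmp_path):
        from PIL import Image
        _, (_, image, _) = default_phantom
        plane = _axis_plane(image.world_center(), [1, 0, 0], [0, 1, 0],
                            [0, 0, 1], (60.0, 90.0))
        ds = select_display_slice(image, plane, spacing=1.5)
        ds.save_png(tmp_path / "s.png")
        img = Image.open(tmp_path / "s.png")
        assert img.size == ds.image.shape  # PIL size is (width, height)

    def test_plane_outside_volume_raises(self, default_phantom):
        _, (_, image, _) = default_phantom
        lo, hi = image.world_bounds()
        plane = _axis_plane(hi + 200.0, [1, 0, 0], [0, 1, 0], [0, 0, 1],
                            (20.0, 20.0))
        with pytest.raises(OutOfBoundsError):
            select_display_slice(image, plane)
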