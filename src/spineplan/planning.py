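"""Scan-plane prescription from labeled disc segmentations.

Per-disc transverse slice groups take their normal from the principal
component of the disc mask closest to the head-foot axis and their
center from the posterior disc edge.  The sagittal and coronal planes
come from a least-squares (total least squares) fit of the spine long
axis through the disc centers.  A saturation band is placed anterior to
the most anterior disc point along the coronal normal, and a scalar
quality factor in [0, 1] summarizes how well the realized inter-disc
spacings agree with the template (and how many discs were found).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import (DegenerateMaskError, InsufficientDiscsError,
                     InsufficientPointsError, OutOfBoundsError)
from .geometry import complete_frame, unit
from .labeling import DiscTemplate, LabelAssignment
from .volume import ImageVolume, Volume

log = logging.getLogger(__name__)


@dataclass
class PrincipalAxes:
    """Orthonormal axes of a voxel mask, sorted by descending variance."""

    axes: np.ndarray        # rows = axes
    variances: np.ndarray
    isotropic: bool = False


@dataclass
class ScanPlane:
    center: np.ndarray
    normal: np.ndarray
    in_plane_axes: tuple[np.ndarray, np.ndarray]
    extent: tuple[float, float] = (160.0, 160.0)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = unit(self.normal)
        u, v = self.in_plane_axes
        self.in_plane_axes = (unit(u), unit(v))
        for a in self.in_plane_axes:
            if abs(np.dot(a, self.normal)) > 1e-9:
                raise ValueError("in-plane axes must be orthogonal to normal")

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(),
                "normal": self.normal.tolist(),
                "in_plane_axes": [a.tolist() for a in self.in_plane_axes],
                "extent": list(self.extent)}


@dataclass
class SaturationBand:
    center: np.ndarray
    normal: np.ndarray
    thickness: float
    offset_distance: float

    def to_dict(self) -> dict:
        return {"center": np.asarray(self.center).tolist(),
                "normal": np.asarray(self.normal).tolist(),
                "thickness": self.thickness,
                "offset_distance": self.offset_distance}


@dataclass
class ScanPlan:
    sagittal: ScanPlane
    coronal: ScanPlane
    transverse: dict[str, ScanPlane]
    sat_band: Optional[SaturationBand]
    quality_factor: float
    disc_labels: tuple[str, ...]
    vertebra_labels: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sagittal": self.sagittal.to_dict(),
            "coronal": self.coronal.to_dict(),
            "transverse": {lv: p.to_dict() for lv, p in self.transverse.items()},
            "sat_band": self.sat_band.to_dict() if self.sat_band else None,
            "quality_factor": self.quality_factor,
            "disc_labels": list(self.disc_labels),
            "vertebra_labels": list(self.vertebra_labels),
        }


def _mask_world_coords(mask: np.ndarray, spacing, origin) -> np.ndarray:
    idx = np.argwhere(np.asarray(mask))
    return np.asarray(origin, dtype=float) + idx * np.asarray(spacing, dtype=float)


def disc_principal_axes(mask: np.ndarray, spacing, origin=(0, 0, 0),
                        isotropy_ratio: float = 1.05) -> PrincipalAxes:
    """PCA of a binary mask's voxel world coordinates.

    Axes are rows sorted by descending variance, each sign-oriented to
    have non-negative dot product with (+X, +Y, +Z) respectively.  Masks
    under 10 voxels are rejected; near-isotropic masks are flagged but
    still decomposed.
    """
    pts = _mask_world_coords(mask, spacing, origin)
    if pts.shape[0] < 10:
        raise DegenerateMaskError(
            f"mask has {pts.shape[0]} voxels; need >= 10")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    for i in range(3):
        if axes[i, i] < 0:
            axes[i] = -axes[i]
    iso = bool(evals[0] / max(evals[2], 1e-12) < isotropy_ratio)
    if iso:
        log.warning("disc_principal_axes: near-isotropic mask "
                    "(variance ratio %.3f)", evals[0] / evals[2])
    return PrincipalAxes(axes=axes, variances=evals, isotropic=iso)


def posterior_edge_point(mask: np.ndarray, spacing, origin=(0, 0, 0),
                         fraction: float = 0.05) -> np.ndarray:
    """Centroid of the most posterior ``fraction`` of mask voxels along
    -Y: a noise-robust stand-in for 'the posterior edge point'."""
    pts = _mask_world_coords(mask, spacing, origin)
    if pts.shape[0] == 0:
        raise DegenerateMaskError("empty mask")
    cut = np.quantile(pts[:, 1], fraction)
    sel = pts[pts[:, 1] <= cut]
    return sel.mean(axis=0)


def transverse_plane_for_disc(mask: np.ndarray, axes: PrincipalAxes,
                              spacing, origin=(0, 0, 0)) -> ScanPlane:
    """Transverse slice-group plane of one disc: normal = the principal
    axis most aligned with the head-foot axis (flipped toward +Z),
    centered at the posterior edge point."""
    dots = np.abs(axes.axes @ np.array([0.0, 0.0, 1.0]))
    normal = axes.axes[int(np.argmax(dots))]
    if axes.isotropic:
        log.warning("transverse_plane_for_disc: isotropic disc; "
                    "falling back to +Z normal")
        normal = np.array([0.0, 0.0, 1.0])
    if normal[2] < 0:
        normal = -normal
    center = posterior_edge_point(mask, spacing, origin)
    u, v = complete_frame(normal, preferred=np.array([1.0, 0.0, 0.0]))
    return ScanPlane(center=center, normal=normal, in_plane_axes=(u, v))


def fit_long_axis_planes(disc_centers: np.ndarray
                         ) -> tuple[ScanPlane, ScanPlane]:
    """Least-squares sagittal and coronal planes through disc centers.

    The spine long axis is the total-least-squares line through the
    centers.  The sagittal plane contains the long axis and the centers'
    anterior-posterior spread (its normal is the smallest-variance PCA
    axis, i.e. +X for a midline spine); the coronal plane is orthogonal
    to it, also containing the long axis.  Both are centered at the
    centroid.
    """
    pts = np.asarray(disc_centers, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InsufficientPointsError("need at least 2 disc centers")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    cov = q.T @ q
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    long_axis = axes[0] if axes[0, 2] >= 0 else -axes[0]
    # transverse spread of the centers defines the sagittal orientation
    if evals[1] < 1e-9 * max(evals[0], 1.0):
        log.warning("fit_long_axis_planes: collinear centers; "
                    "falling back to world axes")
        sag_normal = np.array([1.0, 0.0, 0.0])
        sag_normal = unit(sag_normal - np.dot(sag_normal, long_axis) * long_axis)
    else:
        sag_normal = axes[2]
    if sag_normal[0] < 0:
        sag_normal = -sag_normal
    cor_normal = np.cross(long_axis, sag_normal)
    if cor_normal[1] < 0:
        cor_normal = -cor_normal
    cor_normal = unit(cor_normal)
    sag_u, sag_v = complete_frame(sag_normal, preferred=np.array([0.0, 1.0, 0.0]))
    cor_u, cor_v = complete_frame(cor_normal, preferred=np.array([1.0, 0.0, 0.0]))
    sagittal = ScanPlane(center=centroid, normal=sag_normal,
                         in_plane_axes=(sag_u, sag_v))
    coronal = ScanPlane(center=centroid, normal=cor_normal,
                        in_plane_axes=(cor_u, cor_v))
    return sagittal, coronal


def place_saturation_band(disc_mask: np.ndarray, coronal: ScanPlane,
                          spacing, origin=(0, 0, 0),
                          offset_distance: float = 10.0,
                          thickness: float = 30.0,
                          world_bounds=None) -> SaturationBand:
    """Saturation band anterior to the discs.

    The band's normal is the coronal normal (anterior direction); its
    near face sits ``offset_distance`` mm anterior of the most anterior
    disc point, so no disc voxel can fall inside the band.
    """
    if offset_distance <= 0 or thickness <= 0:
        raise ValueError("offset_distance and thickness must be > 0")
    pts = _mask_world_coords(disc_mask, spacing, origin)
    if pts.shape[0] == 0:
        raise DegenerateMaskError("no disc voxels")
    a = unit(coronal.normal)
    if a[1] < 0:
        a = -a
    proj = pts @ a
    s0 = float(proj.max())
    anterior_pt = pts[int(np.argmax(proj))]
    s_center = s0 + offset_distance + thickness / 2.0
    center = anterior_pt + (s_center - s0) * a
    if world_bounds is not None:
        lo, hi = (np.asarray(b, dtype=float) for b in world_bounds)
        s_max = float(np.sum(np.maximum(lo * a, hi * a)))
        if s0 + offset_distance + thickness > s_max:
            feasible = s_max - thickness - s0
            raise OutOfBoundsError(
                "saturation band exits the volume; maximum feasible "
                f"offset is {feasible:.1f} mm")
    # contract check: no disc voxel inside the band
    inside = (proj >= s0 + offset_distance) & (proj <= s0 + offset_distance + thickness)
    if np.any(inside):
        raise OutOfBoundsError("saturation band overlaps disc voxels")
    return SaturationBand(center=center, normal=a, thickness=thickness,
                          offset_distance=offset_distance)


def quality_factor(assignment: LabelAssignment,
                   template: DiscTemplate) -> float:
    """Reliability score in [0, 1].

    ``exp(-mean relative deviation of consecutive assigned-disc spacings
    from the template)`` scaled by the fraction of assigned discs:
    1 exactly when every spacing matches the template and nothing is
    missing, strictly decreasing as spacings deviate or discs go
    missing.
    """
    labels = template.labels
    present = [lv for lv in labels if assignment.mapping.get(lv) is not None]
    if len(present) < 2:
        raise InsufficientDiscsError("need >= 2 assigned discs")
    devs = []
    for a, b in zip(present[:-1], present[1:]):
        i, j = labels.index(a), labels.index(b)
        d = float(np.linalg.norm(assignment.mapping[a].position -
                                 assignment.mapping[b].position))
        t = template.distances[i, j]
        devs.append(abs(d - t) / t)
    frac = len(present) / len(labels)
    return float(frac * np.exp(-np.mean(devs)))


@dataclass
class DisplaySlice:
    """A plane resampled from an intensity volume."""

    image: np.ndarray
    coverage: float
    plane: ScanPlane

    def save_png(self, path) -> None:
        """8-bit grayscale export (windowed to the image's range)."""
        from PIL import Image
        img = self.image.astype(float)
        lo, hi = float(img.min()), float(img.max())
        scaled = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
        arr = np.round(255 * scaled).astype(np.uint8)
        Image.fromarray(arr.T[::-1]).save(str(path))


def select_display_slice(volume: ImageVolume, plane: ScanPlane,
                         spacing: Optional[float] = None) -> DisplaySlice:
    """Trilinear resampling of the volume onto the plane's in-plane grid
    at native spacing; out-of-volume pixels are 0 and the in-volume
    coverage fraction is reported."""
    if spacing is None:
        spacing = float(np.min(volume.spacing))
    u, v = plane.in_plane_axes
    eu, ev = plane.extent
    nu = max(int(round(eu / spacing)) + 1, 2)
    nv = max(int(round(ev / spacing)) + 1, 2)
    iu = (np.arange(nu) - (nu - 1) / 2.0) * spacing
    iv = (np.arange(nv) - (nv - 1) / 2.0) * spacing
    pts = (plane.center[None, None, :]
           + iu[:, None, None] * u[None, None, :]
           + iv[None, :, None] * v[None, None, :])
    idx = (pts - volume.origin) / volume.spacing
    shape = np.asarray(volume.shape)
    in_vol = np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
    if not np.any(in_vol):
        raise OutOfBoundsError("display plane lies outside the volume")
    img = ndimage.map_coordinates(volume.voxels.astype(float),
                                  idx.reshape(-1, 3).T, order=1,
                                  mode="constant", cval=0.0).reshape(nu, nv)
    img[~in_vol] = 0.0
    return DisplaySlice(image=img, coverage=float(in_vol.mean()), plane=plane)


def build_scan_plan(label_volume, assignment: LabelAssignment,
                    template: DiscTemplate,
                    sat_band_offset: float = 10.0,
                    sat_band_thickness: float = 30.0) -> ScanPlan:
    """Assemble the full scan plan from fused disc labels."""
    present = [lv for lv in template.labels
               if assignment.mapping.get(lv) is not None]
    centers = np.stack([assignment.mapping[lv].position for lv in present])
    sagittal, coronal = fit_long_axis_planes(centers)
    transverse: dict[str, ScanPlane] = {}
    for lv in present:
        name = f"disc_{lv}"
        if name not in label_volume.label_map:
            continue
        mask = label_volume.mask(name)
        try:
            axes = disc_principal_axes(mask, label_volume.spacing,
                                       label_volume.origin)
        except DegenerateMaskError:
            log.warning("build_scan_plan: degenerate disc mask for %s", lv)
            continue
        transverse[lv] = transverse_plane_for_disc(
            mask, axes, label_volume.spacing, label_volume.origin)
    all_discs = label_volume.mask_prefix("disc_")
    sat = None
    try:
        sat = place_saturation_band(
            all_discs, coronal, label_volume.spacing, label_volume.origin,
            offset_distance=sat_band_offset, thickness=sat_band_thickness,
            world_bounds=label_volume.world_bounds())
    except (DegenerateMaskError, OutOfBoundsError) as exc:
        log.warning("build_scan_plan: saturation band skipped (%s)", exc)
    qf = quality_factor(assignment, template)
    verts = tuple(sorted(
        n.split("_", 1)[1] for n in label_volume.label_map
        if n.startswith("vertebra_")))
    return ScanPlan(sagittal=sagittal, coronal=coronal, transverse=transverse,
                    sat_band=sat, quality_factor=qf,
                    disc_labels=tuple(present), vertebra_labels=verts)
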