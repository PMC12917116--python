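"""Parametric synthetic lumbar localizer phantom.

The phantom emulates the content of a low-resolution lumbar spine MRI
localizer: five lumbar vertebral bodies plus a sacral base, five
intervertebral discs tilted according to a lordosis model, the spinal
canal, spinous processes, bilateral psoas muscles, and optional planted
pathology (canal stenosis, lateral recess stenosis, disc herniation).
Every structure is an analytic solid, so ground-truth landmarks,
measurements, and diagnoses are exact by construction.

Geometry model
--------------
The lumbar curve is a circular arc in the sagittal (Y-Z) plane.  The
total lordosis angle ``theta`` is distributed uniformly over the disc
levels: disc ``i`` (head -> foot) has tilt ``phi_i = theta * (i - (n-1)/2) / n``
about the left-right axis, so adjacent disc normals differ by exactly
``theta / n`` degrees.  Disc centers are chained along chords at the
mid-angle between levels.  A rigid pose (rotation about the grid center
plus translation) emulates patient positioning differences.

Labels are rasterized with 3x per-axis sub-voxel supersampling and
majority vote, keeping rasterized areas within ~1-2% of their analytic
values at the default 1.5 mm grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InvalidRangeError, InvalidSpecError, OutOfBoundsError
from .geometry import rotation_xyz, unit
from .landmarks import (SIDES, HerniationGeometry, LevelLandmarks,
                        landmarks_from_dict, landmarks_to_dict)
from .volume import ImageVolume, LabelVolume

DISC_LABELS_5 = ("L1/2", "L2/3", "L3/4", "L4/5", "L5/S1")
VERTEBRA_LABELS_5 = ("L1", "L2", "L3", "L4", "L5")

# mean tissue intensities of the synthetic localizer (arbitrary units,
# loosely T2-like: CSF bright, disc bright, muscle dark)
INTENSITY_MEANS = {
    "background": 15.0,
    "vertebra": 90.0,
    "sacrum": 90.0,
    "disc": 140.0,
    "canal": 170.0,
    "spinous_process": 85.0,
    "psoas": 70.0,
    "herniation": 140.0,
}

# default stenosis thresholds used for the planted-diagnosis booleans;
# the morphometry module re-derives diagnoses from measurements.
_CANAL_THRESHOLD_MM = 10.0
_RECESS_HEIGHT_MM = 3.0
_RECESS_ANGLE_DEG = 30.0


def disc_labels(n: int) -> tuple[str, ...]:
    if n == 5:
        return DISC_LABELS_5
    return tuple(f"D{i + 1}/{i + 2}" for i in range(n))


def vertebra_labels(n: int) -> tuple[str, ...]:
    if n == 5:
        return VERTEBRA_LABELS_5
    return tuple(f"V{i + 1}" for i in range(n))


def _per_level(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise InvalidSpecError(f"{name}: expected scalar or length-{n} sequence")
    return arr


def _per_level_side(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full((n, 2), float(arr))
    elif arr.shape == (2,):
        arr = np.tile(arr, (n, 1))
    elif arr.shape == (n,):
        arr = np.stack([arr, arr], axis=1)
    if arr.shape != (n, 2):
        raise InvalidSpecError(f"{name}: expected scalar, (2,), ({n},) or ({n},2)")
    return arr


@dataclass
class PhantomSpec:
    """Full parametric description of one phantom.

    Per-level quantities accept scalars (broadcast), one value per disc
    level (head -> foot), or, for sided quantities, an ``(n, 2)`` array
    with columns (left, right).
    """

    grid_shape: tuple[int, int, int] = (88, 96, 160)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_discs: int = 5
    lordosis_angle: float = 40.0          # degrees, total arc
    disc_heights: object = 10.0           # mm
    disc_radii: object = (17.0, 25.0)     # mm (AP, LR) semi-axes per level
    vertebra_heights: object = 27.0       # mm
    canal_diameter: object = 14.0         # mm (AP), per level
    recess_height: object = 5.0           # mm, per level per side
    recess_angle: object = 40.0           # degrees, per level per side
    facet_angle: object = 40.0            # degrees, per level per side
    foramen_height: object = 18.0         # mm, per level per side
    psoas_semiaxes: dict = field(
        default_factory=lambda: {"left": (15.0, 10.0), "right": (15.0, 10.0)})
    herniation: dict = field(default_factory=dict)  # level -> {extent, zone}
    pose_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)    # degrees
    pose_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    noise_sd: float = 5.0
    seed: int = 0

    # normalized arrays, filled in __post_init__
    def __post_init__(self) -> None:
        n = int(self.n_discs)
        if n < 1:
            raise InvalidSpecError("n_discs must be >= 1")
        self.n_discs = n
        self.disc_heights = _per_level(self.disc_heights, n, "disc_heights")
        radii = np.asarray(self.disc_radii, dtype=float)
        if radii.shape == (2,):
            radii = np.tile(radii, (n, 1))
        if radii.shape != (n, 2):
            raise InvalidSpecError(f"disc_radii: expected (2,) or ({n},2)")
        self.disc_radii = radii
        self.vertebra_heights = _per_level(self.vertebra_heights, n,
                                           "vertebra_heights")
        self.canal_diameter = _per_level(self.canal_diameter, n, "canal_diameter")
        self.recess_height = _per_level_side(self.recess_height, n, "recess_height")
        self.recess_angle = _per_level_side(self.recess_angle, n, "recess_angle")
        self.facet_angle = _per_level_side(self.facet_angle, n, "facet_angle")
        self.foramen_height = _per_level_side(self.foramen_height, n,
                                              "foramen_height")
        self.validate()

    @property
    def labels(self) -> tuple[str, ...]:
        return disc_labels(self.n_discs)

    @property
    def vert_labels(self) -> tuple[str, ...]:
        return vertebra_labels(self.n_discs)

    def validate(self) -> None:
        for name in ("disc_heights", "vertebra_heights", "canal_diameter"):
            if np.any(getattr(self, name) <= 0):
                raise InvalidSpecError(f"{name} must be > 0")
        if np.any(np.asarray(self.disc_radii) <= 0):
            raise InvalidSpecError("disc_radii must be > 0")
        if np.any(self.recess_height <= 0):
            raise InvalidSpecError("recess_height must be > 0")
        if np.any(np.asarray(self.spacing) <= 0):
            raise InvalidSpecError("spacing must be > 0")
        if any(s < 8 for s in self.grid_shape):
            raise InvalidSpecError("grid_shape too small")
        for level, h in self.herniation.items():
            if level not in self.labels:
                raise InvalidSpecError(f"herniation level {level!r} unknown")
            if h.get("extent", 0.0) < 0:
                raise InvalidSpecError("herniation extent must be >= 0")
            if h.get("zone", "A") not in ("A", "B", "C"):
                raise InvalidSpecError("herniation zone must be A, B, or C")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, tuple):
                return list(v)
            return v
        return {k: conv(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for k in ("grid_shape", "spacing", "pose_rotation", "pose_translation"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic truth for one phantom: centers, normals, landmarks,
    measurement values, and planted diagnoses."""

    disc_labels: tuple[str, ...]
    disc_centers: dict[str, np.ndarray]
    disc_normals: dict[str, np.ndarray]
    landmarks: dict[str, LevelLandmarks]
    true_measurements: dict[str, dict[str, float]]
    planted_diagnoses: dict[str, dict[str, object]]
    patient_axes: np.ndarray  # columns = posed patient X, Y, Z axes

    def to_dict(self) -> dict:
        return {
            "disc_labels": list(self.disc_labels),
            "disc_centers": {k: v.tolist() for k, v in self.disc_centers.items()},
            "disc_normals": {k: v.tolist() for k, v in self.disc_normals.items()},
            "landmarks": {k: landmarks_to_dict(v) for k, v in self.landmarks.items()},
            "true_measurements": self.true_measurements,
            "planted_diagnoses": self.planted_diagnoses,
            "patient_axes": self.patient_axes.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            disc_labels=tuple(d["disc_labels"]),
            disc_centers={k: np.asarray(v) for k, v in d["disc_centers"].items()},
            disc_normals={k: np.asarray(v) for k, v in d["disc_normals"].items()},
            landmarks={k: landmarks_from_dict(v) for k, v in d["landmarks"].items()},
            true_measurements=d["true_measurements"],
            planted_diagnoses=d["planted_diagnoses"],
            patient_axes=np.asarray(d["patient_axes"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# analytic spine geometry (spine frame, before pose)

def _level_frames(spec: PhantomSpec):
    """Tilt angles, frames, and chained disc centers in the spine frame."""
    n = spec.n_discs
    theta = spec.lordosis_angle
    phis = np.array([theta * (i - (n - 1) / 2.0) / n for i in range(n)])
    rads = np.radians(phis)
    normals = np.stack([np.zeros(n), np.sin(rads), np.cos(rads)], axis=1)
    ys = np.stack([np.zeros(n), np.cos(rads), -np.sin(rads)], axis=1)
    centers = np.zeros((n, 3))
    for i in range(n - 1):
        s = spec.vertebra_heights[i + 1] + 0.5 * (
            spec.disc_heights[i] + spec.disc_heights[i + 1])
        mid = 0.5 * (rads[i] + rads[i + 1])
        centers[i + 1] = centers[i] - s * np.array(
            [0.0, math.sin(mid), math.cos(mid)])
    return phis, normals, ys, centers


def disc_center_geometry(spec: PhantomSpec):
    """Recentered disc centers and normals (spine frame, before pose).

    Used by the template builder so that the empirical inter-disc
    distance matrix can be derived from the same curvature model.
    """
    _, normals, _, centers = _level_frames(spec)
    centers = centers - centers.mean(axis=0)
    return centers, normals


class _Structure:
    """Analytic solid: an implicit membership test plus a loose
    spine-frame bounding box."""

    def __init__(self, name, fn, lo, hi):
        self.name = name
        self.fn = fn
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)


def _frame_halfwidth(m: np.ndarray, *, semis) -> np.ndarray:
    """World-axis half-extents of an oriented box with the given frame."""
    return np.abs(m).T @ np.asarray(semis, dtype=float)


def _cylinder(name, center, xhat, yhat, zhat, a, b, half_h):
    c = np.asarray(center, dtype=float)
    m = np.stack([xhat, yhat, zhat])

    def fn(p):
        q = (p - c) @ m.T
        return ((q[..., 0] / a) ** 2 + (q[..., 1] / b) ** 2 <= 1.0) & (
            np.abs(q[..., 2]) <= half_h)

    hw = _frame_halfwidth(m, semis=(a, b, half_h))
    return _Structure(name, fn, c - hw, c + hw)


def _box(name, center, xhat, yhat, zhat, half):
    c = np.asarray(center, dtype=float)
    m = np.stack([xhat, yhat, zhat])
    half = np.asarray(half, dtype=float)

    def fn(p):
        q = np.abs((p - c) @ m.T)
        return np.all(q <= half, axis=-1)

    hw = _frame_halfwidth(m, semis=half)
    return _Structure(name, fn, c - hw, c + hw)


def _posterior_bump(name, center, xhat, yhat, zhat, semis):
    """Herniated disc material: a posterior half elliptic cylinder.

    The cross-section is constant along the disc axis so the maximal
    axial cross-sectional area does not depend on where the voxel
    slices happen to fall.
    """
    c = np.asarray(center, dtype=float)
    m = np.stack([xhat, yhat, zhat])
    s = np.asarray(semis, dtype=float)

    def fn(p):
        q = (p - c) @ m.T
        inside = ((q[..., 0] / s[0]) ** 2 + (q[..., 1] / s[1]) ** 2 <= 1.0) & (
            np.abs(q[..., 2]) <= s[2])
        return inside & (q[..., 1] <= 0.0)  # posterior half only

    hw = _frame_halfwidth(m, semis=s)
    return _Structure(name, fn, c - hw, c + hw)


def _build_structures(spec: PhantomSpec, recenter: np.ndarray):
    """All analytic solids in the (recentered) spine frame, paint order."""
    n = spec.n_discs
    phis, normals, ys, centers = _level_frames(spec)
    centers = centers - recenter
    xhat = np.array([1.0, 0.0, 0.0])
    rads = np.radians(phis)
    structures: list[_Structure] = []

    z_top = centers[0][2] + spec.disc_heights[0] / 2 + spec.vertebra_heights[0]
    z_bot = centers[-1][2] - spec.disc_heights[-1] / 2 - 30.0
    z_mid = 0.5 * (z_top + z_bot)
    half_len = 0.5 * (z_top - z_bot)
    # psoas sits lateral to the vertebral bodies (vertebra lateral
    # extent is disc LR semi-axis + 2 mm; keep a clear gap)
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        ax, by = spec.psoas_semiaxes[side]
        structures.append(_cylinder(
            f"psoas_{side}", (sgn * 42.0, 5.0, z_mid),
            xhat, np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]),
            ax, by, half_len * 0.85))

    # sacral base below the last disc
    i = n - 1
    sac_c = centers[i] - (spec.disc_heights[i] / 2 + 15.0) * normals[i]
    structures.append(_cylinder(
        "sacrum", sac_c, xhat, ys[i], normals[i],
        spec.disc_radii[i, 1] + 2.0, spec.disc_radii[i, 0] + 2.0, 15.0))

    # vertebral bodies: V_0 sits above disc 0, V_j between discs j-1 and j
    vnames = spec.vert_labels
    for j in range(n):
        if j == 0:
            c = centers[0] + (spec.disc_heights[0] / 2 +
                              spec.vertebra_heights[0] / 2) * normals[0]
            rad = rads[0]
        else:
            c = 0.5 * (centers[j - 1] + centers[j])
            rad = 0.5 * (rads[j - 1] + rads[j])
        yv = np.array([0.0, math.cos(rad), -math.sin(rad)])
        nv = np.array([0.0, math.sin(rad), math.cos(rad)])
        structures.append(_cylinder(
            f"vertebra_{vnames[j]}", c, xhat, yv, nv,
            spec.disc_radii[j, 1] + 2.0, spec.disc_radii[j, 0] + 2.0,
            spec.vertebra_heights[j] / 2))

    mean_vert = float(np.mean(spec.vertebra_heights))
    for i in range(n):
        ap, lr = spec.disc_radii[i]
        cd = spec.canal_diameter[i]
        p_post = centers[i] - ap * ys[i]
        structures.append(_cylinder(
            f"__canal_{i}", p_post - (cd / 2) * ys[i], xhat, ys[i], normals[i],
            0.7 * cd, cd / 2, (mean_vert + spec.disc_heights[i]) / 2 + 1.0))
        p_spin = p_post - cd * ys[i]
        structures.append(_box(
            f"__spinous_{i}", p_spin - 7.5 * ys[i], xhat, ys[i], normals[i],
            (4.0, 7.5, 6.0)))

    for i in range(n):
        ap, lr = spec.disc_radii[i]
        structures.append(_cylinder(
            f"disc_{spec.labels[i]}", centers[i], xhat, ys[i], normals[i],
            lr, ap, spec.disc_heights[i] / 2))

    for level, h in spec.herniation.items():
        ext = float(h.get("extent", 0.0))
        if ext <= 0:
            continue
        i = spec.labels.index(level)
        ap, lr = spec.disc_radii[i]
        cd = spec.canal_diameter[i]
        x_if = 0.7 * cd + 3.0
        x_off = {"A": 0.0, "B": 0.75 * x_if, "C": 1.3 * x_if}[h.get("zone", "A")]
        y_ell = -ap * math.sqrt(max(1.0 - (x_off / lr) ** 2, 0.0))
        base = centers[i] + x_off * xhat + y_ell * ys[i]
        structures.append(_posterior_bump(
            f"herniation_{level}", base, xhat, ys[i], normals[i],
            (8.0, ext, 0.4 * spec.disc_heights[i])))
    return structures


def _canal_union_area(cd: float, ap: float, lr: float,
                      x_off: float, extent: float,
                      step: float = 0.05) -> float:
    """Area of (canal ellipse) union (herniation half-ellipse) on the
    mid-disc cross-section, by fine 2D quadrature of the continuous
    geometry (the bump's flat base pokes laterally past the curved
    canal boundary, so the union has no simple closed form)."""
    y_base = -ap * math.sqrt(max(1.0 - (x_off / lr) ** 2, 0.0))
    # canal center sits cd/2 posterior of the disc's posterior edge
    cy = -ap - cd / 2.0
    a_c, b_c = 0.7 * cd, cd / 2.0
    xs = np.arange(-max(a_c, abs(x_off) + 8.0) - 1.0,
                   max(a_c, abs(x_off) + 8.0) + 1.0, step) + step / 2.0
    ys = np.arange(cy - b_c - extent - 1.0, 0.0, step) + step / 2.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    in_canal = (gx / a_c) ** 2 + ((gy - cy) / b_c) ** 2 <= 1.0
    in_bump = (((gx - x_off) / 8.0) ** 2 +
               ((gy - y_base) / extent) ** 2 <= 1.0) & (gy <= y_base)
    return float(np.count_nonzero(in_canal | in_bump)) * step * step


def _landmarks_and_truth(spec: PhantomSpec, recenter, pose):
    """Analytic landmarks and true measurements; ``pose`` maps spine-frame
    points to world."""
    n = spec.n_discs
    phis, normals, ys, centers = _level_frames(spec)
    centers = centers - recenter
    xhat = np.array([1.0, 0.0, 0.0])
    zpat = np.array([0.0, 0.0, 1.0])

    pose_pt, pose_dir = pose
    landmarks: dict[str, LevelLandmarks] = {}
    meas: dict[str, dict[str, float]] = {}
    diags: dict[str, dict[str, object]] = {}
    d_centers: dict[str, np.ndarray] = {}
    d_normals: dict[str, np.ndarray] = {}

    psoas_area = {s: math.pi * spec.psoas_semiaxes[s][0] * spec.psoas_semiaxes[s][1]
                  for s in SIDES}

    for i, level in enumerate(spec.labels):
        ap, lr = spec.disc_radii[i]
        cd = spec.canal_diameter[i]
        h = spec.disc_heights[i]
        c, yv, nv = centers[i], ys[i], normals[i]
        p_post = c - ap * yv
        p_ant = c + ap * yv
        p_spin = p_post - cd * yv
        x_if = 0.7 * cd + 3.0
        if_mid = p_post - 0.6 * cd * yv
        if_line = (if_mid - x_if * xhat, if_mid + x_if * xhat)

        sap, rpd, rsb, rib, fsup, finf, fline = {}, {}, {}, {}, {}, {}, {}
        for side, sgn in (("left", -1.0), ("right", 1.0)):
            j = 0 if side == "left" else 1
            x_r = sgn * 0.6 * cd
            y_loc = -ap * math.sqrt(max(1.0 - (x_r / lr) ** 2, 0.0))
            p_r = c + x_r * xhat + y_loc * yv
            rpd[side] = p_r
            sap[side] = p_r - spec.recess_height[i, j] * yv
            a2 = math.radians(spec.recess_angle[i, j] / 2.0)
            lat = sgn * xhat
            rsb[side] = (p_r, p_r + 10.0 * (math.cos(a2) * lat + math.sin(a2) * nv))
            rib[side] = (p_r, p_r + 10.0 * (math.cos(a2) * lat - math.sin(a2) * nv))
            q0 = c + sgn * (lr + 4.0) * xhat
            fh = spec.foramen_height[i, j]
            fsup[side] = q0 + (fh / 2.0) * zpat
            finf[side] = q0 - (fh / 2.0) * zpat
            fa = math.radians(spec.facet_angle[i, j])
            p0 = if_mid + sgn * x_if * xhat
            fdir = -math.cos(fa) * yv + sgn * math.sin(fa) * xhat
            fline[side] = (p0, p0 + 12.0 * fdir)

        hern_geom = None
        hern_spec = spec.herniation.get(level)
        if hern_spec and hern_spec.get("extent", 0.0) > 0:
            ext = float(hern_spec["extent"])
            zone = hern_spec.get("zone", "A")
            x_off = {"A": 0.0, "B": 0.75 * x_if, "C": 1.3 * x_if}[zone]
            y_ell = -ap * math.sqrt(max(1.0 - (x_off / lr) ** 2, 0.0))
            base = c + x_off * xhat + y_ell * yv
            hern_geom = HerniationGeometry(pose_pt(base - ext * yv), pose_pt(base))

        lm = LevelLandmarks(
            level=level,
            disc_center=pose_pt(c),
            disc_normal=pose_dir(nv),
            posterior_disc_edge_mid=pose_pt(p_post),
            anterior_disc_mid=pose_pt(p_ant),
            spinous_process_mid=pose_pt(p_spin),
            disc_superior_edge_mid=pose_pt(c + (h / 2) * nv),
            disc_inferior_edge_mid=pose_pt(c - (h / 2) * nv),
            midline_direction=pose_dir(yv),
            vertical_direction=pose_dir(zpat),
            intra_facet_line=(pose_pt(if_line[0]), pose_pt(if_line[1])),
            sap_medial_edge={s: pose_pt(p) for s, p in sap.items()},
            recess_posterior_disc_point={s: pose_pt(p) for s, p in rpd.items()},
            recess_superior_border={s: (pose_pt(a), pose_pt(b))
                                    for s, (a, b) in rsb.items()},
            recess_inferior_border={s: (pose_pt(a), pose_pt(b))
                                    for s, (a, b) in rib.items()},
            foramen_superior={s: pose_pt(p) for s, p in fsup.items()},
            foramen_inferior={s: pose_pt(p) for s, p in finf.items()},
            facet_line={s: (pose_pt(a), pose_pt(b)) for s, (a, b) in fline.items()},
            herniation=hern_geom,
        )
        landmarks[level] = lm
        d_centers[level] = pose_pt(c)
        d_normals[level] = pose_dir(nv)

        m: dict[str, float] = {
            "disc_vertical_diameter": h * math.cos(math.radians(phis[i])),
            "canal_diameter": float(cd),
        }
        for side, j in (("left", 0), ("right", 1)):
            m[f"foramen_height_{side}"] = float(spec.foramen_height[i, j])
            m[f"facet_joint_angle_{side}"] = float(spec.facet_angle[i, j])
            m[f"lateral_recess_height_{side}"] = float(spec.recess_height[i, j])
            m[f"lateral_recess_angle_{side}"] = float(spec.recess_angle[i, j])
            m[f"psoas_csa_{side}"] = psoas_area[side]
        if hern_geom is not None:
            ext = float(hern_spec["extent"])
            zone = hern_spec.get("zone", "A")
            x_off = {"A": 0.0, "B": 0.75 * x_if, "C": 1.3 * x_if}[zone]
            hern_area = 0.5 * math.pi * 8.0 * ext
            m["herniation_ratio"] = hern_area / _canal_union_area(
                cd, ap, lr, x_off, ext)
            d_line = 0.6 * cd
            m["msu_grade"] = ("1" if ext < 0.5 * d_line
                              else "2" if ext <= d_line else "3")
            m["msu_zone"] = zone
        else:
            m["herniation_ratio"] = 0.0
            m["msu_grade"] = "none"
            m["msu_zone"] = None
        meas[level] = m

        diags[level] = {
            "canal_stenosis": bool(cd < _CANAL_THRESHOLD_MM),
            "recess_stenosis_left": bool(
                spec.recess_height[i, 0] < _RECESS_HEIGHT_MM
                or spec.recess_angle[i, 0] < _RECESS_ANGLE_DEG),
            "recess_stenosis_right": bool(
                spec.recess_height[i, 1] < _RECESS_HEIGHT_MM
                or spec.recess_angle[i, 1] < _RECESS_ANGLE_DEG),
            "herniation": bool(hern_geom is not None),
        }

    return d_centers, d_normals, landmarks, meas, diags


def _pose_maps(spec: PhantomSpec, grid_center: np.ndarray):
    rot = rotation_xyz(*spec.pose_rotation)
    t = np.asarray(spec.pose_translation, dtype=float)

    def pose_pt(p):
        return rot @ (np.asarray(p, dtype=float) - 0.0) + grid_center + t

    def pose_dir(d):
        return rot @ np.asarray(d, dtype=float)

    def unpose_pts(x):
        # world -> spine frame (array of points, shape (..., 3))
        return (x - grid_center - t) @ rot  # (R^T x) via right-multiplication

    return pose_pt, pose_dir, unpose_pts


def generate_phantom(spec: PhantomSpec):
    """Build one phantom: (LabelVolume, ImageVolume, GroundTruth).

    Deterministic given (spec, spec.seed).  Raises
    :class:`OutOfBoundsError` naming the first structure that does not
    fit in the grid after the pose.
    """
    spec.validate()
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = -(np.asarray(shape) - 1) * spacing / 2.0
    grid_center = np.zeros(3)

    # recenter the spine chain (Y/Z only; X stays symmetric)
    _, _, _, centers = _level_frames(spec)
    recenter = centers.mean(axis=0).copy()
    recenter[0] = 0.0

    structures = _build_structures(spec, recenter)
    pose_pt, pose_dir, unpose_pts = _pose_maps(spec, grid_center)

    labels = np.zeros(shape, dtype=np.int16)
    label_map: dict[str, int] = {}
    rot = rotation_xyz(*spec.pose_rotation)
    t = np.asarray(spec.pose_translation, dtype=float)

    coords_1d = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    # 3x3x3 sub-voxel sampling with majority vote: keeps rasterized
    # areas within ~1% of their analytic values without tie bias
    offs = (-1.0 / 3.0, 0.0, 1.0 / 3.0)
    sub_offsets = [np.array([ox, oy, oz])
                   for ox in offs for oy in offs for oz in offs]
    vote_needed = 14  # majority of 27

    code = 0
    for st in structures:
        code += 1
        name = st.name
        if name.startswith("__canal"):
            name = "canal"
        elif name.startswith("__spinous"):
            name = "spinous_process"
        if name in label_map:
            use = label_map[name]
            code -= 1
        else:
            label_map[name] = code
            use = code

        # world bbox of the posed structure
        corners = np.array([[st.lo[0] if i & 1 else st.hi[0],
                             st.lo[1] if i & 2 else st.hi[1],
                             st.lo[2] if i & 4 else st.hi[2]]
                            for i in range(8)])
        wc = corners @ rot.T + grid_center + t
        idx_lo = np.maximum(np.floor((wc.min(axis=0) - origin) / spacing) - 1,
                            0).astype(int)
        idx_hi = np.minimum(np.ceil((wc.max(axis=0) - origin) / spacing) + 2,
                            shape).astype(int)
        if np.any(idx_lo >= idx_hi):
            continue
        xs = coords_1d[0][idx_lo[0]:idx_hi[0]]
        ys_ = coords_1d[1][idx_lo[1]:idx_hi[1]]
        zs = coords_1d[2][idx_lo[2]:idx_hi[2]]
        gx, gy, gz = np.meshgrid(xs, ys_, zs, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        votes = np.zeros(pts.shape[:-1], dtype=np.int8)
        for off in sub_offsets:
            p = unpose_pts(pts + off * spacing)
            votes += st.fn(p)
        mask = votes >= vote_needed
        # clipping detection: a structure reaching the outermost voxel
        # layer of the grid has been cut off by it
        for a in range(3):
            if ((idx_lo[a] == 0 and np.any(np.take(mask, 0, axis=a))) or
                    (idx_hi[a] == shape[a] and
                     np.any(np.take(mask, -1, axis=a)))):
                raise OutOfBoundsError(
                    f"structure {name!r} exceeds the grid after pose")
        sub = labels[idx_lo[0]:idx_hi[0], idx_lo[1]:idx_hi[1],
                     idx_lo[2]:idx_hi[2]]
        sub[mask] = use

    label_vol = LabelVolume(labels, spacing, origin, label_map)

    d_centers, d_normals, lms, meas, diags = _landmarks_and_truth(
        spec, recenter, (pose_pt, pose_dir))
    truth = GroundTruth(
        disc_labels=spec.labels,
        disc_centers=d_centers,
        disc_normals=d_normals,
        landmarks=lms,
        true_measurements=meas,
        planted_diagnoses=diags,
        patient_axes=rot.copy(),
    )

    for level, lm in truth.landmarks.items():
        for p in lm.all_points():
            if not label_vol.contains_world(p):
                raise OutOfBoundsError(
                    f"landmarks of level {level} exceed the grid after pose")

    means = np.full(len(label_map) + 1, INTENSITY_MEANS["background"],
                    dtype=np.float32)
    for name, c in label_map.items():
        base = name.split("_")[0]
        key = {"psoas": "psoas", "vertebra": "vertebra", "disc": "disc",
               "herniation": "herniation"}.get(base, name)
        means[c] = INTENSITY_MEANS.get(key, INTENSITY_MEANS["background"])
    rng = np.random.default_rng(spec.seed)
    intensity = means[labels] + rng.normal(0.0, spec.noise_sd,
                                           size=shape).astype(np.float32)
    image_vol = ImageVolume(intensity.astype(np.float32), spacing, origin)
    return label_vol, image_vol, truth


# ---------------------------------------------------------------------------
# rigid pose resampling of an existing volume

def apply_pose(volume: LabelVolume, rotation, translation) -> LabelVolume:
    """Rigidly transform a label volume (rotation in degrees about the
    grid world center, then translation in mm), resampling labels with
    nearest-neighbor interpolation.

    Raises :class:`OutOfBoundsError` naming the first structure whose
    voxels would leave the grid.
    """
    from scipy import ndimage

    rot = rotation_xyz(*rotation)
    t = np.asarray(translation, dtype=float)
    ctr = volume.world_center()
    lo, hi = volume.world_bounds()
    lo = lo - volume.spacing / 2.0
    hi = hi + volume.spacing / 2.0

    for name in volume.label_map:
        idx = np.argwhere(volume.mask(name))
        if idx.size == 0:
            continue
        w = volume.index_to_world(idx)
        moved = (w - ctr) @ rot.T + ctr + t
        if np.any(moved < lo) or np.any(moved > hi):
            raise OutOfBoundsError(
                f"structure {name!r} leaves the grid under the requested pose")

    # output voxel -> source voxel: src = R^T (x - ctr - t) + ctr
    spacing = volume.spacing
    matrix = (rot.T * spacing[None, :]) / spacing[:, None]
    # solve offset so that src_idx = matrix @ out_idx + offset
    offset = (rot.T @ (volume.origin - ctr - t) + ctr - volume.origin) / spacing
    out = ndimage.affine_transform(
        volume.voxels, matrix, offset=offset, order=0, mode="constant",
        cval=0, output=volume.voxels.dtype, prefilter=False)
    return LabelVolume(out, volume.spacing.copy(), volume.origin.copy(),
                       dict(volume.label_map))


# ---------------------------------------------------------------------------
# cohorts

_PLANT_LEVEL_INDEX = 2  # mid-lumbar level (L3/4 in the 5-disc phantom)


def cohort_specs(n: int, base_spec: Optional[PhantomSpec] = None,
                 variation: Optional[dict] = None, seed: int = 0
                 ) -> list[PhantomSpec]:
    """Deterministic cohort of phantom specs.

    ``variation`` maps scalar spec fields to (lo, hi) ranges, sampled at
    stratified mid-quantiles (a single phantom gets exact midpoints) and
    permuted per field by the seeded generator.  The special key
    ``"prevalence"`` maps condition names (canal_stenosis,
    recess_stenosis, herniation) to exact planted proportions: with n
    phantoms and proportion p, exactly round(p*n) phantoms carry the
    condition, planted at the mid-lumbar level.
    """
    if n < 1:
        raise InvalidRangeError("cohort size must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    variation = dict(variation or {})
    prevalence = variation.pop("prevalence", {})
    rng = np.random.default_rng(seed)

    scalar_fields = {"lordosis_angle", "noise_sd", "canal_diameter",
                     "disc_heights", "vertebra_heights", "recess_height",
                     "recess_angle", "facet_angle", "foramen_height"}
    per_phantom: dict[str, np.ndarray] = {}
    for key, rng_pair in variation.items():
        if key == "translation":
            lo, hi = rng_pair
            if hi < lo:
                raise InvalidRangeError("translation: hi < lo")
            vals = np.stack([
                lo + (hi - lo) * (rng.permutation(n) + 0.5) / n
                for _ in range(3)], axis=1)
            per_phantom[key] = vals
            continue
        if key not in scalar_fields:
            raise InvalidRangeError(f"unknown variation field {key!r}")
        lo, hi = rng_pair
        if hi < lo:
            raise InvalidRangeError(f"{key}: hi < lo")
        per_phantom[key] = lo + (hi - lo) * (rng.permutation(n) + 0.5) / n

    plant: dict[str, np.ndarray] = {}
    for cond, p in prevalence.items():
        if cond not in ("canal_stenosis", "recess_stenosis", "herniation"):
            raise InvalidRangeError(f"unknown condition {cond!r}")
        if not 0.0 <= p <= 1.0:
            raise InvalidRangeError(f"{cond}: proportion must be in [0,1]")
        k = int(round(p * n))
        chosen = np.zeros(n, dtype=bool)
        chosen[rng.permutation(n)[:k]] = True
        plant[cond] = chosen
    hern_extents = 7.0 + 2.0 * rng.random(n)

    seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    specs = []
    li = min(_PLANT_LEVEL_INDEX, base.n_discs - 1)
    for i in range(n):
        kwargs: dict = {"seed": int(seeds[i])}
        for key, vals in per_phantom.items():
            if key == "translation":
                kwargs["pose_translation"] = tuple(vals[i])
            else:
                kwargs[key] = float(vals[i])
        try:
            sp = replace(base, **kwargs)
            if plant.get("canal_stenosis", np.zeros(n, bool))[i]:
                cd = sp.canal_diameter.copy()
                cd[li] = 8.0
                sp = replace(sp, canal_diameter=cd)
            if plant.get("recess_stenosis", np.zeros(n, bool))[i]:
                rh = sp.recess_height.copy()
                ra = sp.recess_angle.copy()
                rh[li, 0] = 2.2
                ra[li, 0] = 24.0
                sp = replace(sp, recess_height=rh, recess_angle=ra)
            if plant.get("herniation", np.zeros(n, bool))[i]:
                sp = replace(sp, herniation={
                    sp.labels[li]: {"extent": float(hern_extents[i]),
                                    "zone": "A"}})
        except InvalidSpecError as exc:
            raise InvalidRangeError(
                f"variation produced an invalid spec: {exc}")
        specs.append(sp)
    return specs


def phantom_cohort(n: int, base_spec: Optional[PhantomSpec] = None,
                   variation: Optional[dict] = None, seed: int = 0):
    """Materialized cohort: list of (LabelVolume, ImageVolume, GroundTruth)."""
    return [generate_phantom(sp)
            for sp in cohort_specs(n, base_spec, variation, seed)]
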