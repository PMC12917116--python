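"""Small geometric primitives shared across modules.

World frame is RAS+: +X right, +Y anterior, +Z superior (head).  Voxel
indices are 0-based and map to world coordinates as
``world = origin + index * spacing`` (no shear, axis-aligned grids).
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateDirectionError

Vec = np.ndarray


def unit(v: Vec) -> Vec:
    """Normalize ``v``; raise on (near-)zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateDirectionError("cannot normalize a zero-length vector")
    return v / n


def angle_between_lines(u: Vec, v: Vec) -> float:
    """Angle in degrees between two undirected lines, in [0, 90].

    Antiparallel vectors therefore give 0 (line convention).
    """
    u, v = unit(u), unit(v)
    c = abs(float(np.dot(u, v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_between_vectors(u: Vec, v: Vec) -> float:
    """Angle in degrees between two directed vectors, in [0, 180]."""
    u, v = unit(u), unit(v)
    c = float(np.dot(u, v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_about_axis(axis: Vec, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    a = unit(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def rotation_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation composed as Rz @ Ry @ Rx (angles in degrees)."""
    r = rotation_about_axis([1, 0, 0], rx)
    r = rotation_about_axis([0, 1, 0], ry) @ r
    return rotation_about_axis([0, 0, 1], rz) @ r


def complete_frame(normal: Vec, preferred: Vec | None = None) -> tuple[Vec, Vec]:
    """Two orthonormal in-plane axes (u, v) with u x v = normal.

    ``u`` is the projection of ``preferred`` (default: whichever world axis
    is least aligned with the normal) onto the plane.
    """
    n = unit(normal)
    if preferred is None:
        preferred = np.eye(3)[int(np.argmin(np.abs(n)))]
    p = np.asarray(preferred, dtype=float)
    u = p - np.dot(p, n) * n
    u = unit(u)
    v = np.cross(n, u)
    return u, v
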