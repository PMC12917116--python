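"""Voxel-based landmark extraction from labeled volumes.

Recovers the sagittal measurement landmarks (posterior/anterior disc
edge midpoints, disc superior/inferior edge midpoints, spinous process
tip) directly from the rasterized masks, independent of the analytic
ground truth.  Extraction takes extreme one-voxel slabs of the relevant
mask, so each point is accurate to about half a voxel for near-axial
discs; strongly tilted discs shift their world-axis extrema away from
the mid-plane, so extraction is intended for levels within ~10 degrees
of axial (the mid-lumbar levels in this phantom).
"""

from __future__ import annotations

import numpy as np

from .errors import MissingStructureError
from .volume import LabelVolume


def _world_points(vol: LabelVolume, name: str) -> np.ndarray:
    idx = np.argwhere(vol.mask(name))
    if idx.size == 0:
        raise MissingStructureError(f"{name!r} has no voxels")
    return vol.index_to_world(idx)


def _extreme_slab_centroid(pts: np.ndarray, axis: int, direction: int,
                           slab: float) -> np.ndarray:
    """Centroid of the voxels within ``slab`` of the extreme coordinate
    along ``axis`` (direction -1: minimum, +1: maximum)."""
    v = pts[:, axis]
    edge = v.max() if direction > 0 else v.min()
    sel = pts[np.abs(v - edge) <= slab]
    return sel.mean(axis=0)


def extract_disc_landmarks(vol: LabelVolume, level: str) -> dict:
    """Measurement landmarks of one disc level from the voxel masks.

    Returns posterior/anterior disc edge midpoints, superior/inferior
    disc edge midpoints (from the central column of the disc), the
    spinous process anterior tip at the disc's Z span, and the canal
    diameter derived from them.
    """
    disc = _world_points(vol, f"disc_{level}")
    slab = float(vol.spacing.max()) / 2.0 + 1e-6
    # majority-vote rasterization keeps only majority-covered voxels, so
    # extreme-slab centroids sit ~half a voxel inside the true surface;
    # shift each face outward by that amount
    half_y = float(vol.spacing[1]) / 2.0
    # near-midline voxels only: away from x=0 the elliptical boundary
    # curves anteriorly and would bias the face centroid
    mid_x = float(np.median(disc[:, 0]))
    central = disc[np.abs(disc[:, 0] - mid_x) <= 2.5]
    post = _extreme_slab_centroid(central, axis=1, direction=-1, slab=slab)
    post = post - np.array([0.0, half_y, 0.0])
    ant = _extreme_slab_centroid(central, axis=1, direction=+1, slab=slab)
    ant = ant + np.array([0.0, half_y, 0.0])

    center = disc.mean(axis=0)
    col = disc[np.linalg.norm(disc[:, :2] - center[:2], axis=1) <= 3.0]
    sup = _extreme_slab_centroid(col, axis=2, direction=+1, slab=slab)
    inf = _extreme_slab_centroid(col, axis=2, direction=-1, slab=slab)

    spin = _world_points(vol, "spinous_process")
    zc = center[2]
    near = spin[np.abs(spin[:, 2] - zc) <= 6.0]
    if near.shape[0] == 0:
        raise MissingStructureError(
            f"no spinous process voxels near level {level}")
    spin_tip = _extreme_slab_centroid(near, axis=1, direction=+1, slab=slab)
    spin_tip = spin_tip + np.array([0.0, half_y, 0.0])

    return {
        "posterior_disc_edge_mid": post,
        "anterior_disc_mid": ant,
        "disc_superior_edge_mid": sup,
        "disc_inferior_edge_mid": inf,
        "spinous_process_mid": spin_tip,
        "canal_diameter": float(np.linalg.norm(post - spin_tip)),
        # voxel-center extent underestimates the true span by one voxel
        # (half on each face); correct for it
        "disc_vertical_diameter": float(sup[2] - inf[2] + vol.spacing[2]),
    }
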