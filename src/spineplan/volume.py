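"""Voxel-volume containers and NIfTI-1 I/O.

Arrays are indexed ``[i, j, k]`` along world (X, Y, Z); the grid is
axis-aligned with ``world = origin + index * spacing`` so the NIfTI
affine is ``diag(spacing)`` plus the origin translation (RAS+).

Label volumes carry a ``label_map`` (structure name -> positive integer
code, background 0); the map is stored as a JSON side-car next to the
NIfTI file so label semantics survive a round trip.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError

log = logging.getLogger(__name__)


@dataclass
class Volume:
    """A 3D scalar grid with world geometry."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D array, got ndim={self.voxels.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pt: np.ndarray) -> np.ndarray:
        return (np.asarray(pt, dtype=float) - self.origin) / self.spacing

    def world_center(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.shape) - 1) / 2.0)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the outermost voxel centers."""
        return self.origin.copy(), self.index_to_world(np.asarray(self.shape) - 1)

    def contains_world(self, pt: np.ndarray) -> bool:
        lo, hi = self.world_bounds()
        pt = np.asarray(pt, dtype=float)
        return bool(np.all(pt >= lo - 1e-9) and np.all(pt <= hi + 1e-9))


@dataclass
class ImageVolume(Volume):
    """Floating-point intensity volume (localizer image)."""


@dataclass
class LabelVolume(Volume):
    """Integer-labeled volume; ``label_map`` maps structure names to codes."""

    label_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        codes = list(self.label_map.values())
        if any(c <= 0 for c in codes):
            raise FormatError("label codes must be positive (background is 0)")
        if len(set(codes)) != len(codes):
            raise FormatError("label codes must be unique")

    def mask(self, name: str) -> np.ndarray:
        if name not in self.label_map:
            raise FormatError(f"unknown label {name!r}")
        return self.voxels == self.label_map[name]

    def mask_prefix(self, prefix: str) -> np.ndarray:
        """Union mask of all labels whose name starts with ``prefix``."""
        out = np.zeros(self.shape, dtype=bool)
        for name, code in self.label_map.items():
            if name.startswith(prefix):
                out |= self.voxels == code
        return out

    def centroid_world(self, name: str) -> np.ndarray:
        idx = np.argwhere(self.mask(name))
        if idx.size == 0:
            raise FormatError(f"label {name!r} has no voxels")
        return self.index_to_world(idx.mean(axis=0))


def _nifti_bytes(img: nib.Nifti1Image) -> bytes:
    return img.to_bytes()


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; gz output uses mtime=0 so identical
    volumes serialize to identical bytes."""
    path = Path(path)
    data = vol.voxels
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    raw = _nifti_bytes(img)
    if path.name.endswith(".nii.gz"):
        buf = io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
            gz.write(raw)
        path.write_bytes(buf.getvalue())
    elif path.name.endswith(".nii"):
        path.write_bytes(raw)
    else:
        raise FormatError(f"unsupported volume extension in {path.name!r}")
    if isinstance(vol, LabelVolume):
        side = path.with_name(path.name.split(".nii")[0] + ".labels.json")
        side.write_text(json.dumps(vol.label_map, sort_keys=True, indent=2) + "\n")
    return path


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume, reorienting to RAS+ when necessary.

    Integer-typed data with a label side-car (or integer data generally)
    loads as a :class:`LabelVolume`; floating data as :class:`ImageVolume`.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise FormatError(f"cannot read NIfTI volume {path.name}: {exc}") from exc
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"{path.name}: missing or non-finite affine")
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0):
        raise FormatError(f"{path.name}: non-positive voxel spacing in affine")
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * np.max(spacing):
        log.warning("%s: oblique affine; grid treated as axis-aligned RAS", path.name)
    origin = affine[:3, 3]
    side = path.with_name(path.name.split(".nii")[0] + ".labels.json")
    if np.issubdtype(data.dtype, np.integer):
        label_map = json.loads(side.read_text()) if side.exists() else {}
        return LabelVolume(data.astype(np.int32), spacing, origin, label_map)
    return ImageVolume(data.astype(np.float32), spacing, origin)
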