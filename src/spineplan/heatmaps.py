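"""Gaussian heatmap targets, candidate extraction, and training metrics.

A disc-center localization network predicts one heatmap channel per
disc; the training target is a Gaussian bump with peak value 256 at the
keypoint.  This module provides the target generator, the local-maximum
candidate extractor used in postprocessing, and the scalar metrics used
for training and model selection: focal loss, heatmap mean squared
error, and the Dice coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import OutOfBoundsError, ShapeMismatchError
from .volume import Volume

log = logging.getLogger(__name__)

HEAT_PEAK = 256.0


@dataclass
class Heatmap:
    """Per-disc-channel heat volumes, values in [0, 256]."""

    channels: np.ndarray          # (C, nx, ny, nz)
    spacing: np.ndarray
    origin: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.channels.ndim != 4:
            raise ShapeMismatchError("heatmap channels must be a 4D array")
        if self.channels.shape[0] != len(self.channel_labels):
            raise ShapeMismatchError("one label per channel required")

    def channel(self, label: str) -> np.ndarray:
        return self.channels[self.channel_labels.index(label)]


@dataclass
class FocalLossSpec:
    """Focusing parameter and reduction for the focal loss."""

    gamma: float = 2.0
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


@dataclass
class Candidate:
    """A candidate disc center extracted from one heatmap channel."""

    position: np.ndarray   # world mm
    heat: float
    channel: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


def make_gaussian_heatmap(keypoints: dict[str, np.ndarray],
                          shape: tuple[int, int, int],
                          spacing,
                          sigma: float = 6.0,
                          origin=None) -> Heatmap:
    """Gaussian heat targets: ``256 * exp(-||x - k||^2 / (2 sigma^2))``.

    One channel per keypoint, ordered as the dict.  A keypoint centered
    on a voxel yields an exact peak of 256 at that voxel.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    spacing = np.asarray(spacing, dtype=float)
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)
    labels = tuple(keypoints)
    channels = np.zeros((len(labels),) + shape, dtype=float)
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    lo = origin - spacing / 2.0
    hi = origin + (np.asarray(shape) - 1) * spacing + spacing / 2.0
    for c, label in enumerate(labels):
        k = np.asarray(keypoints[label], dtype=float)
        if np.any(k < lo) or np.any(k > hi):
            raise OutOfBoundsError(f"keypoint {label!r} lies outside the grid")
        d2 = ((axes[0] - k[0]) ** 2)[:, None, None] + \
             ((axes[1] - k[1]) ** 2)[None, :, None] + \
             ((axes[2] - k[2]) ** 2)[None, None, :]
        channels[c] = HEAT_PEAK * np.exp(-d2 / (2.0 * sigma ** 2))
    return Heatmap(channels, spacing, origin, labels)


def heatmap_from_truth(truth, volume: Volume, sigma: float = 6.0) -> Heatmap:
    """Heatmap targets for a phantom's true disc centers on its grid."""
    return make_gaussian_heatmap(
        {lv: truth.disc_centers[lv] for lv in truth.disc_labels},
        volume.shape, volume.spacing, sigma=sigma, origin=volume.origin)


def _plateau_maxima(vol: np.ndarray, threshold: float):
    """Indices of strict 26-connected local maxima above ``threshold``.

    Plateaus (connected regions of equal value dominating all their
    neighbors) contribute one candidate each, at the lowest linear index.
    """
    if vol.size == 0:
        return []
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(vol, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    cand = (vol > threshold) & (vol >= neigh_max)
    if not np.any(cand):
        return []
    lab, n = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=int))
    out = []
    for comp in range(1, n + 1):
        idx = np.argwhere(lab == comp)
        vals = vol[tuple(idx.T)]
        # adjacent candidate voxels always share one value, so the
        # component is a plateau; keep its lowest linear index
        lin = np.ravel_multi_index(idx.T, vol.shape)
        out.append((tuple(idx[np.argmin(lin)]), float(vals.max())))
    return out


def extract_candidates(heatmap: Heatmap, threshold: float = 128.0
                       ) -> dict[str, list[Candidate]]:
    """Per-channel candidate disc centers: strict local maxima above the
    threshold, sorted by heat descending."""
    if not 0 < threshold < HEAT_PEAK:
        raise ValueError("threshold must lie in (0, 256)")
    result: dict[str, list[Candidate]] = {}
    for c, label in enumerate(heatmap.channel_labels):
        found = _plateau_maxima(heatmap.channels[c], threshold)
        cands = [Candidate(heatmap.origin + np.asarray(idx) * heatmap.spacing,
                           heat, label)
                 for idx, heat in found]
        cands.sort(key=lambda cd: (-cd.heat, tuple(cd.position)))
        result[label] = cands
    return result


_clamp_warned = False


def focal_loss(probabilities: np.ndarray, labels: np.ndarray,
               spec: FocalLossSpec | None = None,
               eps: float = 1e-7) -> float:
    """Binary focal loss ``-(1 - pt)^gamma * log(pt)``.

    ``pt`` is the predicted probability of the true class: ``p`` where
    the label is 1, ``1 - p`` otherwise.  With ``gamma = 0`` this is
    exactly the cross-entropy.  Probabilities at 0 or 1 are clamped to
    ``eps`` below/above (logged once).
    """
    global _clamp_warned
    if spec is None:
        spec = FocalLossSpec()
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ShapeMismatchError("probabilities and labels differ in shape")
    pt = np.where(y == 1, p, 1.0 - p)
    if np.any(pt < eps):
        if not _clamp_warned:
            log.warning("focal_loss: probabilities clamped to eps=%g", eps)
            _clamp_warned = True
        pt = np.clip(pt, eps, None)
    loss = -((1.0 - pt) ** spec.gamma) * np.log(pt)
    return float(loss.mean() if spec.reduction == "mean" else loss.sum())


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray,
                  reduction: str = "mean", eps: float = 1e-7) -> float:
    """Plain binary cross-entropy (the gamma=0 reference)."""
    return focal_loss(probabilities, labels,
                      FocalLossSpec(gamma=0.0, reduction=reduction), eps=eps)


def heatmap_mse(predicted, target) -> float:
    """Mean squared error over all voxels of all channels."""
    a = predicted.channels if isinstance(predicted, Heatmap) else np.asarray(predicted, dtype=float)
    b = target.channels if isinstance(target, Heatmap) else np.asarray(target, dtype=float)
    if a.shape != b.shape:
        raise ShapeMismatchError(
            f"heatmap shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)``; two empty masks give 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)
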