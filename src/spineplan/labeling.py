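"""Anatomical disc labeling from heatmap candidates.

Candidates from all channels are pooled and assigned to disc labels
(head -> foot) so that the assignment is injective, respects the
head-to-foot spatial order, and minimizes the template matching error

    sum over assigned pairs i<j of | D(c_i, c_j) - T(i, j) |

where D is the Euclidean distance between candidate positions and T the
empirical inter-disc distance template.  The most caudal high-heat
candidate anchors the L5/S1 reference disc.  Fused disc-level labels
are propagated to a generic disc segmentation, and vertebra names are
inferred from their flanking discs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import (InvalidSpecError, NoCandidatesError,
                     NoReferenceFoundError)
from .heatmaps import Candidate
from .volume import LabelVolume

log = logging.getLogger(__name__)

MISSING = None


@dataclass
class DiscTemplate:
    """Empirical inter-disc center distance matrix T(i, j) in mm."""

    labels: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.distances = np.asarray(self.distances, dtype=float)
        d = len(self.labels)
        if self.distances.shape != (d, d):
            raise InvalidSpecError("template distance matrix shape mismatch")
        if not np.allclose(self.distances, self.distances.T):
            raise InvalidSpecError("template distances must be symmetric")
        if np.any(np.diag(self.distances) != 0):
            raise InvalidSpecError("template diagonal must be zero")
        off = self.distances[~np.eye(d, dtype=bool)]
        if d > 1 and np.any(off <= 0):
            raise InvalidSpecError("off-diagonal template distances must be > 0")
        for i, j, k in itertools.permutations(range(d), 3):
            if self.distances[i, j] > self.distances[i, k] + self.distances[k, j] + 1e-9:
                raise InvalidSpecError("template violates the triangle inequality")

    @classmethod
    def from_positions(cls, labels, points) -> "DiscTemplate":
        pts = np.asarray(points, dtype=float)
        diff = pts[:, None, :] - pts[None, :, :]
        return cls(tuple(labels), np.linalg.norm(diff, axis=-1))

    @classmethod
    def default(cls, n_discs: int = 5, adjacent_spacing: float = 35.0,
                lordosis_angle: float = 40.0) -> "DiscTemplate":
        """Template from the circular-arc curvature model: adjacent discs
        ``adjacent_spacing`` mm apart along the arc, tilts spanning
        ``lordosis_angle`` degrees."""
        from .phantom import PhantomSpec, disc_center_geometry, disc_labels
        spec = PhantomSpec(
            n_discs=n_discs, lordosis_angle=lordosis_angle,
            disc_heights=10.0, vertebra_heights=adjacent_spacing - 10.0)
        centers, _ = disc_center_geometry(spec)
        return cls.from_positions(disc_labels(n_discs), centers)

    @classmethod
    def from_spec(cls, spec) -> "DiscTemplate":
        from .phantom import disc_center_geometry
        centers, _ = disc_center_geometry(spec)
        return cls.from_positions(spec.labels, centers)

    def to_dict(self) -> dict:
        return {"labels": list(self.labels),
                "distances": self.distances.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscTemplate":
        return cls(tuple(d["labels"]), np.asarray(d["distances"]))


@dataclass
class LabelAssignment:
    """Disc label -> candidate mapping with its Eq.-style matching error."""

    mapping: dict[str, Optional[Candidate]]
    matching_error: float
    reference: Optional[Candidate] = None

    @property
    def points(self) -> dict[str, np.ndarray]:
        return {lv: c.position for lv, c in self.mapping.items()
                if c is not None}

    def n_assigned(self) -> int:
        return sum(c is not None for c in self.mapping.values())


def find_reference_disc(candidates: dict[str, list[Candidate]],
                        threshold: float = 0.0,
                        z_tie_tolerance: float = 0.75) -> Candidate:
    """The L5/S1 anchor: most caudal (minimum Z) candidate with heat >=
    threshold; Z ties within ``z_tie_tolerance`` mm break toward higher
    heat."""
    pool = [c for lst in candidates.values() for c in lst
            if c.heat >= threshold]
    if not pool:
        raise NoReferenceFoundError(
            f"no candidate with heat >= {threshold}")
    zmin = min(c.position[2] for c in pool)
    tied = [c for c in pool if c.position[2] <= zmin + z_tie_tolerance]
    tied.sort(key=lambda c: (-c.heat, c.position[2]))
    return tied[0]


def _pool_candidates(candidates: dict[str, list[Candidate]]):
    pool = [c for lst in candidates.values() for c in lst]
    # head -> foot: descending Z; deterministic tie-break
    pool.sort(key=lambda c: (-c.position[2], -c.heat))
    return pool


def _pair_cost(chosen: list[tuple[int, Candidate]],
               new: tuple[int, Candidate],
               template: DiscTemplate) -> float:
    li, ci = new
    cost = 0.0
    for lj, cj in chosen:
        d = float(np.linalg.norm(ci.position - cj.position))
        cost += abs(d - template.distances[li, lj])
    return cost


def match_template(candidates: dict[str, list[Candidate]],
                   template: DiscTemplate,
                   anchor: Optional[Candidate] = None) -> LabelAssignment:
    """Globally optimal order-preserving assignment of pooled candidates
    to disc labels.

    Maximizes the number of assigned labels first (missing channels stay
    MISSING), then minimizes the matching error, by depth-first
    branch-and-bound over the Z-sorted candidate pool.  ``anchor``
    constrains the most caudal label to a specific candidate.
    """
    pool = _pool_candidates(candidates)
    if not pool:
        raise NoCandidatesError("no candidates in any channel")
    d = len(template.labels)
    k = min(d, len(pool))

    anchor_pool_idx = None
    if anchor is not None:
        for idx, c in enumerate(pool):
            if c is anchor or (np.array_equal(c.position, anchor.position)
                               and c.heat == anchor.heat):
                anchor_pool_idx = idx
                break
        if anchor_pool_idx is None:
            raise NoCandidatesError("anchor candidate not in the pool")

    best: dict = {"cost": np.inf, "assign": None}

    def dfs(label_idx: int, pool_idx: int, chosen: list, remaining: int,
            cost: float) -> None:
        if cost >= best["cost"]:
            return
        if remaining == 0:
            best["cost"] = cost
            best["assign"] = list(chosen)
            return
        labels_left = d - label_idx
        pool_left = len(pool) - pool_idx
        if labels_left < remaining or pool_left < remaining:
            return
        # try assigning each eligible candidate to this label
        for pi in range(pool_idx, len(pool)):
            if anchor_pool_idx is not None:
                # the anchor is reserved for the most caudal label
                if label_idx == d - 1 and pi != anchor_pool_idx:
                    continue
                if label_idx != d - 1 and pi == anchor_pool_idx:
                    continue
            c = pool[pi]
            add = _pair_cost(chosen, (label_idx, c), template)
            chosen.append((label_idx, c))
            dfs(label_idx + 1, pi + 1, chosen, remaining - 1, cost + add)
            chosen.pop()
        # or leave this label MISSING (only if enough labels remain)
        if labels_left - 1 >= remaining:
            dfs(label_idx + 1, pool_idx, chosen, remaining, cost)

    # the anchor, when given, must occupy the last label; ensure the DFS
    # can reach it by reserving it
    dfs(0, 0, [], k, 0.0)
    if best["assign"] is None:
        raise NoCandidatesError("no feasible assignment")
    mapping: dict[str, Optional[Candidate]] = {lv: MISSING
                                               for lv in template.labels}
    for li, c in best["assign"]:
        mapping[template.labels[li]] = c
    return LabelAssignment(mapping=mapping,
                           matching_error=float(best["cost"]),
                           reference=anchor)


def label_discs(candidates: dict[str, list[Candidate]],
                template: DiscTemplate,
                reference_threshold: float = 0.0) -> LabelAssignment:
    """Full labeling step: anchor L5/S1 at the most caudal candidate,
    then template-match the rest."""
    ref = find_reference_disc(candidates, threshold=reference_threshold)
    out = match_template(candidates, template, anchor=ref)
    out.reference = ref
    return out


def fuse_labels(disc_segmentation: LabelVolume,
                assignment: LabelAssignment,
                gate_mm: float = 15.0,
                disc_class: str = "disc",
                vertebra_class: str = "vertebra") -> LabelVolume:
    """Propagate disc labels to a generic segmentation.

    Each 26-connected component of the generic disc class takes the
    label of the assigned candidate nearest its centroid (within
    ``gate_mm``); unmatched components stay unlabeled.  When two
    components claim one label the nearer keeps it.  Vertebra components
    (when a generic vertebra class exists) are named from their flanking
    discs.
    """
    if disc_class not in disc_segmentation.label_map:
        raise InvalidSpecError(
            f"segmentation lacks a generic {disc_class!r} class")
    struct = np.ones((3, 3, 3), dtype=int)
    comp, n = ndimage.label(disc_segmentation.mask(disc_class), structure=struct)
    if n == 0:
        raise InvalidSpecError("disc class has no connected components")

    cand_pts = [(lv, c.position) for lv, c in assignment.mapping.items()
                if c is not None]
    claims: dict[str, tuple[int, float]] = {}
    centroids = ndimage.center_of_mass(np.ones_like(comp), comp,
                                       range(1, n + 1))
    centroids = [disc_segmentation.index_to_world(c) for c in centroids]
    for ci, cen in enumerate(centroids, start=1):
        dists = [(float(np.linalg.norm(cen - p)), lv) for lv, p in cand_pts]
        if not dists:
            continue
        dmin, lv = min(dists)
        if dmin > gate_mm:
            continue
        if lv in claims and claims[lv][1] <= dmin:
            log.warning("fuse_labels: component %d lost label %s to a "
                        "nearer component", ci, lv)
            continue
        if lv in claims:
            log.warning("fuse_labels: label %s reassigned to nearer "
                        "component %d", lv, ci)
        claims[lv] = (ci, dmin)

    out = disc_segmentation.voxels.copy()
    label_map = dict(disc_segmentation.label_map)
    next_code = max(label_map.values(), default=0) + 1
    comp_to_label: dict[int, str] = {ci: lv for lv, (ci, _) in claims.items()}
    disc_centroid_z: dict[str, float] = {}
    for ci, lv in comp_to_label.items():
        name = f"disc_{lv}"
        label_map[name] = next_code
        out[comp == ci] = next_code
        next_code += 1
        disc_centroid_z[lv] = float(centroids[ci - 1][2])

    if vertebra_class in disc_segmentation.label_map and disc_centroid_z:
        vcomp, vn = ndimage.label(disc_segmentation.mask(vertebra_class),
                                  structure=struct)
        vcents = ndimage.center_of_mass(np.ones_like(vcomp), vcomp,
                                        range(1, vn + 1))
        vcents = [disc_segmentation.index_to_world(c) for c in vcents]
        by_z = sorted(disc_centroid_z.items(), key=lambda kv: -kv[1])
        for vi, cen in enumerate(vcents, start=1):
            z = float(cen[2])
            above = [lv for lv, dz in by_z if dz > z]
            below = [lv for lv, dz in by_z if dz <= z]
            if above:
                name = _vertebra_below_disc(above[-1])
            elif below:
                name = _vertebra_above_disc(below[0])
            else:
                continue
            key = f"vertebra_{name}"
            if key not in label_map:
                label_map[key] = next_code
                next_code += 1
            out[vcomp == vi] = label_map[key]

    return LabelVolume(out, disc_segmentation.spacing.copy(),
                       disc_segmentation.origin.copy(), label_map)


def _vertebra_below_disc(disc_label: str) -> str:
    """Name of the vertebra immediately caudal to a disc (L4/5 -> L5)."""
    lower = disc_label.split("/")[1]
    if lower.isdigit():
        return disc_label.split("/")[0][0] + lower
    return lower


def _vertebra_above_disc(disc_label: str) -> str:
    """Name of the vertebra immediately cranial to a disc (L4/5 -> L4)."""
    return disc_label.split("/")[0]


def identification_rate(predicted: dict[str, np.ndarray],
                        truth: dict[str, np.ndarray],
                        tolerance: float = 6.0) -> float:
    """Fraction of discs correctly identified.

    A disc counts as identified iff a prediction exists for its label,
    the truth centroid closest to that prediction carries the same
    label, and every per-axis localization error is strictly below the
    tolerance (default 6 mm).
    """
    if not truth:
        raise InvalidSpecError("truth disc set is empty")
    n_ok = 0
    t_labels = list(truth)
    t_pts = np.stack([np.asarray(truth[lv], dtype=float) for lv in t_labels])
    for lv in t_labels:
        if lv not in predicted or predicted[lv] is None:
            continue
        p = np.asarray(predicted[lv], dtype=float)
        nearest = t_labels[int(np.argmin(np.linalg.norm(t_pts - p, axis=1)))]
        if nearest != lv:
            continue
        if np.all(np.abs(p - truth[lv]) < tolerance):
            n_ok += 1
    return n_ok / len(t_labels)
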