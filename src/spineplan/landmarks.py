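"""Per-level anatomical landmark containers.

All points are world coordinates in mm (RAS+).  Sides are "left"
(world -X) and "right" (+X).  The landmark set mirrors what a reader
marks on sagittal/axial localizer images: disc edge midpoints, the
spinous process tip, superior articular process (SAP) medial edges,
foraminal borders, facet joint lines, lateral-recess borders, and the
intra-facet reference line used by the MSU herniation grading scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SIDES = ("left", "right")

PointPair = tuple[np.ndarray, np.ndarray]


@dataclass
class HerniationGeometry:
    """Axial-plane geometry of one herniation.

    ``base`` is the posterior disc margin point at the apex's
    mediolateral position; ``apex`` is the most posterior point of the
    herniated material.  ``extent`` is their separation in mm.
    """

    apex: np.ndarray
    base: np.ndarray

    @property
    def extent(self) -> float:
        return float(np.linalg.norm(np.asarray(self.apex) - np.asarray(self.base)))


@dataclass
class LevelLandmarks:
    """Named landmarks for one disc level."""

    level: str
    disc_center: np.ndarray
    disc_normal: np.ndarray
    posterior_disc_edge_mid: np.ndarray
    anterior_disc_mid: np.ndarray
    spinous_process_mid: np.ndarray
    disc_superior_edge_mid: np.ndarray
    disc_inferior_edge_mid: np.ndarray
    midline_direction: np.ndarray
    vertical_direction: np.ndarray
    intra_facet_line: PointPair
    sap_medial_edge: dict[str, np.ndarray] = field(default_factory=dict)
    recess_posterior_disc_point: dict[str, np.ndarray] = field(default_factory=dict)
    recess_superior_border: dict[str, PointPair] = field(default_factory=dict)
    recess_inferior_border: dict[str, PointPair] = field(default_factory=dict)
    foramen_superior: dict[str, np.ndarray] = field(default_factory=dict)
    foramen_inferior: dict[str, np.ndarray] = field(default_factory=dict)
    facet_line: dict[str, PointPair] = field(default_factory=dict)
    herniation: Optional[HerniationGeometry] = None

    def all_points(self) -> list[np.ndarray]:
        pts = [
            self.disc_center,
            self.posterior_disc_edge_mid,
            self.anterior_disc_mid,
            self.spinous_process_mid,
            self.disc_superior_edge_mid,
            self.disc_inferior_edge_mid,
            *self.intra_facet_line,
        ]
        for d in (self.sap_medial_edge, self.recess_posterior_disc_point,
                  self.foramen_superior, self.foramen_inferior):
            pts.extend(d.values())
        for d in (self.facet_line, self.recess_superior_border,
                  self.recess_inferior_border):
            for pair in d.values():
                pts.extend(pair)
        if self.herniation is not None:
            pts.extend([self.herniation.apex, self.herniation.base])
        return pts


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return [float(x) for x in obj]
    if isinstance(obj, tuple):
        return [_jsonify(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    return obj


def landmarks_to_dict(lm: LevelLandmarks) -> dict:
    out = {
        "level": lm.level,
        "disc_center": _jsonify(lm.disc_center),
        "disc_normal": _jsonify(lm.disc_normal),
        "posterior_disc_edge_mid": _jsonify(lm.posterior_disc_edge_mid),
        "anterior_disc_mid": _jsonify(lm.anterior_disc_mid),
        "spinous_process_mid": _jsonify(lm.spinous_process_mid),
        "disc_superior_edge_mid": _jsonify(lm.disc_superior_edge_mid),
        "disc_inferior_edge_mid": _jsonify(lm.disc_inferior_edge_mid),
        "midline_direction": _jsonify(lm.midline_direction),
        "vertical_direction": _jsonify(lm.vertical_direction),
        "intra_facet_line": _jsonify(lm.intra_facet_line),
        "sap_medial_edge": _jsonify(lm.sap_medial_edge),
        "recess_posterior_disc_point": _jsonify(lm.recess_posterior_disc_point),
        "recess_superior_border": _jsonify(lm.recess_superior_border),
        "recess_inferior_border": _jsonify(lm.recess_inferior_border),
        "foramen_superior": _jsonify(lm.foramen_superior),
        "foramen_inferior": _jsonify(lm.foramen_inferior),
        "facet_line": _jsonify(lm.facet_line),
    }
    if lm.herniation is not None:
        out["herniation"] = {
            "apex": _jsonify(lm.herniation.apex),
            "base": _jsonify(lm.herniation.base),
        }
    return out


def _arr(x):
    return np.asarray(x, dtype=float)


def _pair(x) -> PointPair:
    return (_arr(x[0]), _arr(x[1]))


def landmarks_from_dict(d: dict) -> LevelLandmarks:
    hern = None
    if "herniation" in d:
        hern = HerniationGeometry(_arr(d["herniation"]["apex"]),
                                  _arr(d["herniation"]["base"]))
    return LevelLandmarks(
        level=d["level"],
        disc_center=_arr(d["disc_center"]),
        disc_normal=_arr(d["disc_normal"]),
        posterior_disc_edge_mid=_arr(d["posterior_disc_edge_mid"]),
        anterior_disc_mid=_arr(d["anterior_disc_mid"]),
        spinous_process_mid=_arr(d["spinous_process_mid"]),
        disc_superior_edge_mid=_arr(d["disc_superior_edge_mid"]),
        disc_inferior_edge_mid=_arr(d["disc_inferior_edge_mid"]),
        midline_direction=_arr(d["midline_direction"]),
        vertical_direction=_arr(d["vertical_direction"]),
        intra_facet_line=_pair(d["intra_facet_line"]),
        sap_medial_edge={s: _arr(v) for s, v in d["sap_medial_edge"].items()},
        recess_posterior_disc_point={
            s: _arr(v) for s, v in d["recess_posterior_disc_point"].items()},
        recess_superior_border={
            s: _pair(v) for s, v in d["recess_superior_border"].items()},
        recess_inferior_border={
            s: _pair(v) for s, v in d["recess_inferior_border"].items()},
        foramen_superior={s: _arr(v) for s, v in d["foramen_superior"].items()},
        foramen_inferior={s: _arr(v) for s, v in d["foramen_inferior"].items()},
        facet_line={s: _pair(v) for s, v in d["facet_line"].items()},
        herniation=hern,
    )
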