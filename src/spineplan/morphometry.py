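"""Quantitative lumbar measurements and stenosis/herniation rules.

Measurements operate on per-level landmark sets (analytic ground truth
or extracted from a labeled volume), decoupling the geometry from
segmentation quality.  "Vertical" distances are projections onto the
patient's head-foot axis (pose-corrected), matching how the quantities
are read on sagittal images.

Diagnostic thresholds (strict inequalities, configurable):

* spinal canal stenosis: canal diameter < 10 mm;
* lateral recess stenosis: recess height < 3 mm OR recess angle < 30
  degrees (the angle comparison direction is switchable, since the
  opposite convention also circulates);
* disc herniation: MSU grade >= 1.

The MSU scheme grades herniations 1/2/3 by how far the apex reaches
toward (and beyond) the intra-facet line, and zones them A (central),
B (lateral), C (foraminal) by the apex's mediolateral position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (DegenerateCanalError, DegenerateDirectionError,
                     DegenerateLandmarkError, EmptyCohortError,
                     MissingLandmarkError, MissingStructureError)
from .geometry import angle_between_lines, unit
from .landmarks import SIDES, HerniationGeometry, LevelLandmarks
from .volume import LabelVolume


@dataclass
class Thresholds:
    """Diagnostic decision thresholds."""

    canal_mm: float = 10.0
    recess_height_mm: float = 3.0
    recess_angle_deg: float = 30.0
    angle_direction: str = "less"   # stenosis when angle < threshold

    def __post_init__(self) -> None:
        if self.angle_direction not in ("less", "greater"):
            raise ValueError("angle_direction must be 'less' or 'greater'")

    def to_dict(self) -> dict:
        return {"canal_mm": self.canal_mm,
                "recess_height_mm": self.recess_height_mm,
                "recess_angle_deg": self.recess_angle_deg,
                "angle_direction": self.angle_direction}


@dataclass
class MorphometryReport:
    """Per-level measurements, diagnoses, and the thresholds used."""

    measurements: dict[str, dict[str, object]]
    diagnoses: dict[str, dict[str, object]] = field(default_factory=dict)
    thresholds: Optional[Thresholds] = None

    def to_dict(self) -> dict:
        return {
            "measurements": self.measurements,
            "diagnoses": self.diagnoses,
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
        }


# ---------------------------------------------------------------------------
# individual measurements

def measure_offset_angle(standard_line, actual_line) -> float:
    """Angle in [0, 90] degrees between the standard and the actual
    positioning line (undirected)."""
    return angle_between_lines(standard_line, actual_line)


def _vertical_distance(p_sup, p_inf, vertical) -> float:
    v = unit(vertical)
    return abs(float(np.dot(np.asarray(p_sup, dtype=float)
                            - np.asarray(p_inf, dtype=float), v)))


def measure_disc_vertical_diameter(lm: LevelLandmarks) -> float:
    """Head-foot projection of the superior-to-inferior disc edge span."""
    if lm.disc_superior_edge_mid is None or lm.disc_inferior_edge_mid is None:
        raise MissingLandmarkError(f"{lm.level}: disc edge midpoints missing")
    return _vertical_distance(lm.disc_superior_edge_mid,
                              lm.disc_inferior_edge_mid,
                              lm.vertical_direction)


def measure_foramen_height(lm: LevelLandmarks, side: str) -> float:
    """Head-foot distance between foraminal superior/inferior borders."""
    if side not in lm.foramen_superior or side not in lm.foramen_inferior:
        raise MissingLandmarkError(f"{lm.level}: foramen borders ({side}) missing")
    return _vertical_distance(lm.foramen_superior[side],
                              lm.foramen_inferior[side],
                              lm.vertical_direction)


def measure_psoas_csa(labels: LabelVolume, vertebra: str, side: str) -> float:
    """Psoas cross-sectional area (mm^2) on the axial slice through the
    named vertebra's mid-level."""
    vkey = f"vertebra_{vertebra}" if f"vertebra_{vertebra}" in labels.label_map \
        else vertebra
    if vkey not in labels.label_map:
        raise MissingStructureError(f"vertebra {vertebra!r} not in volume")
    pkey = f"psoas_{side}"
    if pkey not in labels.label_map:
        raise MissingStructureError(f"{pkey} not in volume")
    vidx = np.argwhere(labels.mask(vkey))
    if vidx.size == 0:
        raise MissingStructureError(f"vertebra {vertebra!r} has no voxels")
    k = int(round(vidx[:, 2].mean()))
    slab = labels.mask(pkey)[:, :, k]
    count = int(slab.sum())
    if count == 0:
        raise MissingStructureError(
            f"{pkey} has no voxels on the mid-{vertebra} slice")
    return count * float(labels.spacing[0] * labels.spacing[1])


def measure_facet_joint_angle(lm: LevelLandmarks, side: str) -> float:
    """Angle between the side's facet joint line and the midline."""
    if side not in lm.facet_line:
        raise MissingLandmarkError(f"{lm.level}: facet line ({side}) missing")
    p1, p2 = lm.facet_line[side]
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateDirectionError(f"{lm.level}: facet line degenerate")
    return angle_between_lines(d, lm.midline_direction)


def measure_canal_diameter(lm: LevelLandmarks) -> float:
    """Distance from the posterior disc edge midpoint to the spinous
    process midpoint at mid-disc level."""
    if lm.posterior_disc_edge_mid is None or lm.spinous_process_mid is None:
        raise MissingLandmarkError(f"{lm.level}: canal landmarks missing")
    return float(np.linalg.norm(np.asarray(lm.posterior_disc_edge_mid)
                                - np.asarray(lm.spinous_process_mid)))


def measure_lateral_recess(lm: LevelLandmarks, side: str
                           ) -> tuple[float, float]:
    """(height mm, angle degrees) of one lateral recess.

    Height: distance from the SAP medial edge to the posterior disc
    edge at the recess.  Angle: between lines parallel to the recess's
    superior and inferior borders.
    """
    for d in (lm.sap_medial_edge, lm.recess_posterior_disc_point,
              lm.recess_superior_border, lm.recess_inferior_border):
        if side not in d:
            raise MissingLandmarkError(
                f"{lm.level}: recess landmarks ({side}) missing")
    height = float(np.linalg.norm(
        np.asarray(lm.sap_medial_edge[side])
        - np.asarray(lm.recess_posterior_disc_point[side])))
    s1, s2 = lm.recess_superior_border[side]
    i1, i2 = lm.recess_inferior_border[side]
    angle = angle_between_lines(np.asarray(s2) - np.asarray(s1),
                                np.asarray(i2) - np.asarray(i1))
    return height, angle


def herniation_ratio(herniation_mask: np.ndarray, canal_mask: np.ndarray,
                     pixel_area: float = 1.0) -> float:
    """Max over axial slices of herniated-disc area / canal area on the
    same slice.  An empty herniation mask gives 0."""
    h = np.asarray(herniation_mask).astype(bool)
    c = np.asarray(canal_mask).astype(bool)
    if h.shape != c.shape:
        raise DegenerateCanalError("mask shapes differ")
    h_areas = h.sum(axis=(0, 1)).astype(float)
    c_areas = c.sum(axis=(0, 1)).astype(float)
    slices = np.where(h_areas > 0)[0]
    if slices.size == 0:
        return 0.0
    if np.any(c_areas[slices] == 0):
        raise DegenerateCanalError(
            "zero canal area on a slice with herniated disc")
    return float(np.max(h_areas[slices] / c_areas[slices]))


def msu_grade_zone(extent: float, margin_to_line: float,
                   lateral_fraction: float) -> tuple[str, Optional[str]]:
    """Pure MSU rule arithmetic.

    Grade: 1 when the apex reaches < 50% of the posterior-margin to
    intra-facet-line distance, 2 from 50% up to the line, 3 beyond it.
    Zone from the apex's mediolateral position as a fraction of the
    intra-facet half-length: A (central) <= 0.5, B (lateral) <= 1,
    C (foraminal) beyond.
    """
    if extent <= 0:
        return "none", None
    if margin_to_line <= 0:
        raise DegenerateLandmarkError("non-positive margin-to-line distance")
    grade = "1" if extent < 0.5 * margin_to_line else \
            "2" if extent <= margin_to_line else "3"
    f = abs(lateral_fraction)
    zone = "A" if f <= 0.5 else "B" if f <= 1.0 else "C"
    return grade, zone


def msu_classify(geometry: Optional[HerniationGeometry],
                 intra_facet_line, midline_direction
                 ) -> tuple[str, Optional[str]]:
    """MSU grade and zone from 3D herniation geometry.

    The posterior direction is taken from the herniation base toward the
    intra-facet line; the mediolateral axis along the line itself.
    """
    if geometry is None or geometry.extent <= 0:
        return "none", None
    p1, p2 = (np.asarray(p, dtype=float) for p in intra_facet_line)
    if np.linalg.norm(p2 - p1) < 1e-9:
        raise DegenerateLandmarkError("intra-facet line endpoints coincide")
    lat = unit(p2 - p1)
    mid = 0.5 * (p1 + p2)
    half_len = 0.5 * float(np.linalg.norm(p2 - p1))
    base = np.asarray(geometry.base, dtype=float)
    apex = np.asarray(geometry.apex, dtype=float)
    to_line = mid - base
    post = to_line - np.dot(to_line, lat) * lat
    if np.linalg.norm(post) < 1e-9:
        raise DegenerateLandmarkError("herniation base lies on the line")
    d_line = float(np.linalg.norm(post))
    post = post / d_line
    extent = float(np.dot(apex - base, post))
    lateral_fraction = float(np.dot(apex - mid, lat)) / half_len
    return msu_grade_zone(extent, d_line, lateral_fraction)


# ---------------------------------------------------------------------------
# report assembly, diagnosis, cohort statistics

def build_report(truth, label_volume: Optional[LabelVolume] = None,
                 thresholds: Optional[Thresholds] = None,
                 psoas_vertebra: Optional[str] = None) -> MorphometryReport:
    """Measure every level of a phantom from its landmarks (plus the
    label volume for the voxel-based area measurements) and diagnose."""
    thresholds = thresholds or Thresholds()
    meas: dict[str, dict[str, object]] = {}
    for lv in truth.disc_labels:
        lm = truth.landmarks[lv]
        m: dict[str, object] = {
            "disc_vertical_diameter": measure_disc_vertical_diameter(lm),
            "canal_diameter": measure_canal_diameter(lm),
        }
        for side in SIDES:
            m[f"foramen_height_{side}"] = measure_foramen_height(lm, side)
            m[f"facet_joint_angle_{side}"] = measure_facet_joint_angle(lm, side)
            h, a = measure_lateral_recess(lm, side)
            m[f"lateral_recess_height_{side}"] = h
            m[f"lateral_recess_angle_{side}"] = a
        grade, zone = msu_classify(lm.herniation, lm.intra_facet_line,
                                   lm.midline_direction)
        m["msu_grade"], m["msu_zone"] = grade, zone
        if label_volume is not None:
            hkey = f"herniation_{lv}"
            if hkey in label_volume.label_map:
                canal = label_volume.mask("canal") | label_volume.mask(hkey)
                m["herniation_ratio"] = herniation_ratio(
                    label_volume.mask(hkey), canal)
            else:
                m["herniation_ratio"] = 0.0
        else:
            m["herniation_ratio"] = 0.0
        meas[lv] = m
    if label_volume is not None:
        vert = psoas_vertebra
        if vert is None:
            verts = sorted(n.split("_", 1)[1] for n in label_volume.label_map
                           if n.startswith("vertebra_"))
            vert = verts[len(verts) // 2] if verts else None
        if vert is not None:
            for side in SIDES:
                try:
                    area = measure_psoas_csa(label_volume, vert, side)
                except MissingStructureError:
                    area = None
                for lv in truth.disc_labels:
                    meas[lv][f"psoas_csa_{side}"] = area
    report = MorphometryReport(measurements=meas, thresholds=thresholds)
    report.diagnoses = diagnose(report, thresholds)
    return report


def diagnose(report: MorphometryReport,
             thresholds: Optional[Thresholds] = None
             ) -> dict[str, dict[str, object]]:
    """Apply the stenosis/herniation rules to each level's measurements.

    Missing measurements yield "indeterminate", never a silent negative.
    """
    th = thresholds or report.thresholds or Thresholds()
    out: dict[str, dict[str, object]] = {}
    for lv, m in report.measurements.items():
        d: dict[str, object] = {}
        cd = m.get("canal_diameter")
        d["canal_stenosis"] = ("indeterminate" if cd is None
                               else bool(cd < th.canal_mm))
        for side in SIDES:
            h = m.get(f"lateral_recess_height_{side}")
            a = m.get(f"lateral_recess_angle_{side}")
            if h is None or a is None:
                d[f"recess_stenosis_{side}"] = "indeterminate"
            else:
                angle_flag = (a < th.recess_angle_deg
                              if th.angle_direction == "less"
                              else a > th.recess_angle_deg)
                d[f"recess_stenosis_{side}"] = bool(
                    h < th.recess_height_mm or angle_flag)
        grade = m.get("msu_grade")
        d["herniation"] = ("indeterminate" if grade is None
                           else bool(grade in ("1", "2", "3")))
        out[lv] = d
    return out


def detection_rate(reports: list[MorphometryReport], condition: str,
                   level: Optional[str] = None) -> float:
    """Proportion of phantoms whose diagnosis for ``condition`` is
    positive (at the named level, or at any level when unspecified)."""
    if not reports:
        raise EmptyCohortError("no reports")
    n_pos = 0
    for r in reports:
        diag = r.diagnoses or diagnose(r)
        levels = [level] if level is not None else list(diag)
        if any(diag.get(lv, {}).get(condition) is True for lv in levels):
            n_pos += 1
    return n_pos / len(reports)
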