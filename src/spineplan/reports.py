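"""Deterministic report serialization (JSON and flat CSV).

Floats are rounded to 6 significant digits and keys sorted, so a fixed
pipeline configuration and seed produce byte-identical files across
runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .morphometry import MorphometryReport
from .planning import ScanPlan


def _round6(obj):
    if isinstance(obj, dict):
        return {k: _round6(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round6(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round6(obj.tolist())
    return obj


def report_to_json(report) -> str:
    if hasattr(report, "to_dict"):
        report = report.to_dict()
    return json.dumps(_round6(report), sort_keys=True, indent=2) + "\n"


def write_report(report, path: str | Path, format: str = "json") -> Path:
    """Write a MorphometryReport or ScanPlan deterministically."""
    path = Path(path)
    if format == "json":
        path.write_text(report_to_json(report))
        return path
    if format == "csv":
        if not isinstance(report, MorphometryReport):
            raise FormatError("CSV export is defined for morphometry reports")
        rows = report_rows(report)
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        df.to_csv(path, index=False, float_format="%.6g")
        return path
    raise FormatError(f"unknown report format {format!r}")


_CSV_COLUMNS = ["phantom", "level", "side", "measurement", "value"]

_SIDED_PREFIXES = ("foramen_height", "facet_joint_angle",
                   "lateral_recess_height", "lateral_recess_angle",
                   "psoas_csa")


def report_rows(report: MorphometryReport, phantom: str = "0") -> list[dict]:
    """Flatten one report to one row per (level, side, measurement)."""
    rows = []
    for lv, m in report.measurements.items():
        for name, value in sorted(m.items()):
            side = ""
            base = name
            for pre in _SIDED_PREFIXES:
                for s in ("left", "right"):
                    if name == f"{pre}_{s}":
                        base, side = pre, s
            if isinstance(value, float):
                value = float(f"{value:.6g}")
            rows.append({"phantom": phantom, "level": lv, "side": side,
                         "measurement": base, "value": value})
    return rows


def cohort_to_csv(reports: list[MorphometryReport], path: str | Path) -> Path:
    rows = []
    for i, r in enumerate(reports):
        rows.extend(report_rows(r, phantom=str(i)))
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def load_report_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except Exception as exc:
        raise FormatError(f"cannot parse report {path}: {exc}") from exc
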