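"""File formats: implant records, point correspondences, transforms, cohorts.

All tabular formats are plain CSV with fixed column schemas (mm and degrees,
decimal point, 1-based ids); transforms are JSON with a row-major 3x3
rotation and a translation vector; scenario/run configuration is YAML
mirroring the dataclass fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDesign, GroupEffects, ScenarioConfig
from .errors import ConfigError
from .geometry import METRIC_COLUMNS, Implant, RigidTransform
from .registration import PointCorrespondences

__all__ = [
    "read_implants",
    "write_implants",
    "read_correspondences",
    "write_correspondences",
    "read_transform",
    "write_transform",
    "read_deviations",
    "write_deviations",
    "load_run_config",
]

IMPLANT_COLUMNS = ("id", "px", "py", "pz", "ax", "ay", "az")
CORRESPONDENCE_COLUMNS = ("sx", "sy", "sz", "tx", "ty", "tz")


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")


def read_implants(path) -> list[Implant]:
    """Read implants from CSV: id, px..pz (platform), ax..az (apex), factors."""
    frame = pd.read_csv(path)
    _require_columns(frame, IMPLANT_COLUMNS, path)
    factor_cols = [c for c in frame.columns if c not in IMPLANT_COLUMNS]
    implants = []
    for _, row in frame.iterrows():
        implants.append(
            Implant(
                platform=np.array([row.px, row.py, row.pz], dtype=float),
                apex=np.array([row.ax, row.ay, row.az], dtype=float),
                id=str(row.id),
                factors={c: row[c] for c in factor_cols if pd.notna(row[c])},
            )
        )
    return implants


def write_implants(implants, path) -> None:
    rows = []
    for imp in implants:
        row = {
            "id": imp.id,
            "px": imp.platform[0],
            "py": imp.platform[1],
            "pz": imp.platform[2],
            "ax": imp.apex[0],
            "ay": imp.apex[1],
            "az": imp.apex[2],
        }
        row.update(imp.factors)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_correspondences(path) -> PointCorrespondences:
    """Read paired points from CSV: sx..sz (cast), tx..tz (CBCT), label."""
    frame = pd.read_csv(path)
    _require_columns(frame, CORRESPONDENCE_COLUMNS, path)
    coord_cols = list(CORRESPONDENCE_COLUMNS)
    bad = frame[coord_cols].isna().any(axis=1)
    if bad.any():
        raise ConfigError(f"{path}: non-numeric or missing coordinates on line(s) "
                          f"{[int(i) + 2 for i in frame.index[bad]]}")
    labels = list(frame["label"]) if "label" in frame.columns else None
    return PointCorrespondences(
        source_points=frame[["sx", "sy", "sz"]].to_numpy(float),
        target_points=frame[["tx", "ty", "tz"]].to_numpy(float),
        labels=labels,
    )


def write_correspondences(corr: PointCorrespondences, path) -> None:
    frame = pd.DataFrame(
        np.hstack([corr.source_points, corr.target_points]),
        columns=CORRESPONDENCE_COLUMNS,
    )
    if corr.labels is not None:
        frame["label"] = list(corr.labels)
    frame.to_csv(path, index=False)


def write_transform(transform: RigidTransform, path, extra: dict | None = None) -> None:
    payload = {
        "rotation": [list(map(float, row)) for row in transform.rotation],
        "translation": [float(v) for v in transform.translation],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_transform(path) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    try:
        return RigidTransform(
            np.array(payload["rotation"], dtype=float),
            np.array(payload["translation"], dtype=float),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing transform field {exc}") from exc


def write_deviations(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_deviations(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, METRIC_COLUMNS, path)
    return frame


def load_run_config(path):
    """Load a YAML run config: scenario, effects and design sections.

    Returns ``(ScenarioConfig, GroupEffects, CohortDesign or None)``.  The
    design section lists cells as ``registration/jaw/support: count``; when
    absent the caller falls back to the built-in study design.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        config = ScenarioConfig(**raw.get("scenario", {}))
        effects = GroupEffects(**raw.get("effects", {}))
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    design = None
    if "design" in raw:
        cells = {}
        for key, count in raw["design"].items():
            parts = tuple(str(key).split("/"))
            cells[parts] = int(count)
        design = CohortDesign(cells=cells)
    return config, effects, design
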