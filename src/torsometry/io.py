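"""Contour and configuration file I/O.

Contour sets travel as CSV (columns ``level_label,x,y``, one file per torso)
or an equivalent JSON layout; lengths are mm.  Run configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .pipeline import AssessmentConfig
from .slices import LEVEL_INDEX, LandmarkHeights, RawContour


def write_contours_csv(contours: dict[str, RawContour], path) -> None:
    rows = []
    for label, contour in contours.items():
        for x, y in contour.points:
            rows.append((label, x, y))
    pd.DataFrame(rows, columns=["level_label", "x", "y"]).to_csv(path, index=False)


def read_contours_csv(path) -> dict[str, RawContour]:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read contour CSV {path}: {exc}") from exc
    required = {"level_label", "x", "y"}
    if not required.issubset(frame.columns):
        raise FormatError(f"contour CSV needs columns {sorted(required)}")
    out: dict[str, RawContour] = {}
    for label, group in frame.groupby("level_label", sort=False):
        if label not in LEVEL_INDEX:
            raise ValidationError(f"unknown vertebral level {label!r} in {path}")
        out[str(label)] = RawContour(
            level_label=str(label), points=group[["x", "y"]].to_numpy(dtype=float)
        )
    return out


def write_contours_json(contours: dict[str, RawContour], path) -> None:
    payload = {
        "levels": {label: c.points.tolist() for label, c in contours.items()}
    }
    Path(path).write_text(json.dumps(payload))


def read_contours_json(path) -> dict[str, RawContour]:
    try:
        payload = json.loads(Path(path).read_text())
        levels = payload["levels"]
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read contour JSON {path}: {exc}") from exc
    out: dict[str, RawContour] = {}
    for label, pts in levels.items():
        if label not in LEVEL_INDEX:
            raise ValidationError(f"unknown vertebral level {label!r} in {path}")
        out[label] = RawContour(level_label=label, points=np.asarray(pts, dtype=float))
    return out


@dataclass
class RunConfig:
    """Parsed YAML run configuration: axes, landmarks and analysis settings."""

    up_axis: str = "z"
    anterior_axis: str = "y"
    landmarks: LandmarkHeights | None = None
    assessment: AssessmentConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.assessment is None:
            self.assessment = AssessmentConfig()


def load_run_config(path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse config {path}: {exc}") from exc
    axes = raw.get("axes", {})
    landmarks = None
    if "landmarks" in raw:
        lm = raw["landmarks"]
        try:
            landmarks = LandmarkHeights(
                c7=float(lm["c7"]), t8=float(lm["t8"]), l5=float(lm["l5"])
            )
        except KeyError as exc:
            raise ValidationError(f"landmarks need c7/t8/l5 heights: missing {exc}") from exc
    kwargs = {}
    for key in (
        "separation",
        "sp_offset",
        "sp_search_sector",
        "sp_smooth_window",
        "include_endpoints",
        "masks",
        "apex_range",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "sp_search_sector" in kwargs:
        kwargs["sp_search_sector"] = tuple(kwargs["sp_search_sector"])
    if "apex_range" in kwargs and kwargs["apex_range"] is not None:
        kwargs["apex_range"] = tuple(kwargs["apex_range"])
    if "masks" in kwargs:
        kwargs["masks"] = {
            lvl: [tuple(m) for m in masks] for lvl, masks in kwargs["masks"].items()
        }
    return RunConfig(
        up_axis=axes.get("up", "z"),
        anterior_axis=axes.get("anterior", "y"),
        landmarks=landmarks,
        assessment=AssessmentConfig(**kwargs),
    )
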