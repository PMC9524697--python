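"""End-to-end assessment runs, summaries and report serialization.

A run takes either a torso mesh plus the three landmark heights, or a
pre-extracted contour set, processes every vertebral level independently
(failures at single levels become warnings, not aborts), and produces an
:class:`AssessmentReport` with the per-level asymmetry records plus
whole-torso and apex-region means of the three parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import SliceAsymmetry, assess_slice
from .errors import TorsometryError, ValidationError
from .geometry import (
    align_slice,
    compute_centroid,
    detect_sp,
    estimate_vb_line,
    locate_backside_anchors,
    to_polar,
)
from .slices import (
    LEVEL_INDEX,
    LEVELS,
    LandmarkHeights,
    RawContour,
    TorsoMesh,
    exclude_sector,
    extract_slice,
    interpolate_levels,
)

#: Summary statistics reported for a level set.
SUMMARY_KEYS = ("backside_area_asym", "lr_area_asym", "r_squared")


class RunError(TorsometryError):
    """No vertebral level could be processed."""


@dataclass
class AssessmentConfig:
    """Tunable analysis settings (all angles in degrees, lengths in mm)."""

    separation: int = 70
    sp_offset: float = 40.0
    sp_search_sector: tuple[float, float] = (-150.0, -30.0)
    sp_smooth_window: int | None = None
    include_endpoints: bool = True
    masks: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    apex_range: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.apex_range is not None:
            idx = []
            for label in self.apex_range:
                if label not in LEVEL_INDEX:
                    raise ValidationError(f"unknown apex level {label!r}")
                idx.append(LEVEL_INDEX[label])
            idx.sort()
            if idx and idx != list(range(idx[0], idx[-1] + 1)):
                raise ValidationError("apex range must be a contiguous run of levels")
            self.apex_range = tuple(LEVELS[i] for i in idx)
        for label in self.masks:
            if label not in LEVEL_INDEX:
                raise ValidationError(f"mask refers to unknown level {label!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["apex_range"] = list(self.apex_range) if self.apex_range else None
        d["masks"] = {k: [list(m) for m in v] for k, v in self.masks.items()}
        return d


@dataclass
class AssessmentReport:
    """Per-level records plus whole-torso and apex summaries."""

    per_level: list[SliceAsymmetry]
    summary_all: dict[str, float]
    summary_apex: dict[str, float] | None
    metadata: dict

    def levels(self) -> list[str]:
        return [s.level_label for s in self.per_level]

    def level(self, label: str) -> SliceAsymmetry:
        for s in self.per_level:
            if s.level_label == label:
                return s
        raise KeyError(label)


@dataclass
class ReportDelta:
    """Per-level and summary differences (b − a) between two reports."""

    per_level: pd.DataFrame
    summary_all: dict[str, float]


def process_slice(contour: RawContour, config: AssessmentConfig) -> SliceAsymmetry:
    """Run the full per-slice chain: mask, centre, detect SP, align, assess."""
    masks = config.masks.get(contour.level_label or "", [])
    if masks:
        contour = exclude_sector(contour, masks)
    centroid = compute_centroid(contour)
    polar = to_polar(contour, centroid)
    sp = detect_sp(
        polar,
        search_sector=config.sp_search_sector,
        smooth_window=config.sp_smooth_window,
    )
    aligned = align_slice(polar, sp.angle)
    aligned.warnings.extend(sp.warnings)
    if masks:
        aligned.warnings.append(
            f"angular masks applied: {[list(m) for m in masks]}"
        )
    anchors = locate_backside_anchors(aligned, config.separation)
    vb = estimate_vb_line(aligned, config.sp_offset)
    return assess_slice(aligned, anchors, vb, config.include_endpoints)


def summarize(
    per_level: list[SliceAsymmetry], apex_range: tuple[str, ...] | None
) -> tuple[dict[str, float], dict[str, float] | None]:
    """Arithmetic means of the three parameters, overall and at the apex.

    An empty or absent apex range yields ``None`` (reported as not
    available), as for a torso without a localised curve.
    """

    def _means(records: list[SliceAsymmetry]) -> dict[str, float]:
        return {
            "backside_area_asym": float(np.mean([s.backside_area_asym for s in records])),
            "lr_area_asym": float(np.mean([s.lr_area_asym for s in records])),
            "r_squared": float(np.mean([s.r_squared_full for s in records])),
        }

    summary_all = _means(per_level)
    if not apex_range:
        return summary_all, None
    apex_records = [s for s in per_level if s.level_label in set(apex_range)]
    if not apex_records:
        return summary_all, None
    return summary_all, _means(apex_records)


def run_assessment(
    contours: Mapping[str, RawContour] | None = None,
    mesh: TorsoMesh | None = None,
    landmarks: LandmarkHeights | None = None,
    config: AssessmentConfig | None = None,
) -> AssessmentReport:
    """Assess a torso from a contour set or from a mesh plus landmarks.

    Levels are always processed in anatomical order (C7 → L5) so the report
    is independent of input ordering; per-level failures are recorded as
    warnings and the level is left out.  Raises :class:`RunError` when no
    level can be processed.
    """
    config = config or AssessmentConfig()
    run_warnings: list[str] = []
    if (contours is None) == (mesh is None):
        raise ValidationError("provide exactly one of `contours` or `mesh`")
    if mesh is not None:
        if landmarks is None:
            raise ValidationError("mesh input requires landmark heights")
        table = interpolate_levels(landmarks)
        contours = {}
        for label in LEVELS:
            try:
                contours[label] = extract_slice(mesh, table.height_of(label), label)
            except TorsometryError as exc:
                run_warnings.append(f"{label}: slice extraction failed: {exc}")
    missing = [lab for lab in LEVELS if lab not in contours]
    if missing:
        run_warnings.append(f"levels absent from input: {', '.join(missing)}")
    per_level: list[SliceAsymmetry] = []
    for label in LEVELS:
        if label not in contours:
            continue
        try:
            per_level.append(process_slice(contours[label], config))
        except TorsometryError as exc:
            run_warnings.append(f"{label}: {exc}")
    if not per_level:
        raise RunError("no vertebral level could be processed")
    summary_all, summary_apex = summarize(per_level, config.apex_range)
    metadata = {
        "software": f"torsometry {__version__}",
        "config": config.to_dict(),
        "warnings": run_warnings,
    }
    return AssessmentReport(
        per_level=per_level,
        summary_all=summary_all,
        summary_apex=summary_apex,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# serialization and comparison
# ---------------------------------------------------------------------------


def report_to_frame(report: AssessmentReport) -> pd.DataFrame:
    """One row per level with the scalar parameters."""
    rows = []
    for s in report.per_level:
        rows.append(
            {
                "level": s.level_label,
                "r_squared_full": s.r_squared_full,
                "r_squared_backside": s.r_squared_backside,
                "slope_full": s.slope_full,
                "intercept_full": s.intercept_full,
                "la_mm2": s.la,
                "ra_mm2": s.ra,
                "lr_area_asym": s.lr_area_asym,
                "backside_area_asym": s.backside_area_asym,
                "mean_radius_mm": s.mean_radius,
                "n_warnings": len(s.warnings),
            }
        )
    return pd.DataFrame(rows)


def profiles_to_frame(report: AssessmentReport) -> pd.DataFrame:
    """Long-format backside profiles: level, angle offset, side, RR, Dist_VB."""
    rows = []
    for s in report.per_level:
        for side, rr, dist in (
            ("right", s.rad_back_right, s.dist_vb_right),
            ("left", s.rad_back_left, s.dist_vb_left),
        ):
            for off in range(len(rr)):
                rows.append((s.level_label, off, side, rr[off], dist[off]))
    return pd.DataFrame(
        rows, columns=["level", "angle_offset", "side", "rr", "dist_vb"]
    )


def report_to_dict(report: AssessmentReport) -> dict:
    per_level = []
    for s in report.per_level:
        d = asdict(s)
        for key in ("dist_vb_left", "dist_vb_right", "rad_back_left", "rad_back_right"):
            d[key] = np.asarray(d[key]).tolist()
        per_level.append(d)
    return {
        "per_level": per_level,
        "summary_all": report.summary_all,
        "summary_apex": report.summary_apex,
        "metadata": report.metadata,
    }


def write_report(report: AssessmentReport, outdir) -> dict[str, Path]:
    """Write report.csv, profiles.csv and report.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": outdir / "report.csv",
        "profiles": outdir / "profiles.csv",
        "json": outdir / "report.json",
    }
    report_to_frame(report).to_csv(paths["csv"], index=False)
    profiles_to_frame(report).to_csv(paths["profiles"], index=False)
    paths["json"].write_text(json.dumps(report_to_dict(report), indent=1))
    return paths


def read_report_json(path) -> AssessmentReport:
    payload = json.loads(Path(path).read_text())
    per_level = []
    for d in payload["per_level"]:
        for key in ("dist_vb_left", "dist_vb_right", "rad_back_left", "rad_back_right"):
            d[key] = np.asarray(d[key], dtype=float)
        per_level.append(SliceAsymmetry(**d))
    return AssessmentReport(
        per_level=per_level,
        summary_all=payload["summary_all"],
        summary_apex=payload["summary_apex"],
        metadata=payload["metadata"],
    )


def compare_reports(report_a: AssessmentReport, report_b: AssessmentReport) -> ReportDelta:
    """Per-level and summary differences (b − a) for the three parameters."""
    common = [lab for lab in report_a.levels() if lab in set(report_b.levels())]
    if not common:
        raise ValidationError("reports share no vertebral levels")
    rows = []
    for lab in common:
        a, b = report_a.level(lab), report_b.level(lab)
        rows.append(
            {
                "level": lab,
                "d_r_squared_full": b.r_squared_full - a.r_squared_full,
                "d_lr_area_asym": b.lr_area_asym - a.lr_area_asym,
                "d_backside_area_asym": b.backside_area_asym - a.backside_area_asym,
            }
        )
    summary = {
        key: report_b.summary_all[key] - report_a.summary_all[key]
        for key in SUMMARY_KEYS
    }
    return ReportDelta(per_level=pd.DataFrame(rows), summary_all=summary)
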