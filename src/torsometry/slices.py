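"""Torso meshes, vertebral levels and transverse slice extraction.

The torso region analysed runs over the 18 vertebral levels C7, T1–T12,
L1–L5.  Three landmark heights (C7, T8, L5 — identified on the scan by a
specialist, never detected automatically) anchor the level table; the levels
in between are spaced equally within each span.  At every level height a
horizontal plane cuts the mesh and the largest closed intersection loop is
kept as the torso contour; arm fragments that survive as part of the torso
loop can be removed with configured angular masks.

Internal axis convention: ``z`` is the vertical body axis (superior positive)
and ``+y`` is anterior.  Contours are ordered counterclockwise as seen from
superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon

from .errors import (
    EmptySliceError,
    FormatError,
    TopologyError,
    ValidationError,
)

#: The 18 analysed vertebral levels, superior to inferior.
LEVELS: tuple[str, ...] = (
    "C7",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8",
    "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
)

LEVEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(LEVELS)}


def wrap_deg(angle):
    """Wrap angles (degrees) into [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area (positive for counterclockwise loops)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkHeights:
    """Heights (mm, along the vertical axis) of the three marked landmarks."""

    c7: float
    t8: float
    l5: float

    def __post_init__(self) -> None:
        if not (self.c7 > self.t8 > self.l5):
            raise ValidationError(
                f"landmark heights must satisfy c7 > t8 > l5, "
                f"got c7={self.c7}, t8={self.t8}, l5={self.l5}"
            )


@dataclass(frozen=True)
class VertebralLevelTable:
    """Ordered (level label, height) pairs for all 18 levels, C7 first."""

    labels: tuple[str, ...]
    heights: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.labels != LEVELS:
            raise ValidationError("level table must cover exactly C7..L5 in order")
        if not np.all(np.diff(self.heights) < 0):
            raise ValidationError("level heights must be strictly decreasing")

    def height_of(self, label: str) -> float:
        return self.heights[LEVEL_INDEX[label]]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.heights))


@dataclass
class TorsoMesh:
    """A closed torso surface in the internal frame (z up, +y anterior)."""

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3 or len(self.vertices) < 4:
            raise ValidationError("mesh needs >= 4 vertices with 3 coordinates each")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3 or len(self.faces) < 4:
            raise ValidationError("mesh needs >= 4 triangular faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValidationError("face indices out of range")

    @property
    def z_range(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class RawContour:
    """An ordered closed 2D point loop in the transverse plane at one level.

    ``points`` stores the loop open (the closing edge from the last point back
    to the first is implicit).  Consecutive duplicates are dropped at
    construction; the loop must be simple and have at least 30 points.
    ``masked_spans`` records angular intervals (degrees, about the centroid at
    masking time) that were removed and bridged by straight chords.
    """

    level_label: str | None
    points: np.ndarray
    closed: bool = True
    masked_spans: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("contour points must be an (n, 2) array")
        # drop consecutive duplicates, including the wrap pair
        keep = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
        keep = np.concatenate([[True], keep])
        pts = pts[keep]
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 30:
            raise ValidationError(f"contour needs >= 30 distinct points, got {len(pts)}")
        poly = Polygon(pts)
        if not poly.is_simple or not poly.is_valid:
            raise TopologyError(
                f"contour at level {self.level_label!r} is self-intersecting"
            )
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


def _axis_vector(name: str) -> np.ndarray:
    sign = 1.0
    name = name.strip().lower()
    if name.startswith(("+", "-")):
        sign = -1.0 if name[0] == "-" else 1.0
        name = name[1:]
    if name not in _AXES:
        raise ValidationError(f"unknown axis {name!r}; use one of +-x, +-y, +-z")
    return sign * _AXES[name]


def load_mesh(path, up_axis: str = "z", anterior_axis: str = "y") -> TorsoMesh:
    """Load a PLY/OBJ surface and rotate it into the internal frame.

    ``up_axis``/``anterior_axis`` name the file's vertical body axis and
    anterior direction (e.g. ``"y"``, ``"-x"``); they must be orthogonal.
    """
    up = _axis_vector(up_axis)
    ant = _axis_vector(anterior_axis)
    if abs(float(up @ ant)) > 1e-9:
        raise ValidationError("up_axis and anterior_axis must differ and be orthogonal")
    try:
        loaded = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise FormatError(f"could not read mesh {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise FormatError(f"{path} contains no triangulated surface")
    # columns of the world->internal rotation: internal x, y(anterior), z(up)
    x_int = np.cross(ant, up)
    basis = np.column_stack([x_int, ant, up])
    vertices = np.asarray(loaded.vertices, dtype=float) @ basis
    return TorsoMesh(vertices=vertices, faces=np.asarray(loaded.faces))


def interpolate_levels(landmarks: LandmarkHeights) -> VertebralLevelTable:
    """Equal-spacing level heights from the C7/T8/L5 landmarks.

    C7→T8 is divided into 8 equal intervals (C7, T1..T8) and T8→L5 into 9
    (T9..L5); the three landmark heights are reproduced exactly.
    """
    upper = np.linspace(landmarks.c7, landmarks.t8, 9)       # C7..T8
    lower = np.linspace(landmarks.t8, landmarks.l5, 10)[1:]  # T9..L5
    heights = tuple(float(h) for h in np.concatenate([upper, lower]))
    return VertebralLevelTable(labels=LEVELS, heights=heights)


def extract_slice(mesh: TorsoMesh, height: float, level_label: str | None = None) -> RawContour:
    """Cut the mesh with the horizontal plane at ``height``.

    If several closed loops result (torso plus arms) the loop of largest
    enclosed area is kept.  Points are returned counterclockwise as seen from
    superior.
    """
    zmin, zmax = mesh.z_range
    if not (zmin < height < zmax):
        raise EmptySliceError(
            f"plane z={height} outside mesh vertical extent [{zmin}, {zmax}]"
        )
    section = mesh.to_trimesh().section(
        plane_origin=[0.0, 0.0, float(height)], plane_normal=[0.0, 0.0, 1.0]
    )
    if section is None:
        raise EmptySliceError(f"plane z={height} does not intersect the mesh")
    loops = []
    for polyline in section.discrete:
        pts = np.asarray(polyline, dtype=float)
        if not np.allclose(pts[0], pts[-1], atol=1e-6):
            raise TopologyError(
                f"open polyline in section at z={height}: endpoints "
                f"{pts[0][:2]} vs {pts[-1][:2]}"
            )
        loops.append(pts[:-1, :2])
    if not loops:
        raise EmptySliceError(f"plane z={height} produced no loops")
    # largest enclosed area wins, independent of the order trimesh returns
    areas = [abs(shoelace_area(lp)) for lp in loops]
    pts = loops[int(np.argmax(areas))]
    if shoelace_area(pts) < 0:
        pts = pts[::-1]
    return RawContour(level_label=level_label, points=pts)


def _normalize_masks(masks) -> list[tuple[float, float]]:
    """Split wrap-around intervals and validate total coverage < 180 degrees."""
    flat: list[tuple[float, float]] = []
    total = 0.0
    for lo, hi in masks:
        lo_w, hi_w = float(wrap_deg(lo)), float(wrap_deg(hi))
        if hi_w <= lo_w:  # wraps through +-180
            flat.extend([(lo_w, 180.0), (-180.0, hi_w)])
            total += (180.0 - lo_w) + (hi_w + 180.0)
        else:
            flat.append((lo_w, hi_w))
            total += hi_w - lo_w
    if total >= 180.0:
        raise ValidationError(
            f"angular masks cover {total:.1f} deg >= 180 deg; contour not analyzable"
        )
    return flat


def exclude_sector(contour: RawContour, masks) -> RawContour:
    """Remove points inside angular masks about the contour centroid.

    ``masks`` is an iterable of (lo, hi) degree intervals in the raw frame
    (0° = +x, counterclockwise).  Each removed run is bridged by a straight
    chord sampled at roughly the original point spacing so downstream angular
    resampling stays defined; the removed spans are recorded on the result.
    """
    masks = list(masks)
    if not masks:
        return contour
    flat = _normalize_masks(masks)
    pts = contour.points
    centroid = pts.mean(axis=0)
    ang = np.degrees(np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0]))
    inside = np.zeros(len(pts), dtype=bool)
    for lo, hi in flat:
        inside |= (ang >= lo) & (ang <= hi)
    if not inside.any():
        return contour
    if inside.all():
        raise ValidationError("masks remove every contour point")
    # walk the loop, emit kept points, bridge each removed run with a chord
    n = len(pts)
    start = int(np.flatnonzero(~inside)[0])
    order = (np.arange(n) + start) % n
    spacing = float(np.median(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    out: list[np.ndarray] = []
    i = 0
    while i < n:
        idx = order[i]
        if not inside[idx]:
            out.append(pts[idx])
            i += 1
            continue
        j = i
        while j < n and inside[order[j]]:
            j += 1
        a = pts[order[i - 1]]
        b = pts[order[j % n]]
        gap = float(np.linalg.norm(b - a))
        n_fill = max(int(gap / max(spacing, 1e-9)) - 1, 0)
        for t in np.linspace(0.0, 1.0, n_fill + 2)[1:-1]:
            out.append(a + t * (b - a))
        i = j
    return RawContour(
        level_label=contour.level_label,
        points=np.asarray(out),
        masked_spans=contour.masked_spans + flat,
    )
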