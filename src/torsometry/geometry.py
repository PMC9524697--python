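"""Polar conversion, spinous-process detection and slice alignment.

Every slice is analysed in a centroid-origin polar frame.  The spinous
process (SP) shows as the characteristic dip — the local radius minimum — on
the posterior part of the contour.  After a two-step rotation (maximal
centroid diameter made horizontal, then a fine rotation putting the SP
directly below the centroid) the contour is resampled onto a uniform 1° grid
with the SP at 0°.  Aligned angles run counterclockwise: 0°..180° is the
right body side, 0°..−180° the left, and ±180° (the anterior midline) is one
physical point stored twice for wraparound.

In the aligned frame the Cartesian coordinates of grid angle θ are
``x = r sin θ``, ``y = −r cos θ`` (SP at the bottom, anterior at the top).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point

from .errors import GeometryError, ValidationError
from .slices import RawContour, wrap_deg

#: Aligned angular grid, degrees: 0 at the SP, −180..180 inclusive (361 nodes).
THETA_GRID = np.arange(-180.0, 181.0)

_POSTERIOR = -90.0  # standard-frame angle of the posterior midline (anterior = +y)


@dataclass
class PolarContour:
    """Centroid-origin polar samples of a raw contour, sorted by angle.

    ``theta`` is in degrees in [−180, 180) in the standard frame (0° = +x,
    counterclockwise, anterior = +90°).  ``star_shaped`` is False when the
    source loop crossed some ray from the origin more than once; angular
    resampling then keeps the largest radius per 1° bin (outer silhouette).
    """

    theta: np.ndarray
    r: np.ndarray
    origin: np.ndarray
    star_shaped: bool = True
    level_label: str | None = None
    masked_spans: list[tuple[float, float]] = field(default_factory=list)

    def rotated(self, angle_deg: float) -> "PolarContour":
        th = wrap_deg(self.theta + angle_deg)
        order = np.argsort(th, kind="stable")
        return PolarContour(
            theta=th[order],
            r=self.r[order],
            origin=self.origin,
            star_shaped=self.star_shaped,
            level_label=self.level_label,
            masked_spans=self.masked_spans,
        )

    def to_points(self) -> np.ndarray:
        """Inverse transform back to Cartesian points about the origin."""
        th = np.radians(self.theta)
        return self.origin + np.column_stack([self.r * np.cos(th), self.r * np.sin(th)])


@dataclass
class AlignedPolarContour:
    """Radii on the exact 1° grid of the aligned (SP-at-0°) frame.

    ``radius`` has 361 entries for θ = −180..180 with
    ``radius[0] == radius[360]``; the mean radius is taken over the 360
    distinct grid angles.
    """

    radius: np.ndarray
    rotation_applied: float = 0.0
    level_label: str | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.radius = np.asarray(self.radius, dtype=float)
        if self.radius.shape != (361,):
            raise ValidationError("aligned contour needs 361 grid radii (-180..180)")
        if np.any(self.radius <= 0):
            raise ValidationError("aligned contour radii must be positive")
        if not np.isclose(self.radius[0], self.radius[360], rtol=1e-9, atol=1e-9):
            raise ValidationError("wraparound mismatch: r(-180) != r(+180)")

    @property
    def theta(self) -> np.ndarray:
        return THETA_GRID

    @property
    def mean_radius(self) -> float:
        """Grid-mean radius r_m over the 360 distinct angles."""
        return float(self.radius[:360].mean())

    def r(self, theta_deg):
        """Radii at integer grid angles (degrees, −180..180)."""
        idx = np.asarray(np.round(theta_deg), dtype=int) + 180
        return self.radius[idx]

    def points(self) -> np.ndarray:
        """Aligned-frame Cartesian grid points (SP at the bottom)."""
        th = np.radians(THETA_GRID[:360])
        r = self.radius[:360]
        return np.column_stack([r * np.sin(th), -r * np.cos(th)])


@dataclass(frozen=True)
class BacksideAnchors:
    """BLSP/BRSP anchor angles at ±separation about the SP."""

    separation: int
    sp_index: int = 180  # grid index of θ = 0

    def __post_init__(self) -> None:
        if not 0 < self.separation < 180:
            raise ValidationError(
                f"anchor separation must lie in (0, 180) deg, got {self.separation}"
            )

    @property
    def brsp_angle(self) -> float:
        return float(self.separation)

    @property
    def blsp_angle(self) -> float:
        return -float(self.separation)


@dataclass(frozen=True)
class VBLine:
    """Horizontal line through the approximated vertebral-body centre.

    The centre is placed ``sp_offset`` mm anterior of the SP surface point on
    the SP–centroid vertical; vertebral anatomy beyond this offset is
    deliberately neglected.
    """

    vb_center: tuple[float, float]
    sp_offset: float
    direction: tuple[float, float] = (1.0, 0.0)

    @property
    def height(self) -> float:
        return self.vb_center[1]


@dataclass
class SPDetection:
    """Detected spinous-process angle (standard frame) plus any warnings."""

    angle: float
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_centroid(contour: RawContour) -> np.ndarray:
    """Arithmetic mean of the contour points (point mean, not area centroid)."""
    return contour.points.mean(axis=0)


def to_polar(contour: RawContour, origin) -> PolarContour:
    """Convert a contour to centroid-origin polar samples sorted by angle."""
    origin = np.asarray(origin, dtype=float)
    if not contour.polygon.contains(Point(origin)):
        raise GeometryError(f"polar origin {origin} lies outside the contour")
    rel = contour.points - origin
    theta = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    r = np.linalg.norm(rel, axis=1)
    # star-shapedness: walking the loop, the polar angle must wind monotonically
    d = wrap_deg(np.diff(theta, append=theta[:1]))
    star = bool(np.all(d > -1e-9) or np.all(d < 1e-9))
    order = np.argsort(theta, kind="stable")
    return PolarContour(
        theta=wrap_deg(theta[order]),
        r=r[order],
        origin=origin,
        star_shaped=star,
        level_label=contour.level_label,
        masked_spans=list(contour.masked_spans),
    )


def _prepared_samples(polar: PolarContour) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique angular samples; non-star loops keep max radius per 1° bin."""
    theta, r = polar.theta, polar.r
    if not polar.star_shaped:
        bins = np.round(theta).astype(int)
        keep_theta, keep_r = [], []
        for b in np.unique(bins):
            sel = bins == b
            keep_theta.append(float(b))
            keep_r.append(float(r[sel].max()))
        theta, r = np.asarray(keep_theta), np.asarray(keep_r)
    else:
        uniq, idx = np.unique(theta, return_index=True)
        theta, r = uniq, r[idx]
    return theta, r


def _grid_interp(theta: np.ndarray, r: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation of r(θ) at the query angles (degrees)."""
    return np.interp(wrap_deg(query), theta, r, period=360.0)


def _gap_warnings(theta: np.ndarray, limit: float = 10.0) -> list[str]:
    gaps = np.diff(np.concatenate([theta, [theta[0] + 360.0]]))
    worst = float(gaps.max())
    if worst > limit:
        at = float(theta[int(np.argmax(gaps))])
        return [f"angular gap of {worst:.1f} deg starting at {at:.1f} deg interpolated"]
    return []


def resample_angular(polar: PolarContour, rotation_applied: float = 0.0) -> AlignedPolarContour:
    """Resample already-aligned polar samples onto the exact 1° grid.

    Radii are linearly interpolated in (θ, r) with wraparound; a contour that
    is linear in θ between samples is reproduced exactly and a constant
    contour is a fixed point.  Gaps wider than 10° (e.g. masked arms) are
    interpolated across and recorded as warnings.
    """
    theta, r = _prepared_samples(polar)
    warnings = _gap_warnings(theta)
    if not polar.star_shaped:
        warnings.append("non-star-shaped contour: kept largest radius per 1 deg bin")
    radius = _grid_interp(theta, r, THETA_GRID)
    return AlignedPolarContour(
        radius=radius,
        rotation_applied=rotation_applied,
        level_label=polar.level_label,
        warnings=warnings,
    )


def moving_average_filter(radius: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average over ``window`` degrees (odd window)."""
    if window < 3 or window % 2 == 0:
        raise ValidationError("smoothing window must be an odd integer >= 3")
    kernel = np.ones(window) / window
    half = window // 2
    padded = np.concatenate([radius[-half:], radius, radius[:half]])
    return np.convolve(padded, kernel, mode="valid")


def detect_sp(
    polar: PolarContour,
    search_sector: tuple[float, float] = (-150.0, -30.0),
    smooth_window: int | None = None,
) -> SPDetection:
    """Locate the spinous process as the radius minimum in the posterior sector.

    The search is restricted to ``search_sector`` (standard-frame degrees;
    default the posterior 120°) so waist concavities elsewhere cannot win.
    Ties are broken towards the sector midline; a flat minimum spanning more
    than 30° yields a low-confidence warning (a featureless circle returns
    the posterior midline).  The grid minimum is refined to sub-degree
    precision by a parabola through its two neighbours, so the detected angle
    (and hence the alignment rotation) responds continuously to small shape
    changes instead of hopping in 1° steps.  ``smooth_window`` (degrees, odd)
    enables the optional moving-average pre-filter for noisy scans; detection
    itself is otherwise unsmoothed.
    """
    lo, hi = float(search_sector[0]), float(search_sector[1])
    if not lo < hi:
        raise ValidationError("search sector must be a non-empty (lo, hi) interval")
    theta, r = _prepared_samples(polar)
    grid_r = _grid_interp(theta, r, THETA_GRID[:360])
    if smooth_window:
        grid_r = moving_average_filter(grid_r, smooth_window)
    grid_t = THETA_GRID[:360]
    midline = 0.5 * (lo + hi)
    sel = (grid_t >= lo) & (grid_t <= hi)
    if not sel.any():
        raise ValidationError("search sector contains no grid angles")
    warnings: list[str] = []
    sector_t, sector_r = grid_t[sel], grid_r[sel]
    rmin = float(sector_r.min())
    mean_r = float(grid_r.mean())
    ties = sector_t[sector_r <= rmin + 1e-9 * mean_r]
    angle = float(ties[np.argmin(np.abs(ties - midline))])
    # a near-flat minimum (within 0.1% of r_m) spanning > 30 deg is unreliable
    flat = sector_t[sector_r <= rmin + 1e-3 * mean_r]
    flat_minimum = flat.max() - flat.min() > 30.0
    if flat_minimum:
        warnings.append(
            f"flat radius minimum spanning {flat.max() - flat.min():.0f} deg; "
            "SP position is low-confidence"
        )
    else:
        # parabolic sub-degree refinement through the grid neighbours
        k = int(angle) + 180
        r_m1, r_0, r_p1 = grid_r[(k - 1) % 360], grid_r[k % 360], grid_r[(k + 1) % 360]
        curvature = r_m1 - 2.0 * r_0 + r_p1
        if curvature > 1e-12 * mean_r:
            shift = 0.5 * (r_m1 - r_p1) / curvature
            angle += float(np.clip(shift, -0.5, 0.5))
    return SPDetection(angle=angle, warnings=warnings)


def align_slice(polar: PolarContour, sp_angle: float) -> AlignedPolarContour:
    """Two-step rotational alignment, then resampling onto the aligned grid.

    Step 1 makes the maximal centroid diameter — the angle maximising
    d(θ) = r(θ) + r(θ+180°) on the 1° grid — horizontal (ties, e.g. a circle,
    break towards the diameter already closest to horizontal).  Step 2 adds
    the fine rotation that puts the SP directly below the centroid; of the two
    horizontal orientations of step 1 the one needing the smaller correction
    is used, and a correction beyond 45° is flagged.  Angles are then
    re-indexed so the SP sits at 0° with the right body side at 0°..180°.
    """
    theta, r = _prepared_samples(polar)
    grid_r = _grid_interp(theta, r, THETA_GRID[:360])
    diam = grid_r[:180] + grid_r[180:]          # θ = −180..−1 paired with θ+180
    diam_theta = THETA_GRID[:180]
    near_max = diam >= diam.max() - 1e-9 * float(grid_r.mean())
    cand = diam_theta[near_max]
    tilt = np.minimum(np.abs(cand), np.abs(cand + 180.0))  # distance from horizontal
    theta_star = float(cand[np.argmin(tilt)])
    warnings: list[str] = []
    best_total, best_delta = None, None
    for rho1 in (-theta_star, -theta_star + 180.0):
        delta = float(wrap_deg(_POSTERIOR - sp_angle - rho1))
        if best_delta is None or abs(delta) < abs(best_delta):
            best_delta, best_total = delta, float(wrap_deg(rho1 + delta))
    if abs(best_delta) > 45.0:
        warnings.append(
            f"SP fine-tuning needed {best_delta:.1f} deg; SP detection and "
            "principal direction disagree strongly"
        )
    total = best_total
    # aligned θ_a corresponds to pre-rotation standard angle θ_a − 90° − total
    radius = _grid_interp(theta, r, THETA_GRID + _POSTERIOR - total)
    out = AlignedPolarContour(
        radius=radius,
        rotation_applied=total,
        level_label=polar.level_label,
        warnings=warnings + _gap_warnings(theta),
    )
    if not polar.star_shaped:
        out.warnings.append("non-star-shaped contour: kept largest radius per 1 deg bin")
    return out


def locate_backside_anchors(
    aligned: AlignedPolarContour, separation: int = 70
) -> BacksideAnchors:
    """Anchor BRSP/BLSP at ±separation degrees about the SP on the grid."""
    sep = float(separation)
    if abs(sep - round(sep)) > 1e-9:
        raise ValidationError("anchor separation must be a whole number of degrees")
    return BacksideAnchors(separation=int(round(sep)))


def estimate_vb_line(aligned: AlignedPolarContour, sp_offset: float = 40.0) -> VBLine:
    """Place the vertebral-body centre ``sp_offset`` mm anterior of the SP.

    In the aligned frame the SP point is (0, −r(0°)); the VB centre sits on
    the vertical SP–centroid line at (0, −r(0°) + sp_offset) and the VB line
    is the horizontal line through it.  The centre must stay strictly inside
    the contour (sp_offset below the vertical diameter r(0°) + r(180°)).
    """
    if sp_offset <= 0:
        raise ValidationError("sp_offset must be positive (mm)")
    r_sp = float(aligned.r(0))
    r_ant = float(aligned.r(180))
    if sp_offset >= r_sp + r_ant:
        raise ValidationError(
            f"sp_offset {sp_offset} mm places the VB centre outside the contour "
            f"(vertical diameter {r_sp + r_ant:.1f} mm)"
        )
    return VBLine(vb_center=(0.0, -r_sp + float(sp_offset)), sp_offset=float(sp_offset))
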