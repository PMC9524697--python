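"""Per-slice asymmetry parameters.

Three quantities characterise each aligned slice:

* the coefficient of determination R² of an ordinary least-squares fit of the
  left relative-radius branch against the right one — 1 for a perfectly
  mirror-symmetric contour, smaller the more the sides disagree;
* the left–right area asymmetry |LA − RA| / (LA + RA), where LA and RA are
  the triangle-fan areas of the contour on either side of the SP–centroid
  axis;
* the same area asymmetry restricted to the backside sectors between the SP
  and the BLSP/BRSP anchors.

Relative radii RR(θ) = r(θ)/r_m · 100 are dimensionless (percent of the mean
contour radius), so R² and the area asymmetries are scale-invariant.
``Dist_VB`` profiles — vertical distances from the vertebral-body line to the
backside contour — quantify rib-hump prominence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import AlignedPolarContour, BacksideAnchors, VBLine

logger = logging.getLogger(__name__)

_DEG = np.pi / 180.0


@dataclass
class RelativeRadiusProfile:
    """Normalised radii split into right (0..180°) and left (0..−180°) branches.

    Both branches have 181 entries indexed by |θ| and share the SP point at
    index 0 and the anterior midline at index 180.  The mean of RR over the
    360 distinct grid angles is 100 by construction.
    """

    rr_right: np.ndarray
    rr_left: np.ndarray
    mean_radius: float
    level_label: str | None = None

    def __post_init__(self) -> None:
        self.rr_right = np.asarray(self.rr_right, dtype=float)
        self.rr_left = np.asarray(self.rr_left, dtype=float)
        if self.rr_right.shape != (181,) or self.rr_left.shape != (181,):
            raise ValidationError("each RR branch needs 181 entries (0..180 deg)")
        if not np.isclose(self.rr_right[0], self.rr_left[0]):
            raise ValidationError("branches must share the SP point at index 0")


@dataclass(frozen=True)
class SymmetryFit:
    """OLS fit of the left branch on the right branch and its R²."""

    slope: float
    intercept: float
    r_squared: float
    r_squared_identity: float
    n_points: int


@dataclass
class BacksideMetrics:
    """Backside sector areas, their asymmetry, and SP-centred profiles."""

    la_back: float
    ra_back: float
    backside_area_asym: float
    dist_vb_left: np.ndarray
    dist_vb_right: np.ndarray
    rad_back_left: np.ndarray
    rad_back_right: np.ndarray


@dataclass
class SliceAsymmetry:
    """Complete per-slice record of the asymmetry parameters."""

    level_label: str | None
    r_squared_full: float
    r_squared_backside: float
    slope_full: float
    intercept_full: float
    la: float
    ra: float
    lr_area_asym: float
    backside_area_asym: float
    dist_vb_left: np.ndarray
    dist_vb_right: np.ndarray
    rad_back_left: np.ndarray
    rad_back_right: np.ndarray
    mean_radius: float
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def relative_radius(aligned: AlignedPolarContour) -> RelativeRadiusProfile:
    """Normalise grid radii by the mean radius, on the percent scale."""
    rm = aligned.mean_radius
    rr = aligned.radius / rm * 100.0
    return RelativeRadiusProfile(
        rr_right=rr[180:361],        # θ = 0, 1, .., 180
        rr_left=rr[180::-1],         # θ = 0, −1, .., −180
        mean_radius=rm,
        level_label=aligned.level_label,
    )


def _select_pairs(
    profile: RelativeRadiusProfile, sector, include_endpoints: bool
) -> tuple[np.ndarray, np.ndarray]:
    if sector == "full":
        hi = 180
    else:
        hi = int(sector)
        if not 0 < hi <= 180:
            raise ValidationError("backside sector must lie in (0, 180] degrees")
    x = profile.rr_right[: hi + 1]
    y = profile.rr_left[: hi + 1]
    if not include_endpoints:
        x, y = x[1:-1], y[1:-1]
    if len(x) < 3:
        raise ValidationError("need at least 3 paired angles for the symmetry fit")
    return x, y


def fit_left_right(
    profile: RelativeRadiusProfile,
    sector="full",
    include_endpoints: bool = True,
) -> SymmetryFit:
    """OLS fit of paired branches and its coefficient of determination.

    Pairs (RR_right(|θ|), RR_left(|θ|)) are matched by equal |θ| on the 1°
    grid; ``sector`` is ``"full"`` (|θ| = 0..180) or a backside separation in
    degrees (|θ| = 0..separation).  The right branch is the abscissa.  R² is
    one minus the residual sum of squares about the fitted line over the
    total sum of squares; ``r_squared_identity`` uses residuals about the
    ideal symmetry line y = x instead.  A constant contour (zero abscissa
    variance) is exactly symmetric and returns the perfect-symmetry
    convention slope 1, intercept 0, R² = 1.
    """
    x, y = _select_pairs(profile, sector, include_endpoints)
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx < 1e-12:
        logger.info("zero abscissa variance: returning perfect-symmetry convention")
        return SymmetryFit(
            slope=1.0, intercept=0.0, r_squared=1.0, r_squared_identity=1.0, n_points=n
        )
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_id = float(np.sum((y - x) ** 2))
    if ss_tot < 1e-12:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
        r2_id = 1.0 if ss_id < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2_id = 1.0 - ss_id / ss_tot
    return SymmetryFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        r_squared_identity=r2_id,
        n_points=n,
    )


def fan_area(aligned: AlignedPolarContour, sector: tuple[int, int] = (-180, 180)) -> float:
    """Triangle-fan area (mm²) of an angular sector about the centroid.

    The sector is split into 1° triangles whose apex is the centroid and
    whose other vertices are consecutive grid points; each triangle area is
    half the cross product r_i r_{i+1} sin(1°) and the fan is their sum.  For
    the full sector this equals the shoelace area of the grid polygon.
    """
    lo, hi = int(sector[0]), int(sector[1])
    if not (-180 <= lo <= hi <= 180):
        raise ValidationError(f"sector {sector} outside the grid range [-180, 180]")
    if lo == hi:
        return 0.0
    i = np.arange(lo + 180, hi + 180)
    r = aligned.radius
    return float(0.5 * np.sin(_DEG) * np.sum(r[i] * r[i + 1]))


def area_asymmetry(la: float, ra: float) -> float:
    """Dimensionless area asymmetry |LA − RA| / (LA + RA), in [0, 1]."""
    if la < 0 or ra < 0:
        raise ValidationError("areas must be non-negative")
    if la + ra == 0:
        raise ValidationError("area asymmetry undefined for two zero areas")
    return abs(la - ra) / (la + ra)


def backside_metrics(
    aligned: AlignedPolarContour,
    anchors: BacksideAnchors,
    vb: VBLine,
) -> BacksideMetrics:
    """Backside area asymmetry, Dist_VB and relative-radius profiles.

    Fan areas over [0, +sep] and [−sep, 0] feed the area-asymmetry formula.
    For each grid angle between the SP and an anchor, Dist_VB is the vertical
    distance from the VB line down to the contour point (aligned frame
    y = −r cos θ), indexed by angular offset from the SP so the SP sits at
    offset 0.  ``rad_back`` are the RR values over the same offsets.
    """
    sep = anchors.separation
    ra_back = fan_area(aligned, (0, sep))
    la_back = fan_area(aligned, (-sep, 0))
    offsets = np.arange(sep + 1)
    r_right = aligned.r(offsets)
    r_left = aligned.r(-offsets)
    cos = np.cos(np.radians(offsets))
    dist_right = vb.height + r_right * cos
    dist_left = vb.height + r_left * cos
    rm = aligned.mean_radius
    return BacksideMetrics(
        la_back=la_back,
        ra_back=ra_back,
        backside_area_asym=area_asymmetry(la_back, ra_back),
        dist_vb_left=dist_left,
        dist_vb_right=dist_right,
        rad_back_left=r_left / rm * 100.0,
        rad_back_right=r_right / rm * 100.0,
    )


def assess_slice(
    aligned: AlignedPolarContour,
    anchors: BacksideAnchors,
    vb: VBLine,
    include_endpoints: bool = True,
) -> SliceAsymmetry:
    """Compose the full per-slice asymmetry record."""
    profile = relative_radius(aligned)
    fit_full = fit_left_right(profile, "full", include_endpoints)
    fit_back = fit_left_right(profile, anchors.separation, include_endpoints)
    ra = fan_area(aligned, (0, 180))
    la = fan_area(aligned, (-180, 0))
    back = backside_metrics(aligned, anchors, vb)
    return SliceAsymmetry(
        level_label=aligned.level_label,
        r_squared_full=fit_full.r_squared,
        r_squared_backside=fit_back.r_squared,
        slope_full=fit_full.slope,
        intercept_full=fit_full.intercept,
        la=la,
        ra=ra,
        lr_area_asym=area_asymmetry(la, ra),
        backside_area_asym=back.backside_area_asym,
        dist_vb_left=back.dist_vb_left,
        dist_vb_right=back.dist_vb_right,
        rad_back_left=back.rad_back_left,
        rad_back_right=back.rad_back_right,
        mean_radius=aligned.mean_radius,
        warnings=list(aligned.warnings),
    )
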