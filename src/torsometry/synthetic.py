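"""Parametric synthetic torsos with known ground truth.

No public scan data exist for this method, so the generator is the primary
test input.  A cross-section is a superellipse (a rounded-rectangle torso
outline) plus angular Gaussian features: a posterior dip emulating the
spinous-process groove, and one or more one-sided rib-hump bumps whose
amplitude falls off as a Gaussian of vertebral level around a chosen apex.
Optionally the 18 per-level contours are lofted into a watertight mesh (the
loft always uses the noiseless surface) so the slicing stage can be exercised
end to end.

Angles of the dip and humps are given as offsets from the posterior midline,
positive towards the right body side — i.e. directly in the aligned-frame
convention of :mod:`torsometry.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import trimesh
import yaml

from .errors import ValidationError
from .slices import (
    LEVEL_INDEX,
    LEVELS,
    LandmarkHeights,
    RawContour,
    TorsoMesh,
    VertebralLevelTable,
    interpolate_levels,
    wrap_deg,
)

_POSTERIOR = -90.0  # standard-frame angle of the posterior midline

#: Default landmark heights (mm) for a full synthetic torso.
DEFAULT_LANDMARKS = LandmarkHeights(c7=480.0, t8=330.0, l5=150.0)


@dataclass(frozen=True)
class Hump:
    """One rib-hump component: a one-sided angular bump with an axial apex."""

    amplitude: float       # mm, peak radial elevation at the apex level
    angle: float           # deg from the posterior midline, + = right side
    width: float           # deg, angular Gaussian sd
    apex_level: str = "T8"
    apex_spread: float = 2.0  # vertebral levels, axial Gaussian sd

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("hump amplitude must be >= 0")
        if self.apex_level not in LEVEL_INDEX:
            raise ValidationError(f"unknown apex level {self.apex_level!r}")
        if self.width <= 0 or self.apex_spread <= 0:
            raise ValidationError("hump width and apex_spread must be positive")

    def scale(self, level_coord: float) -> float:
        """Amplitude at a (possibly fractional) vertebral-level coordinate."""
        d = level_coord - LEVEL_INDEX[self.apex_level]
        return self.amplitude * float(np.exp(-0.5 * (d / self.apex_spread) ** 2))


@dataclass(frozen=True)
class SyntheticTorsoSpec:
    """Generator parameters and ground-truth labels for one synthetic torso."""

    base_a: float = 150.0               # lateral semi-axis, mm
    base_b: float = 100.0               # antero-posterior semi-axis, mm
    superellipse_exponent: float = 2.5  # 2 = ellipse, higher = boxier
    dip_depth: float = 8.0              # mm
    dip_width: float = 8.0              # deg, Gaussian sd
    dip_angle: float = 0.0              # deg offset of the dip from posterior midline
    hump_amplitude: float = 0.0         # mm, primary hump peak
    hump_angle: float = 40.0            # deg from posterior midline, + = right
    hump_width: float = 15.0            # deg, Gaussian sd
    apex_level: str = "T8"
    apex_spread: float = 2.0            # levels
    extra_humps: tuple[Hump, ...] = ()
    noise_sd: float = 0.0               # mm radial noise per sample point
    seed: int = 0
    n_points: int = 720

    def __post_init__(self) -> None:
        if self.base_a <= 0 or self.base_b <= 0:
            raise ValidationError("superellipse semi-axes must be positive")
        if self.dip_depth < 0 or self.hump_amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("dip depth, hump amplitude and noise sd must be >= 0")
        if self.n_points < 90:
            raise ValidationError("need n_points >= 90 samples per contour")
        if self.apex_level not in LEVEL_INDEX:
            raise ValidationError(f"unknown apex level {self.apex_level!r}")

    @property
    def humps(self) -> tuple[Hump, ...]:
        primary = ()
        if self.hump_amplitude > 0:
            primary = (
                Hump(
                    amplitude=self.hump_amplitude,
                    angle=self.hump_angle,
                    width=self.hump_width,
                    apex_level=self.apex_level,
                    apex_spread=self.apex_spread,
                ),
            )
        return primary + tuple(self.extra_humps)


@dataclass
class ContourTruth:
    """Ground truth attached to one generated contour."""

    level_label: str
    sp_angle: float            # standard-frame angle of the dip centre, deg
    hump_side: str | None      # "right", "left" or None
    hump_scales: dict[float, float]  # aligned hump angle -> amplitude at level
    la_true: float             # quadrature left fan area about the point centroid
    ra_true: float
    lr_area_asym_true: float


@dataclass
class SyntheticTorso:
    """A full generated stack: contours, truths, level table, optional mesh."""

    spec: SyntheticTorsoSpec
    level_table: VertebralLevelTable
    contours: dict[str, RawContour]
    truths: dict[str, ContourTruth]
    mesh: TorsoMesh | None = None
    arm_centers: tuple[tuple[float, float], ...] = ()


# ---------------------------------------------------------------------------
# radius model
# ---------------------------------------------------------------------------


def superellipse_radius(theta_deg, a: float, b: float, p: float):
    """Polar radius of the superellipse |x/a|^p + |y/b|^p = 1."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    return (np.abs(np.cos(t) / a) ** p + np.abs(np.sin(t) / b) ** p) ** (-1.0 / p)


def _bump(theta_deg, center_deg: float, width_deg: float):
    """Angular Gaussian bump of unit peak (wrap-aware)."""
    d = wrap_deg(np.asarray(theta_deg, dtype=float) - center_deg)
    return np.exp(-0.5 * (d / width_deg) ** 2)


def noiseless_radius(spec: SyntheticTorsoSpec, theta_deg, level_coord: float):
    """Noise-free model radius at standard-frame angles for a level coordinate."""
    r = superellipse_radius(theta_deg, spec.base_a, spec.base_b, spec.superellipse_exponent)
    if spec.dip_depth > 0:
        r = r - spec.dip_depth * _bump(theta_deg, _POSTERIOR + spec.dip_angle, spec.dip_width)
    for hump in spec.humps:
        s = hump.scale(level_coord)
        if s > 0:
            r = r + s * _bump(theta_deg, _POSTERIOR + hump.angle, hump.width)
    return r


def _truth_for(spec: SyntheticTorsoSpec, level: str) -> ContourTruth:
    """Quadrature ground truth at 0.01° resolution on the noiseless contour."""
    coord = float(LEVEL_INDEX[level])
    theta = np.arange(-180.0, 180.0, 0.01)
    r = noiseless_radius(spec, theta, coord)
    t = np.radians(theta)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    # SP axis: radius minimum about the centroid within the posterior sector
    rad = np.linalg.norm(rel, axis=1)
    post = (ang >= -150.0) & (ang <= -30.0)
    sp_axis = float(ang[post][np.argmin(rad[post])])
    offset = wrap_deg(ang - sp_axis)
    # triangle fan over consecutive fine samples, split by the side of the
    # segment midpoint relative to the SP axis
    cross = rel[:, 0] * np.roll(rel[:, 1], -1) - np.roll(rel[:, 0], -1) * rel[:, 1]
    mid = wrap_deg(offset + 0.5 * wrap_deg(np.roll(offset, -1) - offset))
    right = (mid > 0) & (mid < 180.0)
    ra = float(0.5 * np.abs(cross[right]).sum())
    la = float(0.5 * np.abs(cross[~right]).sum())
    scales = {h.angle: h.scale(coord) for h in spec.humps}
    net = sum(s * (1 if a > 0 else -1) for a, s in scales.items() if a != 0)
    side = None
    if abs(net) > 1e-9:
        side = "right" if net > 0 else "left"
    return ContourTruth(
        level_label=level,
        sp_angle=_POSTERIOR + spec.dip_angle,
        hump_side=side,
        hump_scales=scales,
        la_true=la,
        ra_true=ra,
        lr_area_asym_true=abs(la - ra) / (la + ra),
    )


def generate_contour(
    spec: SyntheticTorsoSpec, level: str = "T8", with_truth: bool = True
) -> tuple[RawContour, ContourTruth | None]:
    """Generate one contour at a vertebral level, with ground truth.

    Sample angles are uniform over [−180°, 180°) starting at −180°, so the
    sample set is symmetric about the posterior midline and, for ``n_points``
    a multiple of 360, contains the 1° analysis grid.  Radial noise is drawn
    from a per-level stream seeded by (seed, level index): contours are
    bit-identical for a fixed seed regardless of generation order.
    """
    if level not in LEVEL_INDEX:
        raise ValidationError(f"unknown vertebral level {level!r}")
    coord = float(LEVEL_INDEX[level])
    fine = np.arange(-180.0, 180.0, 0.05)
    if float(noiseless_radius(spec, fine, coord).min()) <= 0.0:
        raise ValidationError(
            "spec produces non-positive radii (dip deeper than the base contour)"
        )
    theta = -180.0 + 360.0 * np.arange(spec.n_points) / spec.n_points
    r = noiseless_radius(spec, theta, coord)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, LEVEL_INDEX[level]])
        r = r + rng.normal(0.0, spec.noise_sd, spec.n_points)
        if np.any(r <= 0):
            raise ValidationError("noise drove a contour radius below zero")
    t = np.radians(theta)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
    contour = RawContour(level_label=level, points=pts)
    truth = _truth_for(spec, level) if with_truth else None
    return contour, truth


# ---------------------------------------------------------------------------
# full torso + mesh
# ---------------------------------------------------------------------------


def _loft_mesh(
    spec: SyntheticTorsoSpec,
    table: VertebralLevelTable,
    n_rings: int,
    ring_points: int,
) -> TorsoMesh:
    heights_desc = np.asarray(table.heights)
    z_asc = heights_desc[::-1]
    idx_desc = np.arange(len(LEVELS) - 1, -1, -1, dtype=float)
    lo, hi = float(z_asc[0]) - 6.0, float(z_asc[-1]) + 6.0
    rings_z = np.linspace(lo, hi, n_rings)
    # nudge rings off exact level heights so section planes cut faces cleanly
    for i, z in enumerate(rings_z):
        if np.any(np.abs(heights_desc - z) < 1e-6):
            rings_z[i] = z + 0.05
    theta = -180.0 + 360.0 * np.arange(ring_points) / ring_points
    t = np.radians(theta)
    verts = []
    for z in rings_z:
        coord = float(np.interp(z, z_asc, idx_desc))
        r = noiseless_radius(spec, theta, coord)
        verts.append(np.column_stack([r * np.cos(t), r * np.sin(t), np.full_like(r, z)]))
    vertices = np.concatenate(verts)
    faces = []
    m = ring_points
    for k in range(n_rings - 1):
        a = k * m + np.arange(m)
        b = (a + 1) % m + k * m
        c, d = a + m, (a + 1) % m + (k + 1) * m
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    # caps: fan around an apex vertex on the axis at each end
    bottom_apex = len(vertices)
    top_apex = len(vertices) + 1
    vertices = np.concatenate(
        [vertices, [[0.0, 0.0, rings_z[0]], [0.0, 0.0, rings_z[-1]]]]
    )
    a0 = np.arange(m)
    faces.append(np.column_stack([a0, np.full(m, bottom_apex), (a0 + 1) % m]))
    at = (n_rings - 1) * m + np.arange(m)
    faces.append(
        np.column_stack([at, (at + 1) % m + (n_rings - 1) * m, np.full(m, top_apex)])
    )
    return TorsoMesh(vertices=vertices, faces=np.concatenate(faces))


def generate_torso(
    spec: SyntheticTorsoSpec,
    landmarks: LandmarkHeights = DEFAULT_LANDMARKS,
    with_mesh: bool = False,
    with_arms: bool = False,
    n_rings: int = 111,
    ring_points: int = 360,
) -> SyntheticTorso:
    """Generate all 18 per-level contours, ground truth and optionally a mesh.

    The hump amplitude follows its axial Gaussian apex profile; the lofted
    mesh interpolates the same profile continuously in height (always
    noiseless), closed by top/bottom caps so it is watertight.  ``with_arms``
    adds two detached vertical cylinders beside the torso (radius 25 mm) so
    slice extraction must pick the torso loop by largest area.
    """
    table = interpolate_levels(landmarks)
    contours: dict[str, RawContour] = {}
    truths: dict[str, ContourTruth] = {}
    for level in LEVELS:
        contour, truth = generate_contour(spec, level)
        contours[level] = contour
        truths[level] = truth
    mesh = None
    arm_centers: tuple[tuple[float, float], ...] = ()
    if with_mesh or with_arms:
        mesh = _loft_mesh(spec, table, n_rings, ring_points)
        if with_arms:
            arm_r, arm_gap = 25.0, 40.0
            cx = spec.base_a + arm_gap
            z_top = table.height_of("T3")
            z_bot = landmarks.l5 - 6.0
            tm = mesh.to_trimesh()
            parts = [tm]
            for sx in (+cx, -cx):
                cyl = trimesh.creation.cylinder(
                    radius=arm_r, height=z_top - z_bot, sections=64
                )
                cyl.apply_translation([sx, 0.0, 0.5 * (z_top + z_bot)])
                parts.append(cyl)
            merged = trimesh.util.concatenate(parts)
            mesh = TorsoMesh(vertices=np.asarray(merged.vertices), faces=np.asarray(merged.faces))
            arm_centers = ((cx, 0.0), (-cx, 0.0))
    return SyntheticTorso(
        spec=spec,
        level_table=table,
        contours=contours,
        truths=truths,
        mesh=mesh,
        arm_centers=arm_centers,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def load_preset(name: str, **overrides) -> SyntheticTorsoSpec:
    """Load a named preset spec (``healthy``, ``thoracic_t8``, ``double_t9_l2``).

    Presets are scenario templates — a healthy torso, a single thoracic-apex
    curve and a double curve — not reproductions of any patient.  Keyword
    overrides replace preset fields (e.g. ``noise_sd=0`` or ``seed=7``).
    """
    text = resources.files("torsometry.data").joinpath("presets.yaml").read_text()
    presets = yaml.safe_load(text)
    if name not in presets:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    params = dict(presets[name])
    extra = tuple(Hump(**h) for h in params.pop("extra_humps", []))
    spec = SyntheticTorsoSpec(extra_humps=extra, **params)
    if overrides:
        spec = replace(spec, **overrides)
    return spec
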