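import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import torsometry as tm
from torsometry.synthetic import superellipse_radius

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture
def circle_aligned() -> tm.AlignedPolarContour:
    """A unit-symmetric circle of radius 100 on the aligned grid."""
    return tm.AlignedPolarContour(radius=np.full(361, 100.0))


@pytest.fixture
def circle_contour() -> tm.RawContour:
    ang = np.radians(np.arange(0.0, 360.0, 1.0))
    pts = np.column_stack([100.0 * np.cos(ang), 100.0 * np.sin(ang)])
    return tm.RawContour(level_label=None, points=pts)


def make_symmetric_contour(rng: np.random.Generator) -> tm.RawContour:
    """Random mirror-symmetric contour: superellipse + posterior dip + even
    cosine perturbations about the posterior midline, sampled on a 0.5° lattice
    (a superset of the 1° analysis grid) so resampling is node-exact."""
    a = rng.uniform(120.0, 170.0)
    b = rng.uniform(85.0, 110.0)
    p = rng.uniform(2.0, 3.0)
    depth = rng.uniform(4.0, 12.0)
    width = rng.uniform(5.0, 15.0)
    theta = np.arange(-180.0, 180.0, 0.5)
    d = theta + 90.0  # offset from the posterior midline
    r = superellipse_radius(theta, a, b, p)
    r = r - depth * np.exp(-0.5 * (tm.slices.wrap_deg(d) / width) ** 2)
    for k in range(2, 6):
        r = r + rng.uniform(-3.0, 3.0) * np.cos(np.radians(k * d))
    t = np.radians(theta)
    return tm.RawContour(
        level_label=None, points=np.column_stack([r * np.cos(t), r * np.sin(t)])
    )


def run_slice(contour: tm.RawContour, config: tm.AssessmentConfig | None = None):
    from torsometry.pipeline import process_slice

    return process_slice(contour, config or tm.AssessmentConfig())
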