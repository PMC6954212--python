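from __future__ import annotations

import numpy as np
import pytest

from immunogold3d import (
    AffineTransform2D,
    Contour,
    Mark2D,
    ObservationWindow,
    PointPattern3D,
    Section,
    SectionSeries,
    fig1f_preset,
    generate_experiment,
)


@pytest.fixture(scope="session")
def fig1f_experiment():
    """Deterministic single-cell preset: 13 sections x 50 nm, sphere model."""
    cfg = fig1f_preset()
    series, truth = generate_experiment(cfg)
    return cfg, series, truth


@pytest.fixture
def unit_box():
    return ObservationWindow("box", bounds=(0.0, 1000.0, 0.0, 1000.0, 0.0, 1000.0))


@pytest.fixture
def tiny_series():
    """Hand-built two-section series with one mark and one contour."""
    tri = Contour(
        name="wall_outer", closed=True, vertices=[[0, 0], [10, 0], [0, 10]]
    )
    return SectionSeries(
        series_name="tiny",
        sections=(
            Section(index=0, contours=(tri,), marks=(Mark2D("gold", (10.0, 20.0)),)),
            Section(index=1, marks=(Mark2D("gold", (3.0, 4.0)),)),
        ),
        section_thickness=50.0,
        pixel_size=2.0,
    )


def random_pattern(rng: np.random.Generator, n: int) -> PointPattern3D:
    """Uniform points in a random box, for estimator cross-checks."""
    sides = rng.uniform(200.0, 1200.0, size=3)
    origin = rng.uniform(-500.0, 500.0, size=3)
    pts = origin + rng.uniform(size=(n, 3)) * sides
    window = ObservationWindow(
        "box",
        bounds=(
            origin[0], origin[0] + sides[0],
            origin[1], origin[1] + sides[1],
            origin[2], origin[2] + sides[2],
        ),
    )
    return PointPattern3D.from_points(pts, window)
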