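"""Independent reference implementations used only to check the package.

These are deliberately naive (double loops, direct integration) and share
no code with the production paths they verify.
"""

from __future__ import annotations

import math

import numpy as np


def k3_brute_force(points: np.ndarray, volume: float, r_grid: np.ndarray) -> np.ndarray:
    """Literal O(n^2) evaluation of the uncorrected K estimator.

    K(r) = V / (n (n-1)) * sum over ordered pairs i != j of 1(d_ij <= r).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = np.zeros(len(r_grid))
    for a, r in enumerate(r_grid):
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if math.dist(points[i], points[j]) <= r:
                    count += 1
        out[a] = volume * count / (n * (n - 1))
    return out


def ball_slab_detection_probability(
    cell_radius: float,
    center_z: float,
    n_sections: int,
    thickness: float,
    capture_depth: float,
) -> float:
    """P(an epitope uniform in a ball lies within capture_depth of a cut face).

    The z-marginal density of a uniform ball is proportional to
    R^2 - (z - zc)^2; integrate it exactly (antiderivative of a cubic) over
    the near-face strips of every slab and divide by the whole-ball mass.
    """

    def mass(a: float, b: float) -> float:
        # integral of R^2 - (z - zc)^2 over [a, b] clipped to the ball
        a = max(a, center_z - cell_radius)
        b = min(b, center_z + cell_radius)
        if b <= a:
            return 0.0

        def anti(z: float) -> float:
            u = z - center_z
            return cell_radius**2 * u - u**3 / 3.0

        return anti(b) - anti(a)

    total = mass(center_z - cell_radius, center_z + cell_radius)
    near_face = 0.0
    for i in range(n_sections):
        lo, hi = i * thickness, (i + 1) * thickness
        if 2.0 * capture_depth >= thickness:
            near_face += mass(lo, hi)
        else:
            near_face += mass(lo, lo + capture_depth)
            near_face += mass(hi - capture_depth, hi)
    return near_face / total
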