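"""Section-plane geometry of a sectioned spherical cell.

An ultrathin section cuts a roughly spherical coccal cell along a plane at
distance ``s`` from the cell centre.  A spherical shell of radius ``r``
(e.g. the cell wall) then appears in the section as a circle of in-plane
radius ``x = sqrt(r^2 - s^2)``.  Because the section is a slab of finite
thickness — and the wall itself has finite thickness — the wall signal is
smeared over an annulus; its radial extent ``D = |x2 - x1|`` is the
cell-wall blur.  The same slab geometry also controls where an
antibody-accessible epitope can sit, and the antibody complex adds a
linkage error modelled as a 40 nm uncertainty sphere around each gold
particle with a 65 nm mean displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BlurInput",
    "BlurResult",
    "LinkageSpec",
    "inplane_radius",
    "blur_extent",
    "wall_band",
    "linkage_ball",
]


def inplane_radius(r: float, s: float) -> float:
    """In-plane radius of a spherical shell of radius *r* cut at distance *s*.

    Both in nm.  Requires ``0 <= s <= r``; a plane farther from the centre
    than the shell radius misses the shell entirely.
    """
    if not r > 0:
        raise ValueError(f"shell radius must be positive, got {r}")
    if s < 0:
        raise ValueError(f"plane distance must be non-negative, got {s}")
    if s > r:
        raise ValueError(
            f"section plane outside shell (s={s} > r={r})"
        )
    return math.sqrt(r * r - s * s)


@dataclass(frozen=True)
class BlurInput:
    """Two shell/plane pairs bounding the blurred wall signal (all nm).

    ``r1, r2`` are shell radii and ``s1, s2`` the distances of the bounding
    planes from the cell centre.  Which pair corresponds to the wall's
    inner/outer surface versus the slab's top/bottom face is the caller's
    choice; the four parameters accept either assignment.
    """

    r1: float
    r2: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "s1", "s2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.s1 > self.r1 or self.s2 > self.r2:
            raise ValueError("section plane outside shell (require s_n <= r_n)")


@dataclass(frozen=True)
class BlurResult:
    x1: float
    x2: float
    D: float
    wall_estimate: float


def blur_extent(inp: BlurInput) -> BlurResult:
    """Cell-wall blur extent D = |x2 - x1| with x_n = sqrt(r_n^2 - s_n^2).

    The blur is reported as a width (absolute value); the signed in-plane
    radii are available as ``x1``/``x2``.  The average wall position is
    estimated as the midpoint of the two in-plane radii.
    """
    x1 = inplane_radius(inp.r1, inp.s1)
    x2 = inplane_radius(inp.r2, inp.s2)
    return BlurResult(x1=x1, x2=x2, D=abs(x2 - x1), wall_estimate=0.5 * (x1 + x2))


def wall_band(
    cell_center: tuple[float, float, float],
    cell_radius: float,
    wall_thickness: float,
    section_z: tuple[float, float],
) -> tuple[float, float]:
    """In-plane radial band where wall signal can appear in a section slab.

    The wall is the shell between ``cell_radius`` and
    ``cell_radius + wall_thickness``.  Over the slab ``section_z = (z_lo,
    z_hi)`` the wall's in-plane radius sweeps an annulus; the returned
    ``(inner, outer)`` radii (nm) bound it.  ``inner`` is 0 where the slab
    reaches heights at which the inner wall surface is not cut (a cap
    section), giving a filled disc rather than an annulus.
    """
    if cell_radius <= 0 or wall_thickness < 0:
        raise ValueError("cell_radius must be > 0 and wall_thickness >= 0")
    z_lo, z_hi = section_z
    if z_hi < z_lo:
        raise ValueError("section_z must be (z_lo, z_hi) with z_lo <= z_hi")
    zc = cell_center[2]
    r_out = cell_radius + wall_thickness
    if z_lo > zc + r_out or z_hi < zc - r_out:
        raise ValueError("section slab lies entirely outside the cell wall")
    # distances from the cell equator, over the part of the slab cutting the wall
    lo = max(z_lo, zc - r_out) - zc
    hi = min(z_hi, zc + r_out) - zc
    s_min = 0.0 if lo <= 0.0 <= hi else min(abs(lo), abs(hi))
    s_max = max(abs(lo), abs(hi))
    outer = inplane_radius(r_out, min(s_min, r_out))
    inner = 0.0 if s_max >= cell_radius else inplane_radius(cell_radius, s_max)
    return inner, outer


@dataclass(frozen=True)
class LinkageSpec:
    """Antibody linkage-error model.

    ``sphere_diameter`` (nm) is the diameter of the uncertainty sphere drawn
    around each gold particle; ``jitter_mean`` (nm) the mean displacement
    applied to simulated points.  The two are independent parameters;
    ``jitter_mean = 0`` disables the jitter (an idealised zero-linkage
    label, useful as a limiting case).
    """

    sphere_diameter: float = 40.0
    jitter_mean: float = 65.0

    def __post_init__(self) -> None:
        if not self.sphere_diameter > 0:
            raise ValueError("sphere_diameter must be positive")
        if self.jitter_mean < 0:
            raise ValueError("jitter_mean must be non-negative")


def linkage_ball(
    point: tuple[float, float, float], spec: LinkageSpec | None = None
) -> tuple[tuple[float, float, float], float]:
    """Uncertainty sphere for one gold particle: (centre, radius) in nm."""
    spec = spec or LinkageSpec()
    return tuple(float(c) for c in point), spec.sphere_diameter / 2.0
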