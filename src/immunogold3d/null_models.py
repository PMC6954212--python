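"""Generative null models for gold-particle patterns.

Four geometries capture the candidate subcellular distributions of a
membrane-associated protein in a coccal cell:

``csr_ball``
    complete spatial randomness — uniform in the cell volume;
``sphere``
    uniform on a spherical surface — random distribution near the wall;
``ring``
    uniform on a circle — a single ring structure;
``two_rings``
    uniform on two parallel circles — a double ring.

Every simulated point is then jittered to reflect that a gold particle only
approximates the epitope position (antibody linkage error, 65 nm mean
displacement by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .patterns import ObservationWindow, PointPattern3D

__all__ = [
    "JitterSpec",
    "NullModelSpec",
    "MODEL_KINDS",
    "EstimationError",
    "sample_null",
    "apply_jitter",
    "estimate_model_params",
    "generation_window",
]

MODEL_KINDS = ("csr_ball", "sphere", "ring", "two_rings")

# E||d|| = 2*sigma*sqrt(2/pi) for an isotropic 3D Gaussian (chi_3 mean),
# so sigma = mean / (2*sqrt(2/pi)) calibrates the mean displacement.
_CHI3_FACTOR = 2.0 * math.sqrt(2.0 / math.pi)


class EstimationError(ValueError):
    """Raised when model parameters cannot be estimated from a pattern."""


@dataclass(frozen=True)
class JitterSpec:
    """Linkage-error jitter: displacement model for simulated points.

    ``gaussian`` draws isotropic 3D Gaussian displacements with per-axis
    sd ``mean_distance / (2*sqrt(2/pi))`` so the expected displacement norm
    equals ``mean_distance``; ``fixed`` displaces by exactly
    ``mean_distance`` in a uniformly random direction.
    """

    mode: str = "gaussian"
    mean_distance: float = 65.0

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian", "fixed"):
            raise ValueError(f"unknown jitter mode {self.mode!r}")
        if self.mean_distance < 0:
            raise ValueError("mean_distance must be non-negative")

    @property
    def sigma(self) -> float:
        """Per-axis Gaussian sd implied by the mean displacement norm."""
        return self.mean_distance / _CHI3_FACTOR

    def displacements(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean_distance == 0.0 or n == 0:
            return np.zeros((n, 3))
        if self.mode == "gaussian":
            return rng.normal(0.0, self.sigma, size=(n, 3))
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return d * self.mean_distance

    def to_dict(self) -> dict:
        return {"mode": self.mode, "mean_distance": self.mean_distance}

    @classmethod
    def from_dict(cls, d: dict) -> "JitterSpec":
        return cls(**d)


@dataclass(frozen=True)
class NullModelSpec:
    """One of the four null geometries plus its jitter; determines a simulator."""

    kind: str
    radius: float
    n_points: int
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normal: tuple[float, float, float] | None = None
    separation: float | None = None
    jitter: JitterSpec = field(default_factory=JitterSpec)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected {MODEL_KINDS}")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.kind in ("ring", "two_rings"):
            normal = np.asarray(
                self.normal if self.normal is not None else (0.0, 0.0, 1.0),
                dtype=float,
            )
            nrm = np.linalg.norm(normal)
            if abs(nrm - 1.0) > 1e-9:
                raise ValueError("normal must be a unit vector (|n| = 1 +- 1e-9)")
            object.__setattr__(self, "normal", tuple(normal))
        if self.kind == "two_rings":
            if self.separation is None or not self.separation > 0:
                raise ValueError("two_rings requires separation > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    # -- geometry helpers ---------------------------------------------------

    def _plane_basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.asarray(self.normal)
        a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2, n

    def geometry_half_extent(self) -> np.ndarray:
        """Half-extent of the generating geometry along each axis (pre-jitter)."""
        if self.kind in ("csr_ball", "sphere"):
            return np.full(3, self.radius)
        n = np.abs(np.asarray(self.normal))
        ext = self.radius * np.sqrt(np.clip(1.0 - n * n, 0.0, 1.0))
        if self.kind == "two_rings":
            ext = ext + 0.5 * self.separation * n
        return ext

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "radius": self.radius,
            "n_points": self.n_points,
            "center": list(self.center),
            "jitter": self.jitter.to_dict(),
        }
        if self.normal is not None:
            d["normal"] = list(self.normal)
        if self.separation is not None:
            d["separation"] = self.separation
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NullModelSpec":
        d = dict(d)
        jitter = d.pop("jitter", None)
        kwargs = {
            **d,
            "center": tuple(d.get("center", (0.0, 0.0, 0.0))),
        }
        if "normal" in d and d["normal"] is not None:
            kwargs["normal"] = tuple(d["normal"])
        if jitter is not None:
            kwargs["jitter"] = JitterSpec.from_dict(jitter)
        return cls(**kwargs)


def generation_window(spec: NullModelSpec, min_pad: float = 1.0) -> ObservationWindow:
    """Observation window for patterns simulated from *spec*.

    The bounding box of the generating geometry, expanded on each side by
    four times the jitter mean (capturing essentially all displaced points)
    and never less than *min_pad* nm, which keeps the volume positive for
    degenerate (planar) geometries at zero jitter.
    """
    c = np.asarray(spec.center)
    half = spec.geometry_half_extent()
    pad = max(4.0 * spec.jitter.mean_distance, min_pad)
    lo, hi = c - half - pad, c + half + pad
    return ObservationWindow(
        "box", bounds=(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
    )


def sample_geometry(
    spec: NullModelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``spec.n_points`` i.i.d. points on/in the generating geometry (no jitter)."""
    n = spec.n_points
    c = np.asarray(spec.center)
    if spec.kind == "csr_ball":
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        rho = spec.radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
        return c + d * rho
    if spec.kind == "sphere":
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return c + d * spec.radius
    e1, e2, nvec = spec._plane_basis()
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    on_circle = spec.radius * (
        np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
    )
    if spec.kind == "ring":
        return c + on_circle
    side = rng.integers(0, 2, size=n) * 2 - 1  # two_rings: fair coin per point
    return c + on_circle + (0.5 * spec.separation) * side[:, None] * nvec


def sample_null(
    spec: NullModelSpec, seed: int | np.random.Generator
) -> PointPattern3D:
    """Simulate one jittered point pattern from a null-model specification.

    Points are drawn i.i.d. on the model geometry, then displaced by the
    linkage-error jitter.  The window is the generating geometry's bounding
    box expanded by four jitter means, further expanded if any displaced
    point escapes it.  Identical spec and seed give identical patterns.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = sample_geometry(spec, rng)
    window = generation_window(spec)
    pattern = PointPattern3D.from_points(base, window, labels=spec.kind)
    return apply_jitter(pattern, spec.jitter, rng)


def apply_jitter(
    pattern: PointPattern3D,
    jitter: JitterSpec,
    seed: int | np.random.Generator,
) -> PointPattern3D:
    """Displace every point by the linkage-error jitter; expand the window to fit."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    disp = jitter.displacements(pattern.n, rng)
    pts = pattern.points + disp
    window = pattern.window.expanded_to(pts)
    return PointPattern3D(pts, pattern.labels, window)


# -- parameter estimation ---------------------------------------------------

# inverse radial-CDF median of a uniform ball: median ||p - c|| = R / 2^(1/3)
_BALL_MEDIAN_FACTOR = 2.0 ** (1.0 / 3.0)


def _fit_plane_normal(centered: np.ndarray) -> np.ndarray:
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    if not np.all(np.isfinite(evals)) or evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise EstimationError(
            "degenerate covariance (collinear points): cannot fit a plane"
        )
    return evecs[:, 0]


def _fit_sphere_algebraic(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit: ||p||^2 = 2 c.p + (R^2 - ||c||^2).

    Linear in (c, k), hence exact — to machine precision — for points lying
    exactly on a sphere, which a centroid estimate of the centre is not.
    """
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r_sq = sol[3] + center @ center
    if not np.isfinite(r_sq) or r_sq <= 0:
        raise EstimationError("degenerate sphere fit (points nearly coplanar?)")
    return center, float(np.sqrt(r_sq))


def estimate_model_params(
    pattern: PointPattern3D,
    kind: str,
    jitter: JitterSpec | None = None,
) -> NullModelSpec:
    """Fit a null-model specification of the given *kind* to an observed pattern.

    ``sphere``: centre from the algebraic least-squares sphere fit, radius
    the median distance to it (exact on noiseless sphere samples).
    ``csr_ball``: centre at the centroid, radius the median distance scaled
    by 2^(1/3) — the exact inverse of the uniform-ball radial median, so a
    CSR sample recovers its own ball.  ``ring``: plane normal from the
    smallest-variance principal axis, radius the median in-plane distance.
    ``two_rings``: points split at the median projection onto that axis,
    one plane fitted exactly per group, separation the inter-plane distance
    along the common normal (exact on noiseless two-ring samples).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    n = pattern.n
    minimum = 8 if kind == "two_rings" else 4
    if n < minimum:
        raise EstimationError(f"need >= {minimum} points to fit {kind!r}, got {n}")
    jitter = jitter if jitter is not None else JitterSpec()
    pts = pattern.points
    centroid = pts.mean(axis=0)
    centered = pts - centroid

    if kind == "sphere":
        center, _ = _fit_sphere_algebraic(pts)
        radius = float(np.median(np.linalg.norm(pts - center, axis=1)))
        if radius <= 0:
            raise EstimationError("all points coincide; radius is undefined")
        return NullModelSpec(
            kind="sphere", radius=radius, n_points=n, center=tuple(center),
            jitter=jitter,
        )

    if kind == "csr_ball":
        med = float(np.median(np.linalg.norm(centered, axis=1)))
        if med <= 0:
            raise EstimationError("all points coincide; radius is undefined")
        return NullModelSpec(
            kind="csr_ball",
            radius=med * _BALL_MEDIAN_FACTOR,
            n_points=n,
            center=tuple(centroid),
            jitter=jitter,
        )

    normal = _fit_plane_normal(centered)
    proj = centered @ normal
    inplane = centered - proj[:, None] * normal

    if kind == "ring":
        radius = float(np.median(np.linalg.norm(inplane, axis=1)))
        if radius <= 0:
            raise EstimationError("in-plane radii degenerate; cannot fit a ring")
        return NullModelSpec(
            kind="ring",
            radius=radius,
            n_points=n,
            center=tuple(centroid),
            normal=tuple(normal),
            jitter=jitter,
        )

    upper = proj > np.median(proj)
    # the coin-flip ring assignment makes group sizes unequal; refine the
    # median threshold toward the midpoint of the two group means
    for _ in range(3):
        if upper.sum() < 3 or (~upper).sum() < 3:
            break
        threshold = 0.5 * (proj[upper].mean() + proj[~upper].mean())
        new_upper = proj > threshold
        if np.array_equal(new_upper, upper):
            break
        upper = new_upper
    if upper.sum() < 3 or (~upper).sum() < 3:
        raise EstimationError("cannot split points into two ring groups")
    means, normals, radii = [], [], []
    for grp in (~upper, upper):
        gpts = pts[grp]
        gmean = gpts.mean(axis=0)
        gnormal = _fit_plane_normal(gpts - gmean)
        if gnormal @ normal < 0:
            gnormal = -gnormal
        gproj = (gpts - gmean) @ gnormal
        ginplane = gpts - gmean - gproj[:, None] * gnormal
        means.append(gmean)
        normals.append(gnormal)
        radii.append(float(np.median(np.linalg.norm(ginplane, axis=1))))
    common = normals[0] + normals[1]
    common /= np.linalg.norm(common)
    separation = abs(float((means[1] - means[0]) @ common))
    if separation <= 0:
        raise EstimationError("two ring planes coincide; separation undefined")
    center = 0.5 * (means[0] + means[1])
    return NullModelSpec(
        kind="two_rings",
        radius=float(np.mean(radii)),
        n_points=n,
        center=tuple(center),
        normal=tuple(common),
        separation=separation,
        jitter=jitter,
    )
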