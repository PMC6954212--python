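"""3D Ripley's K estimation, simulation envelopes, and pattern classification.

For a stationary point process of intensity lambda, K(r) is lambda^-1 times
the expected number of further points within distance r of a typical point;
for 3D complete spatial randomness K(r) = (4/3) pi r^3.  The estimator here
is the standard pair-count form

    K_hat(r) = V / (n (n-1)) * sum_{i != j} 1(d_ij <= r) * e_ij

with e_ij = 1 (no correction) or the translation edge correction
e_ij = V / prod_k (L_k - |dx_k|) for an axis-aligned box window with sides
L_k.  An observed pattern is classified by contrasting its K_hat with
pointwise Monte-Carlo envelopes built from each candidate null model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .null_models import JitterSpec, NullModelSpec, generation_window, sample_null
from .patterns import ObservationWindow, PointPattern3D

__all__ = [
    "KEstimate",
    "Envelope",
    "ClassifySettings",
    "ClassificationReport",
    "csr_k_theoretical",
    "default_r_grid",
    "k3_estimate",
    "simulate_envelope",
    "classify_pattern",
]


def csr_k_theoretical(r: np.ndarray) -> np.ndarray:
    """K(r) of 3D complete spatial randomness: (4/3) pi r^3."""
    r = np.asarray(r, dtype=float)
    return 4.0 / 3.0 * np.pi * r**3


def default_r_grid(window: ObservationWindow, n_steps: int = 100) -> np.ndarray:
    """0 to min(shortest window side / 4, 500 nm) in *n_steps* equal steps.

    The quarter-side cap is the usual validity heuristic for edge-corrected
    K estimation; 500 nm is the coccal cell radius scale beyond which K
    carries no subcellular information.
    """
    r_max = min(window.shortest_side() / 4.0, 500.0)
    return np.linspace(0.0, r_max, n_steps + 1)


@dataclass(frozen=True)
class KEstimate:
    """Estimated K(r) (nm^3) on an increasing r-grid (nm)."""

    r_grid: np.ndarray
    k_hat: np.ndarray
    n_points: int
    window_volume: float
    correction: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_grid", np.asarray(self.r_grid, dtype=float))
        object.__setattr__(self, "k_hat", np.asarray(self.k_hat, dtype=float))


def _validate_r_grid(r_grid: np.ndarray) -> np.ndarray:
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or len(r) < 2 or np.any(np.diff(r) <= 0) or r[0] < 0:
        raise ValueError("r_grid must be 1D, increasing and non-negative")
    if r[0] > 0:
        r = np.concatenate(([0.0], r))
    return r


def k3_estimate(
    pattern: PointPattern3D,
    r_grid: np.ndarray | None = None,
    correction: str = "translation",
) -> KEstimate:
    """Estimate the 3D K function of a point pattern.

    Parameters
    ----------
    pattern
        At least two points in a window of finite volume.
    r_grid
        Increasing distances (nm); defaults to :func:`default_r_grid`.
        A grid not starting at 0 has 0 prepended so K(0) = 0 is explicit.
    correction
        ``"translation"`` (default; box windows only — pass
        ``pattern.window.enclosing_box()`` for a ball) or ``"none"``.
    """
    if correction not in ("none", "translation"):
        raise ValueError(f"unknown correction {correction!r}")
    n = pattern.n
    if n < 2:
        raise ValueError(f"K estimation requires n >= 2 points, got {n}")
    window = pattern.window
    if correction == "translation" and window.kind != "box":
        raise ValueError(
            "translation correction supports box windows only; "
            "restrict the pattern to window.enclosing_box() first"
        )
    r = _validate_r_grid(r_grid if r_grid is not None else default_r_grid(window))
    if correction == "translation" and r[-1] > window.shortest_side() + 1e-9:
        raise ValueError(
            f"max(r_grid)={r[-1]:g} exceeds the shortest window side "
            f"{window.shortest_side():g}; translation correction is invalid there"
        )
    volume = window.volume()

    pts = pattern.points
    iu, ju = np.triu_indices(n, k=1)
    diffs = pts[iu] - pts[ju]
    dists = np.linalg.norm(diffs, axis=1)
    if correction == "none":
        weights = np.ones(len(dists))
    else:
        sides = window.side_lengths()
        overlap = np.prod(sides - np.abs(diffs), axis=1)
        weights = volume / overlap
    # each unordered pair contributes twice to the sum over ordered pairs
    order = np.argsort(dists, kind="stable")
    cum = np.concatenate(([0.0], np.cumsum(2.0 * weights[order])))
    idx = np.searchsorted(dists[order], r, side="right")
    k_hat = volume / (n * (n - 1)) * cum[idx]
    return KEstimate(
        r_grid=r, k_hat=k_hat, n_points=n, window_volume=volume, correction=correction
    )


@dataclass(frozen=True)
class Envelope:
    """Pointwise simulation band for K under one null model."""

    r_grid: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    m_sims: int
    model: NullModelSpec
    correction: str = "translation"

    def contains(self, k: KEstimate, tol: float = 1e-9) -> np.ndarray:
        if len(k.r_grid) != len(self.r_grid) or not np.allclose(
            k.r_grid, self.r_grid
        ):
            raise ValueError("K estimate and envelope use different r-grids")
        return (k.k_hat >= self.lo - tol) & (k.k_hat <= self.hi + tol)

    def inside_fraction(self, k: KEstimate) -> float:
        return float(self.contains(k).mean())


def _min_sims(level: float) -> int:
    return math.ceil(2.0 / (1.0 - level) - 1.0)


def simulate_envelope(
    model: NullModelSpec,
    r_grid: np.ndarray | None = None,
    m_sims: int = 999,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    correction: str = "translation",
    window: ObservationWindow | None = None,
) -> Envelope:
    """Pointwise (1-level)/2 and (1+level)/2 quantile band of K under *model*.

    All simulated patterns are estimated on one common *window* (default:
    the model's generation window); jittered points escaping it are
    dropped, exactly as they would be for an observed pattern, keeping the
    simulations exchangeable with data restricted to the same window.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    needed = _min_sims(level)
    if m_sims < needed:
        raise ValueError(
            f"m_sims={m_sims} too few for a pointwise {level:.0%} band; "
            f"need at least {needed}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    window = (window or generation_window(model)).enclosing_box()
    r = _validate_r_grid(r_grid if r_grid is not None else default_r_grid(window))
    ks = np.empty((m_sims, len(r)))
    for i in range(m_sims):
        sim = sample_null(model, rng).restrict(window)
        ks[i] = k3_estimate(sim, r, correction).k_hat
    alpha = 1.0 - level
    lo, hi = np.quantile(ks, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    return Envelope(
        r_grid=r, lo=lo, hi=hi, level=level, m_sims=m_sims, model=model,
        correction=correction,
    )


@dataclass(frozen=True)
class ClassifySettings:
    """Envelope and comparison settings for pattern classification."""

    m_sims: int = 999
    level: float = 0.95
    r_grid: np.ndarray | None = None
    correction: str = "translation"
    seed: int = 0
    compatibility_threshold: float = 0.95


@dataclass(frozen=True)
class ClassificationReport:
    """Envelope agreement of one observed pattern against candidate models.

    ``inside_fractions`` maps model kind to the fraction of the r-grid at
    which the data K lies inside that model's band; ``best_model`` attains
    the maximum (ties broken by the order models were supplied).
    """

    inside_fractions: dict[str, float]
    best_model: str
    compatible_models: tuple[str, ...]
    settings: ClassifySettings
    n_points: int
    k_data: KEstimate
    envelopes: dict[str, Envelope]

    def to_dict(self) -> dict:
        return {
            "inside_fractions": self.inside_fractions,
            "best_model": self.best_model,
            "compatible_models": list(self.compatible_models),
            "n_points": self.n_points,
            "settings": {
                "m_sims": self.settings.m_sims,
                "level": self.settings.level,
                "correction": self.settings.correction,
                "seed": self.settings.seed,
                "compatibility_threshold": self.settings.compatibility_threshold,
                "r_max": float(self.k_data.r_grid[-1]),
                "n_r": int(len(self.k_data.r_grid)),
            },
            "models": {k: e.model.to_dict() for k, e in self.envelopes.items()},
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def classify_pattern(
    pattern: PointPattern3D,
    models: Sequence[NullModelSpec],
    settings: ClassifySettings | None = None,
) -> ClassificationReport:
    """Classify a pattern by envelope agreement across candidate null models.

    The data K is computed once on the pattern's window (its enclosing box
    under the translation correction).  Each model's envelope is built on
    that same window with the pattern's own point count, so band width is
    conditioned on n.  Supplying two models of the same kind is rejected,
    as the report keys fractions by kind.
    """
    settings = settings or ClassifySettings()
    if not models:
        raise ValueError("need at least one candidate model")
    kinds = [m.kind for m in models]
    if len(set(kinds)) != len(kinds):
        raise ValueError("candidate models must have distinct kinds")
    window = pattern.window
    if settings.correction == "translation":
        window = window.enclosing_box()
        pattern = pattern.restrict(window)
    r = _validate_r_grid(
        settings.r_grid if settings.r_grid is not None else default_r_grid(window)
    )
    k_data = k3_estimate(pattern, r, settings.correction)
    rng = np.random.default_rng(settings.seed)
    fractions: dict[str, float] = {}
    envelopes: dict[str, Envelope] = {}
    for model in models:
        spec = replace(model, n_points=pattern.n)
        env = simulate_envelope(
            spec,
            r_grid=r,
            m_sims=settings.m_sims,
            level=settings.level,
            seed=rng,
            correction=settings.correction,
            window=window,
        )
        envelopes[model.kind] = env
        fractions[model.kind] = env.inside_fraction(k_data)
    best = max(fractions, key=lambda k: fractions[k])  # first max wins ties
    compatible = tuple(
        k for k, f in fractions.items() if f >= settings.compatibility_threshold
    )
    return ClassificationReport(
        inside_fractions=fractions,
        best_model=best,
        compatible_models=compatible,
        settings=settings,
        n_points=pattern.n,
        k_data=k_data,
        envelopes=envelopes,
    )
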