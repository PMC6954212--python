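"""Point patterns and observation windows.

All world coordinates are in nanometres.  A :class:`PointPattern3D` is the
object every spatial statistic in this package operates on: an (n, 3) array
of gold-particle coordinates together with an explicit observation window,
which the K estimator needs for intensity and edge correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ObservationWindow", "PointPattern3D"]

_CONTAIN_TOL = 1e-9  # nm tolerance for boundary membership


@dataclass(frozen=True)
class ObservationWindow:
    """Bounded region within which a point pattern is observed.

    Parameters
    ----------
    kind
        ``"box"`` (axis-aligned) or ``"ball"``.
    bounds
        For a box: ``(xmin, xmax, ymin, ymax, zmin, zmax)`` in nm.
    center, radius
        For a ball: centre (nm) and radius (nm).
    """

    kind: str
    bounds: tuple[float, float, float, float, float, float] | None = None
    center: tuple[float, float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "box":
            if self.bounds is None:
                raise ValueError("box window requires bounds")
            b = np.asarray(self.bounds, dtype=float)
            if b.shape != (6,) or not np.all(np.isfinite(b)):
                raise ValueError("bounds must be 6 finite numbers")
            if not np.all(b[1::2] > b[::2]):
                raise ValueError("box sides must be positive")
            object.__setattr__(self, "bounds", tuple(b))
        elif self.kind == "ball":
            if self.center is None or self.radius is None:
                raise ValueError("ball window requires center and radius")
            if not self.radius > 0:
                raise ValueError("ball radius must be positive")
            object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        else:
            raise ValueError(f"unknown window kind {self.kind!r}")

    # -- geometry -----------------------------------------------------------

    @classmethod
    def box_around(cls, points: np.ndarray, pad: float) -> "ObservationWindow":
        """Tight axis-aligned bounding box of *points* expanded by *pad* per side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = pts.min(axis=0) - pad
        hi = pts.max(axis=0) + pad
        return cls("box", bounds=(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2]))

    def volume(self) -> float:
        if self.kind == "box":
            b = np.asarray(self.bounds)
            return float(np.prod(b[1::2] - b[::2]))
        return float(4.0 / 3.0 * np.pi * self.radius**3)

    def side_lengths(self) -> np.ndarray:
        """Box side lengths (nm); for a ball, the sides of its bounding cube."""
        if self.kind == "box":
            b = np.asarray(self.bounds)
            return b[1::2] - b[::2]
        return np.full(3, 2.0 * self.radius)

    def shortest_side(self) -> float:
        return float(self.side_lengths().min())

    def enclosing_box(self) -> "ObservationWindow":
        if self.kind == "box":
            return self
        c, r = np.asarray(self.center), self.radius
        return ObservationWindow(
            "box", bounds=(c[0] - r, c[0] + r, c[1] - r, c[1] + r, c[2] - r, c[2] + r)
        )

    def contains(self, points: np.ndarray, tol: float = _CONTAIN_TOL) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "box":
            b = np.asarray(self.bounds)
            return np.all((pts >= b[::2] - tol) & (pts <= b[1::2] + tol), axis=1)
        d = np.linalg.norm(pts - np.asarray(self.center), axis=1)
        return d <= self.radius + tol

    def expanded_to(self, points: np.ndarray) -> "ObservationWindow":
        """Smallest window of the same kind containing both self and *points*."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            return self
        if self.kind == "box":
            b = np.asarray(self.bounds)
            lo = np.minimum(b[::2], pts.min(axis=0))
            hi = np.maximum(b[1::2], pts.max(axis=0))
            return ObservationWindow(
                "box", bounds=(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])
            )
        d = np.linalg.norm(pts - np.asarray(self.center), axis=1)
        return ObservationWindow(
            "ball", center=self.center, radius=max(self.radius, float(d.max()))
        )


@dataclass(frozen=True)
class PointPattern3D:
    """Gold-particle coordinates (nm) inside an explicit observation window."""

    points: np.ndarray
    labels: tuple[str, ...]
    window: ObservationWindow

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        labels = tuple(self.labels)
        if len(labels) != len(pts):
            raise ValueError(
                f"{len(labels)} labels for {len(pts)} points (must be parallel)"
            )
        if len(pts) and not np.all(self.window.contains(pts)):
            raise ValueError("all points must lie inside the observation window")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_points(
        cls,
        points: np.ndarray,
        window: ObservationWindow,
        labels: Sequence[str] | str = "gold",
    ) -> "PointPattern3D":
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if isinstance(labels, str):
            labels = (labels,) * len(pts)
        return cls(pts, tuple(labels), window)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    def restrict(self, window: ObservationWindow) -> "PointPattern3D":
        """Drop points outside *window*; the returned pattern uses *window*."""
        keep = window.contains(self.points)
        return PointPattern3D(
            self.points[keep],
            tuple(l for l, k in zip(self.labels, keep) if k),
            window,
        )

    def translate(self, shift: Sequence[float]) -> "PointPattern3D":
        shift = np.asarray(shift, dtype=float)
        pts = self.points + shift
        if self.window.kind == "box":
            b = np.asarray(self.window.bounds)
            win = ObservationWindow(
                "box",
                bounds=tuple(
                    (b.reshape(3, 2) + shift[:, None]).reshape(-1)
                ),
            )
        else:
            win = ObservationWindow(
                "ball",
                center=tuple(np.asarray(self.window.center) + shift),
                radius=self.window.radius,
            )
        return PointPattern3D(pts, self.labels, win)
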