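"""Forward simulation of a serial-section immunogold experiment.

Generates what the wet workflow would produce — a coccal cell (~1 um
diameter) embedded in resin, cut into ~50 nm serial sections, labelled
with gold-conjugated antibodies and traced in a reconstruction tool —
entirely in silico, with ground truth, so the parser, the extraction step
and the spatial statistics are testable end to end without any micrograph.

The simulation chain: epitopes are drawn from a chosen null geometry;
each epitope falls into one section slab; it is detectable only if it lies
within ``capture_depth`` of the slab's upper or lower cut face (antibodies
reach only antigens exposed on a section surface); detectable epitopes are
labelled with probability ``labeling_prob``; the gold mark is displaced
from the epitope by the antibody linkage error.  The emitted mark carries
only its section index — as real data does — so the z quantisation error
of extraction is part of what downstream tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import section_geometry
from .null_models import JitterSpec, NullModelSpec
from .null_models import sample_geometry as _sample_geometry
from .reconstruct_io import (
    _fmt,
    Contour,
    Mark2D,
    Section,
    SectionSeries,
    write_series as write_reconstruct_xml,
)
from .section_geometry import LinkageSpec, wall_band

__all__ = [
    "ExperimentConfig",
    "GroundTruth",
    "generate_experiment",
    "write_reconstruct_xml",
    "fig1f_preset",
]

_WALL_POLY_VERTICES = 72


def _default_model() -> NullModelSpec:
    # wild-type-like: epitopes spread over a sphere just inside the wall
    return NullModelSpec(
        kind="sphere", radius=480.0, n_points=600, center=(0.0, 0.0, 525.0)
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one simulated serial-section immunogold experiment.

    Lengths in nm.  The sectioned column spans z in
    ``[0, n_sections * section_thickness]``; the cell must fit inside it
    and the model geometry inside the cell column.  ``capture_depth`` is
    the depth below a cut face within which an epitope is antibody
    accessible; ``labeling_prob`` the chance an accessible epitope
    actually receives a gold particle.
    """

    cell_center: tuple[float, float, float] = (0.0, 0.0, 525.0)
    cell_radius: float = 500.0
    wall_thickness: float = 20.0
    model: NullModelSpec = field(default_factory=_default_model)
    section_thickness: float = 50.0
    n_sections: int = 21
    capture_depth: float = 10.0
    labeling_prob: float = 0.7
    linkage: LinkageSpec = field(default_factory=LinkageSpec)
    pixel_size: float = 2.0
    seed: int = 0
    series_name: str = "synthetic_cell"

    def __post_init__(self) -> None:
        if self.n_sections < 1 or self.section_thickness <= 0:
            raise ValueError("need n_sections >= 1 and section_thickness > 0")
        if self.n_sections * self.section_thickness < 2 * self.cell_radius:
            raise ValueError(
                "sectioned column thinner than the cell: "
                f"{self.n_sections} x {self.section_thickness} nm < "
                f"2 x {self.cell_radius} nm"
            )
        if not 0.0 <= self.labeling_prob <= 1.0:
            raise ValueError("labeling_prob must be a probability")
        if not 0.0 < self.capture_depth <= self.section_thickness:
            raise ValueError("capture_depth must be in (0, section_thickness]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        z_top = self.n_sections * self.section_thickness
        c = np.asarray(self.model.center)
        half = self.model.geometry_half_extent()
        if c[2] - half[2] < -1e-9 or c[2] + half[2] > z_top + 1e-9:
            raise ValueError(
                "model geometry extends outside the sectioned volume "
                f"(z span {c[2] - half[2]:g}..{c[2] + half[2]:g} vs 0..{z_top:g})"
            )

    @property
    def jitter(self) -> JitterSpec:
        return JitterSpec(mode="gaussian", mean_distance=self.linkage.jitter_mean)


@dataclass(frozen=True)
class GroundTruth:
    """True epitope positions and the fate of each one.

    ``epitope_xyz``: all simulated epitopes (n, 3).  ``detected``: whether
    each produced a gold mark.  Per mark (in section/mark emission order):
    the source epitope index, the jitter-displaced 3D position, the
    reconstructed position implied by the mark (displaced x, y and the
    section mid-plane z — what extraction can recover), the section index
    and the cut face (``upper``/``lower``) the epitope was labelled on.
    """

    epitope_xyz: np.ndarray
    detected: np.ndarray
    epitope_index: np.ndarray
    displaced_xyz: np.ndarray
    mark_xyz: np.ndarray
    section_index: np.ndarray
    face: tuple[str, ...]

    def to_csv(self, path: str | Path) -> Path:
        import csv

        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "epitope_index", "true_x_nm", "true_y_nm", "true_z_nm",
                    "detected", "displaced_x_nm", "displaced_y_nm",
                    "displaced_z_nm", "mark_x_nm", "mark_y_nm", "mark_z_nm",
                    "section_index", "face",
                ]
            )
            by_epitope = {int(e): j for j, e in enumerate(self.epitope_index)}
            for i, p in enumerate(self.epitope_xyz):
                j = by_epitope.get(i)
                row = [i, _fmt(p[0]), _fmt(p[1]), _fmt(p[2]), int(self.detected[i])]
                if j is None:
                    row += [""] * 8
                else:
                    row += (
                        [_fmt(v) for v in self.displaced_xyz[j]]
                        + [_fmt(v) for v in self.mark_xyz[j]]
                        + [int(self.section_index[j]), self.face[j]]
                    )
                w.writerow(row)
        return path


def generate_experiment(cfg: ExperimentConfig) -> tuple[SectionSeries, GroundTruth]:
    """Run the forward simulation; returns the traced series plus ground truth.

    Reproducible: a fixed config (including its seed) always produces the
    same series and ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.section_thickness
    epitopes = _sample_geometry(cfg.model, rng)
    n = len(epitopes)

    sec_idx = np.clip((epitopes[:, 2] // t).astype(int), 0, cfg.n_sections - 1)
    dist_lower = epitopes[:, 2] - sec_idx * t
    dist_upper = (sec_idx + 1) * t - epitopes[:, 2]
    accessible = np.minimum(dist_lower, dist_upper) <= cfg.capture_depth
    labelled = accessible & (rng.uniform(size=n) < cfg.labeling_prob)

    disp = cfg.jitter.displacements(int(labelled.sum()), rng)
    epitope_index = np.flatnonzero(labelled)
    displaced = epitopes[labelled] + disp
    mark_sec = sec_idx[labelled]  # particle stays on the face it was bound to
    mark_xyz = displaced.copy()
    mark_xyz[:, 2] = (mark_sec + 0.5) * t
    face = tuple(
        "upper" if du < dl else "lower"
        for du, dl in zip(dist_upper[labelled], dist_lower[labelled])
    )

    cu = cfg.cell_center[0] / cfg.pixel_size
    cv = cfg.cell_center[1] / cfg.pixel_size
    theta = np.linspace(0.0, 2.0 * np.pi, _WALL_POLY_VERTICES, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])

    sections = []
    for i in range(cfg.n_sections):
        contours: list[Contour] = []
        try:
            inner, outer = wall_band(
                cfg.cell_center, cfg.cell_radius, cfg.wall_thickness,
                (i * t, (i + 1) * t),
            )
        except ValueError:
            inner = outer = 0.0  # slab misses the cell entirely
        for name, radius in (("wall_inner", inner), ("wall_outer", outer)):
            if radius > 0:
                verts = circle * (radius / cfg.pixel_size) + (cu, cv)
                contours.append(Contour(name=name, closed=True, vertices=verts))
        in_sec = mark_sec == i
        marks = tuple(
            Mark2D(label="gold", position=(x / cfg.pixel_size, y / cfg.pixel_size))
            for x, y in mark_xyz[in_sec, :2]
        )
        sections.append(
            Section(index=i, contours=tuple(contours), marks=marks)
        )

    # reorder mark-level ground truth to section-emission order
    order = np.argsort(mark_sec, kind="stable")
    truth = GroundTruth(
        epitope_xyz=epitopes,
        detected=labelled,
        epitope_index=epitope_index[order],
        displaced_xyz=displaced[order],
        mark_xyz=mark_xyz[order],
        section_index=mark_sec[order],
        face=tuple(face[i] for i in order),
    )
    series = SectionSeries(
        series_name=cfg.series_name,
        sections=tuple(sections),
        section_thickness=t,
        pixel_size=cfg.pixel_size,
    )
    return series, truth


def fig1f_preset(seed: int = 7) -> ExperimentConfig:
    """A single small coccal cell followed over 13 consecutive 50 nm sections.

    The whole cell fits inside the 13-section column (650 nm), so the cell
    radius is 300 nm — a small coccus — with a surface-associated
    (sphere-model) epitope distribution, matching a wild-type-like
    membrane-proximal localisation.
    """
    center = (0.0, 0.0, 13 * 50.0 / 2.0)
    return ExperimentConfig(
        cell_center=center,
        cell_radius=300.0,
        wall_thickness=20.0,
        model=NullModelSpec(
            kind="sphere", radius=280.0, n_points=600, center=center
        ),
        section_thickness=50.0,
        n_sections=13,
        seed=seed,
        series_name="fig1f_cell",
    )
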