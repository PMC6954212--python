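"""Serial-section reconstruction I/O.

Reads a documented minimal subset of the Reconstruct serial-section XML
dialect into typed objects and converts gold "stamp" marks into 3D point
clouds, taking the role of the original coordinate-extraction script.

Supported dialect
-----------------
* A series file ``NAME.ser``::

      <Series name="NAME" sectionThickness="50.0" pixelSize="2.0"
              markPrefix="gold">
        <SectionRef index="0" file="NAME.0"/>
        ...
      </Series>

  ``sectionThickness`` and ``pixelSize`` are in nm and nm/pixel.
* One file per section::

      <Section index="0">
        <Transform xcoef="0 1 0 0 0 0" ycoef="0 0 1 0 0 0">
          <Contour name="wall_outer" closed="True"
                   points="12.0 13.5, 14 15,"/>
          <Contour name="gold" closed="False" points="10 20"/>
        </Transform>
      </Section>

  ``xcoef``/``ycoef`` hold six coefficients each mapping traced to aligned
  pixel coordinates (u' = a0 + a1 u + a2 v, v' = b0 + b1 u + b2 v); any
  nonzero higher-order coefficient (index 3-5) is a non-affine transform
  and is rejected loudly, never silently truncated.  A one-vertex contour
  whose name starts with the mark prefix is a gold stamp mark; everything
  else is a traced contour.

Coordinates are right-handed: x = u * pixel_size, y = v * pixel_size, z
increasing with 0-based section index.
"""

from __future__ import annotations

import json
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patterns import ObservationWindow, PointPattern3D

__all__ = [
    "AffineTransform2D",
    "Contour",
    "Mark2D",
    "Section",
    "SectionSeries",
    "ReconstructParseError",
    "UnsupportedTransformError",
    "parse_series",
    "write_series",
    "extract_points",
    "write_points_csv",
    "read_points_csv",
    "export_model",
]

DEFAULT_MARK_PREFIX = "gold"


class ReconstructParseError(ValueError):
    """Malformed series/section XML; the message carries the element path."""


class UnsupportedTransformError(ReconstructParseError):
    """A transform outside the supported affine subset (degree > 1)."""


@dataclass(frozen=True)
class AffineTransform2D:
    """Affine map from traced to aligned pixel coordinates.

    ``u' = a[0] + a[1] u + a[2] v`` and ``v' = b[0] + b[1] u + b[2] v``.
    """

    a: tuple[float, float, float] = (0.0, 1.0, 0.0)
    b: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        det = self.a[1] * self.b[2] - self.a[2] * self.b[1]
        if det == 0.0:
            raise ValueError("transform linear part is singular (determinant 0)")

    def apply(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        u = self.a[0] + self.a[1] * uv[:, 0] + self.a[2] * uv[:, 1]
        v = self.b[0] + self.b[1] * uv[:, 0] + self.b[2] * uv[:, 1]
        return np.column_stack([u, v])

    def then_translate(self, du: float, dv: float) -> "AffineTransform2D":
        return AffineTransform2D(
            (self.a[0] + du, self.a[1], self.a[2]),
            (self.b[0] + dv, self.b[1], self.b[2]),
        )


@dataclass(frozen=True, eq=False)
class Contour:
    """A traced structure outline in pixel units (e.g. a cell-wall trace)."""

    name: str
    closed: bool
    vertices: np.ndarray  # (k, 2), pixel units

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Contour):
            return NotImplemented
        return (
            self.name == other.name
            and self.closed == other.closed
            and np.array_equal(self.vertices, other.vertices)
        )

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if v.shape[0] < 1 or v.shape[1] != 2 or not np.all(np.isfinite(v)):
            raise ValueError(f"contour {self.name!r}: vertices must be finite (k, 2)")
        if self.closed and v.shape[0] < 3:
            raise ValueError(f"closed contour {self.name!r} needs >= 3 vertices")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class Mark2D:
    """A gold-particle stamp mark in pixel units."""

    label: str
    position: tuple[float, float]

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"mark {self.label!r}: position must be finite")
        object.__setattr__(self, "position", tuple(float(c) for c in self.position))


@dataclass(frozen=True)
class Section:
    index: int
    transform: AffineTransform2D = field(default_factory=AffineTransform2D)
    contours: tuple[Contour, ...] = ()
    marks: tuple[Mark2D, ...] = ()

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("section index must be >= 0")
        object.__setattr__(self, "contours", tuple(self.contours))
        object.__setattr__(self, "marks", tuple(self.marks))


@dataclass(frozen=True)
class SectionSeries:
    """An ordered stack of sections — the parsed serial-section reconstruction."""

    series_name: str
    sections: tuple[Section, ...]
    section_thickness: float  # nm
    pixel_size: float  # nm / pixel
    mark_prefix: str = DEFAULT_MARK_PREFIX

    def __post_init__(self) -> None:
        if not self.section_thickness > 0:
            raise ValueError("section_thickness must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        secs = tuple(sorted(self.sections, key=lambda s: s.index))
        indices = [s.index for s in secs]
        if len(set(indices)) != len(indices):
            raise ValueError(f"duplicate section indices: {indices}")
        object.__setattr__(self, "sections", secs)


# -- XML parsing ------------------------------------------------------------


def _attr(elem: ET.Element, name: str, path: str) -> str:
    val = elem.get(name)
    if val is None:
        raise ReconstructParseError(f"{path}: missing attribute {name!r}")
    return val


def _parse_points_attr(text: str, path: str) -> np.ndarray:
    tokens = text.replace(",", " ").split()
    if len(tokens) == 0 or len(tokens) % 2:
        raise ReconstructParseError(
            f"{path}: points attribute needs an even number of coordinates"
        )
    try:
        vals = np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise ReconstructParseError(f"{path}: non-numeric point coordinate") from exc
    return vals.reshape(-1, 2)


def _parse_coefs(elem: ET.Element, name: str, path: str) -> tuple[float, float, float]:
    tokens = _attr(elem, name, path).split()
    if len(tokens) != 6:
        raise ReconstructParseError(f"{path}: {name} must hold 6 coefficients")
    try:
        coefs = [float(t) for t in tokens]
    except ValueError as exc:
        raise ReconstructParseError(f"{path}: non-numeric {name}") from exc
    if any(c != 0.0 for c in coefs[3:]):
        raise UnsupportedTransformError(
            f"{path}: {name} has nonzero degree-2 coefficients; "
            "only affine transforms are supported"
        )
    return coefs[0], coefs[1], coefs[2]


def _parse_section_file(path: Path, mark_prefix: str) -> Section:
    if not path.is_file():
        raise FileNotFoundError(f"section file not found: {path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ReconstructParseError(f"{path}: malformed XML ({exc})") from exc
    where = f"{path.name}/Section"
    if root.tag != "Section":
        raise ReconstructParseError(f"{where}: root element is {root.tag!r}")
    index = int(_attr(root, "index", where))
    transforms = root.findall("Transform")
    if len(transforms) > 1:
        raise ReconstructParseError(
            f"{where}: multiple Transform elements are not supported"
        )
    transform = AffineTransform2D()
    contours: list[Contour] = []
    marks: list[Mark2D] = []
    if transforms:
        telem = transforms[0]
        tpath = f"{where}/Transform"
        transform = AffineTransform2D(
            _parse_coefs(telem, "xcoef", tpath), _parse_coefs(telem, "ycoef", tpath)
        )
        for i, celem in enumerate(telem.findall("Contour")):
            cpath = f"{tpath}/Contour[{i}]"
            name = _attr(celem, "name", cpath)
            closed = _attr(celem, "closed", cpath).lower() in ("true", "1")
            pts = _parse_points_attr(_attr(celem, "points", cpath), cpath)
            if len(pts) == 1 and name.startswith(mark_prefix):
                marks.append(Mark2D(label=name, position=tuple(pts[0])))
            else:
                contours.append(Contour(name=name, closed=closed, vertices=pts))
    return Section(index=index, transform=transform, contours=tuple(contours),
                   marks=tuple(marks))


def parse_series(series_path: str | Path) -> SectionSeries:
    """Parse a series file and the section files it references.

    Raises ``FileNotFoundError`` naming any missing file,
    :class:`ReconstructParseError` with the offending element path for
    malformed XML, and :class:`UnsupportedTransformError` for non-affine
    transforms.
    """
    series_path = Path(series_path)
    if not series_path.is_file():
        raise FileNotFoundError(f"series file not found: {series_path}")
    try:
        root = ET.parse(series_path).getroot()
    except ET.ParseError as exc:
        raise ReconstructParseError(
            f"{series_path}: malformed XML ({exc})"
        ) from exc
    where = f"{series_path.name}/Series"
    if root.tag != "Series":
        raise ReconstructParseError(f"{where}: root element is {root.tag!r}")
    name = _attr(root, "name", where)
    thickness = float(_attr(root, "sectionThickness", where))
    pixel_size = float(_attr(root, "pixelSize", where))
    mark_prefix = root.get("markPrefix", DEFAULT_MARK_PREFIX)
    sections = []
    for i, ref in enumerate(root.findall("SectionRef")):
        rpath = f"{where}/SectionRef[{i}]"
        fname = _attr(ref, "file", rpath)
        sections.append(
            _parse_section_file(series_path.parent / fname, mark_prefix)
        )
    return SectionSeries(
        series_name=name,
        sections=tuple(sections),
        section_thickness=thickness,
        pixel_size=pixel_size,
        mark_prefix=mark_prefix,
    )


# -- XML writing (the dialect parse_series consumes) ------------------------


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def write_series(series: SectionSeries, out_dir: str | Path) -> Path:
    """Write a series file plus one file per section; returns the series path.

    ``parse_series(write_series(s, d))`` is the identity on the typed model
    (up to float round-trip at 17 significant digits).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ser = ET.Element(
        "Series",
        name=series.series_name,
        sectionThickness=_fmt(series.section_thickness),
        pixelSize=_fmt(series.pixel_size),
        markPrefix=series.mark_prefix,
    )
    for sec in series.sections:
        fname = f"{series.series_name}.{sec.index}"
        ET.SubElement(ser, "SectionRef", index=str(sec.index), file=fname)
        selem = ET.Element("Section", index=str(sec.index))
        telem = ET.SubElement(
            selem,
            "Transform",
            xcoef=" ".join(_fmt(c) for c in (*sec.transform.a, 0.0, 0.0, 0.0)),
            ycoef=" ".join(_fmt(c) for c in (*sec.transform.b, 0.0, 0.0, 0.0)),
        )
        for c in sec.contours:
            ET.SubElement(
                telem,
                "Contour",
                name=c.name,
                closed=str(c.closed),
                points=", ".join(f"{_fmt(u)} {_fmt(v)}" for u, v in c.vertices),
            )
        for m in sec.marks:
            ET.SubElement(
                telem,
                "Contour",
                name=m.label,
                closed="False",
                points=f"{_fmt(m.position[0])} {_fmt(m.position[1])}",
            )
        tree = ET.ElementTree(selem)
        ET.indent(tree)
        tree.write(out_dir / fname, encoding="unicode", xml_declaration=False)
    tree = ET.ElementTree(ser)
    ET.indent(tree)
    series_file = out_dir / f"{series.series_name}.ser"
    tree.write(series_file, encoding="unicode", xml_declaration=False)
    return series_file


# -- 3D coordinate extraction ----------------------------------------------


def extract_points(
    series: SectionSeries,
    label_filter: str = DEFAULT_MARK_PREFIX,
    z_convention: str = "midplane",
) -> PointPattern3D:
    """Convert stamp marks into a 3D point pattern in nm.

    Each matching mark is pushed through its section's affine transform,
    scaled by the pixel size, and given z = (index + 0.5) * thickness
    (``z_convention="midplane"``, default — a slab localises a particle
    only to the slab, and the midpoint minimises worst-case error) or
    z = index * thickness (``"top"``).  The window is the tight bounding
    box of the points expanded by one section thickness per side.
    """
    if z_convention not in ("midplane", "top"):
        raise ValueError(f"unknown z_convention {z_convention!r}")
    offset = 0.5 if z_convention == "midplane" else 0.0
    t = series.section_thickness
    coords, labels = [], []
    for sec in series.sections:
        matching = [m for m in sec.marks if m.label.startswith(label_filter)]
        if not matching:
            continue
        uv = sec.transform.apply(np.array([m.position for m in matching]))
        xy = uv * series.pixel_size
        z = (sec.index + offset) * t
        coords.append(np.column_stack([xy, np.full(len(xy), z)]))
        labels.extend(m.label for m in matching)
    if not coords:
        warnings.warn(
            f"no marks matched label filter {label_filter!r}; empty pattern",
            stacklevel=2,
        )
        window = ObservationWindow("box", bounds=(-t, t, -t, t, -t, t))
        return PointPattern3D(np.empty((0, 3)), (), window)
    pts = np.vstack(coords)
    window = ObservationWindow.box_around(pts, pad=t)
    return PointPattern3D(pts, tuple(labels), window)


# -- CSV point clouds -------------------------------------------------------

_CSV_HEADER = ["x_nm", "y_nm", "z_nm", "label"]


def write_points_csv(pattern: PointPattern3D, path: str | Path) -> Path:
    """Write ``x_nm,y_nm,z_nm,label`` rows; the window goes in a # comment."""
    import csv

    path = Path(path)
    w = pattern.window
    if w.kind == "box":
        wtext = "box " + " ".join(_fmt(b) for b in w.bounds)
    else:
        wtext = (
            "ball " + " ".join(_fmt(c) for c in w.center) + f" {_fmt(w.radius)}"
        )
    with open(path, "w", newline="") as fh:
        fh.write(f"# window: {wtext}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for p, label in zip(pattern.points, pattern.labels):
            writer.writerow([_fmt(p[0]), _fmt(p[1]), _fmt(p[2]), label])
    return path


def read_points_csv(path: str | Path) -> PointPattern3D:
    """Read a point-cloud CSV written by :func:`write_points_csv`.

    A malformed row raises :class:`ReconstructParseError` with its line
    number.  Without a window comment, the tight bounding box padded by
    50 nm (one default section thickness) is used.
    """
    import csv

    path = Path(path)
    window: ObservationWindow | None = None
    coords: list[list[float]] = []
    labels: list[str] = []
    with open(path, newline="") as fh:
        lineno = 0
        first = fh.readline()
        lineno += 1
        if first.startswith("# window:"):
            tokens = first[len("# window:"):].split()
            try:
                if tokens[0] == "box":
                    window = ObservationWindow(
                        "box", bounds=tuple(float(t) for t in tokens[1:7])
                    )
                else:
                    window = ObservationWindow(
                        "ball",
                        center=tuple(float(t) for t in tokens[1:4]),
                        radius=float(tokens[4]),
                    )
            except (ValueError, IndexError) as exc:
                raise ReconstructParseError(
                    f"{path}:{lineno}: malformed window comment"
                ) from exc
            header_line = fh.readline()
            lineno += 1
        else:
            header_line = first
        header = [h.strip() for h in header_line.strip().split(",")]
        if header != _CSV_HEADER:
            raise ReconstructParseError(
                f"{path}:{lineno}: expected header {','.join(_CSV_HEADER)}"
            )
        for row in csv.reader(fh):
            lineno += 1
            if not row:
                continue
            if len(row) != 4:
                raise ReconstructParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(row)}"
                )
            try:
                coords.append([float(row[0]), float(row[1]), float(row[2])])
            except ValueError as exc:
                raise ReconstructParseError(
                    f"{path}:{lineno}: non-numeric coordinate"
                ) from exc
            labels.append(row[3])
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if window is None:
        if len(pts) == 0:
            window = ObservationWindow("box", bounds=(-50, 50, -50, 50, -50, 50))
        else:
            window = ObservationWindow.box_around(pts, pad=50.0)
    return PointPattern3D(pts, tuple(labels), window)


# -- 3D model export --------------------------------------------------------


def export_model(
    pattern: PointPattern3D,
    path: str | Path,
    sphere_diameter: float = 40.0,
    subdivisions: int = 1,
) -> Path:
    """Export the pattern as an ASCII PLY mesh of linkage-error spheres.

    One icosphere per gold particle, radius ``sphere_diameter / 2`` —
    each sphere is the possible space of the true epitope position given
    the antibody linkage error.  A JSON sidecar ``<path>.json`` records
    the diameter and point count.
    """
    import trimesh

    if not sphere_diameter > 0:
        raise ValueError(f"sphere_diameter must be positive, got {sphere_diameter}")
    path = Path(path)
    radius = sphere_diameter / 2.0
    spheres = []
    for p in pattern.points:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        ico.apply_translation(p)
        spheres.append(ico)
    if spheres:
        mesh = trimesh.util.concatenate(spheres)
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 0\n"
            "property float x\nproperty float y\nproperty float z\n"
            "element face 0\nproperty list uchar int vertex_indices\n"
            "end_header\n"
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"sphere_diameter_nm": sphere_diameter, "n_points": pattern.n},
            indent=2,
        )
    )
    return path
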