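"""Reconstruct-dialect parsing, 3D extraction, CSV and PLY round trips."""

from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunogold3d import (
    AffineTransform2D,
    Mark2D,
    ReconstructParseError,
    Section,
    SectionSeries,
    UnsupportedTransformError,
    export_model,
    extract_points,
    parse_series,
    read_points_csv,
    write_points_csv,
    write_reconstruct_xml,
    write_series,
)


class TestParseSeries:
    def test_fig1f_fixture(self, fig1f_experiment, tmp_path):
        """The bundled single-cell preset: 13 sections of 50 nm thickness."""
        _, series, _ = fig1f_experiment
        parsed = parse_series(write_reconstruct_xml(series, tmp_path))
        assert len(parsed.sections) == 13
        assert parsed.section_thickness == 50.0
        assert parsed == series

    def test_empty_section_preserved(self, tmp_path):
        series = SectionSeries(
            "empty", (Section(index=0),), section_thickness=50.0, pixel_size=2.0
        )
        parsed = parse_series(write_series(series, tmp_path))
        assert len(parsed.sections) == 1
        assert parsed.sections[0].contours == ()
        assert parsed.sections[0].marks == ()

    def test_missing_section_file_named(self, tmp_path, tiny_series):
        f = write_series(tiny_series, tmp_path)
        (tmp_path / "tiny.1").unlink()
        with pytest.raises(FileNotFoundError, match="tiny.1"):
            parse_series(f)

    def test_missing_series_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nowhere.ser"):
            parse_series(tmp_path / "nowhere.ser")

    def test_malformed_xml_reports_file(self, tmp_path, tiny_series):
        f = write_series(tiny_series, tmp_path)
        (tmp_path / "tiny.0").write_text("<Section index='0'><oops></Section>")
        with pytest.raises(ReconstructParseError, match="tiny.0"):
            parse_series(f)

    def test_non_affine_transform_rejected(self, tmp_path, tiny_series):
        f = write_series(tiny_series, tmp_path)
        text = (tmp_path / "tiny.0").read_text()
        (tmp_path / "tiny.0").write_text(
            text.replace('xcoef="0 1 0 0 0 0"', 'xcoef="0 1 0 0.5 0 0"')
        )
        with pytest.raises(UnsupportedTransformError, match="affine"):
            parse_series(f)

    def test_sections_sorted_by_index(self, tmp_path):
        series = SectionSeries(
            "s",
            (Section(index=2), Section(index=0), Section(index=1)),
            section_thickness=50.0,
            pixel_size=1.0,
        )
        assert [s.index for s in series.sections] == [0, 1, 2]
        with pytest.raises(ValueError, match="duplicate"):
            SectionSeries(
                "d", (Section(index=1), Section(index=1)),
                section_thickness=50.0, pixel_size=1.0,
            )


class TestExtractPoints:
    def test_midplane_arithmetic(self):
        series = SectionSeries(
            "a",
            (Section(index=4, marks=(Mark2D("gold", (10.0, 20.0)),)),),
            section_thickness=50.0,
            pixel_size=2.0,
        )
        p = extract_points(series)
        assert p.points[0] == pytest.approx([20.0, 40.0, 225.0])
        p_top = extract_points(series, z_convention="top")
        assert p_top.points[0] == pytest.approx([20.0, 40.0, 200.0])

    def test_transform_translation(self):
        t = AffineTransform2D((5.0, 1.0, 0.0), (0.0, 0.0, 1.0))
        series = SectionSeries(
            "a",
            (Section(index=4, transform=t, marks=(Mark2D("gold", (10.0, 20.0)),)),),
            section_thickness=50.0,
            pixel_size=2.0,
        )
        assert extract_points(series).points[0] == pytest.approx([30.0, 40.0, 225.0])

    def test_no_matching_marks_warns_not_errors(self, tiny_series):
        with pytest.warns(UserWarning, match="no marks"):
            p = extract_points(tiny_series, label_filter="silver")
        assert p.n == 0

    def test_round_trip_matches_ground_truth(self, fig1f_experiment, tmp_path):
        """write -> parse -> extract reproduces ground truth to < 1e-6 nm."""
        _, series, truth = fig1f_experiment
        parsed = parse_series(write_reconstruct_xml(series, tmp_path))
        pattern = extract_points(parsed)
        assert pattern.n == len(truth.mark_xyz)
        assert np.abs(pattern.points - truth.mark_xyz).max() < 1e-6

    @given(
        du=st.floats(-50.0, 50.0),
        dv=st.floats(-50.0, 50.0),
        a1=st.floats(0.5, 2.0),
        b2=st.floats(0.5, 2.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_affine_equivariance(self, du, dv, a1, b2):
        """Composing a pixel translation into the transform equals translating
        the extracted pattern by pixel_size * (du, dv), to 1e-9 nm."""
        px = 2.0
        base = AffineTransform2D((1.0, a1, 0.25), (-2.0, 0.5, b2))
        marks = (Mark2D("gold", (3.0, 7.0)), Mark2D("gold", (-4.0, 1.5)))

        def series_with(t):
            return SectionSeries(
                "e", (Section(index=0, transform=t, marks=marks),),
                section_thickness=50.0, pixel_size=px,
            )

        direct = extract_points(series_with(base.then_translate(du, dv)))
        shifted = extract_points(series_with(base)).translate((du * px, dv * px, 0.0))
        assert np.abs(direct.points - shifted.points).max() < 1e-9

    def test_z_strictly_increases_with_section(self, fig1f_experiment, tmp_path):
        _, series, _ = fig1f_experiment
        pattern = extract_points(series)
        by_z = {}
        for sec in series.sections:
            if sec.marks:
                by_z[sec.index] = (sec.index + 0.5) * series.section_thickness
        zs = sorted(by_z.items())
        assert all(z1 < z2 for (_, z1), (_, z2) in zip(zs, zs[1:]))
        assert set(np.round(pattern.points[:, 2], 9)) <= {
            round(z, 9) for _, z in zs
        }


class TestPointsCsv:
    def test_empty_pattern_header_only(self, tmp_path):
        from immunogold3d import ObservationWindow, PointPattern3D

        w = ObservationWindow("box", bounds=(0, 1, 0, 1, 0, 1))
        path = write_points_csv(PointPattern3D(np.empty((0, 3)), (), w), tmp_path / "e.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[-1] == "x_nm,y_nm,z_nm,label"
        assert read_points_csv(path).n == 0

    def test_three_point_round_trip(self, tmp_path):
        from immunogold3d import ObservationWindow, PointPattern3D

        w = ObservationWindow("ball", center=(0, 0, 0), radius=10.0)
        p = PointPattern3D.from_points(
            [[1, 2, 3], [-1, 0.5, 2], [0, 0, 0]], w, labels=["a", "b", "c"]
        )
        q = read_points_csv(write_points_csv(p, tmp_path / "p.csv"))
        assert np.abs(q.points - p.points).max() <= 1e-9
        assert q.labels == p.labels
        assert q.window == p.window

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x_nm,y_nm,z_nm,label\n1,2,3,a\n1,zzz,3,b\n")
        with pytest.raises(ReconstructParseError, match="bad.csv:3"):
            read_points_csv(path)


class TestExportModel:
    def test_default_diameter_recorded_and_vertices_near_marks(self, tmp_path):
        from immunogold3d import ObservationWindow, PointPattern3D

        w = ObservationWindow("box", bounds=(-50, 50, -50, 50, -50, 50))
        p = PointPattern3D.from_points([[5.0, -3.0, 7.0]], w)
        path = export_model(p, tmp_path / "m.ply")
        meta = json.loads((tmp_path / "m.ply.json").read_text())
        assert meta["sphere_diameter_nm"] == 40.0
        header, _, body = path.read_text().partition("end_header\n")
        assert "format ascii" in header
        n_verts = int(
            next(l for l in header.splitlines() if l.startswith("element vertex")).split()[-1]
        )
        verts = np.array(
            [[float(x) for x in l.split()[:3]] for l in body.splitlines()[:n_verts]]
        )
        d = np.linalg.norm(verts - [5.0, -3.0, 7.0], axis=1)
        assert np.all(d <= 20.0 + 1e-3)  # PLY stores float32 vertices
        assert np.all(d >= 10.0)  # icosphere vertices sit near the radius

    def test_empty_pattern_valid_mesh(self, tmp_path):
        from immunogold3d import ObservationWindow, PointPattern3D

        w = ObservationWindow("box", bounds=(0, 1, 0, 1, 0, 1))
        path = export_model(PointPattern3D(np.empty((0, 3)), (), w), tmp_path / "e.ply")
        assert "element vertex 0" in path.read_text()

    def test_zero_diameter_rejected(self, tmp_path):
        from immunogold3d import ObservationWindow, PointPattern3D

        w = ObservationWindow("box", bounds=(0, 1, 0, 1, 0, 1))
        p = PointPattern3D.from_points([[0.5, 0.5, 0.5]], w)
        with pytest.raises(ValueError, match="sphere_diameter"):
            export_model(p, tmp_path / "z.ply", sphere_diameter=0.0)
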