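"""K estimator correctness, envelope construction, and classification logic."""

from __future__ import annotations

import numpy as np
import pytest

from immunogold3d import (
    ClassifySettings,
    JitterSpec,
    NullModelSpec,
    ObservationWindow,
    PointPattern3D,
    classify_pattern,
    csr_k_theoretical,
    default_r_grid,
    k3_estimate,
    sample_null,
    simulate_envelope,
)

from _oracles import k3_brute_force


def box_pattern(points, bounds):
    return PointPattern3D.from_points(
        points, ObservationWindow("box", bounds=bounds)
    )


class TestK3Estimate:
    def test_two_points_hand_computed(self):
        """n=2 at distance 10: sum over ordered pairs is 2, so K = V for r >= 10."""
        p = box_pattern([[0, 0, 0], [10, 0, 0]], (-20, 30, -25, 25, -25, 25))
        volume = 50.0**3
        k = k3_estimate(p, r_grid=np.array([0.0, 5.0, 10.0, 15.0]), correction="none")
        assert k.k_hat == pytest.approx([0.0, 0.0, volume, volume])

    def test_zero_below_minimum_interpoint_distance(self):
        rng = np.random.default_rng(0)
        p = box_pattern(rng.uniform(0, 1000, (30, 3)), (0, 1000, 0, 1000, 0, 1000))
        from scipy.spatial.distance import pdist

        d_min = pdist(p.points).min()
        k = k3_estimate(p, r_grid=np.array([0.0, d_min * 0.99]), correction="none")
        assert np.all(k.k_hat == 0.0)

    def test_matches_brute_force_oracle(self):
        """Vectorised estimator equals a literal double-loop evaluation."""
        from conftest import random_pattern

        rng = np.random.default_rng(42)
        for _ in range(50):
            p = random_pattern(rng, int(rng.integers(5, 20)))
            r = np.linspace(0.0, p.window.shortest_side() / 2.0, 8)
            k = k3_estimate(p, r_grid=r, correction="none")
            expected = k3_brute_force(p.points, p.window.volume(), r)
            assert np.allclose(k.k_hat, expected, rtol=1e-12, atol=1e-9)

    def test_translation_correction_dominates_uncorrected(self):
        """Translation weights e_ij >= 1, so corrected K >= uncorrected K."""
        from conftest import random_pattern

        rng = np.random.default_rng(7)
        for _ in range(10):
            p = random_pattern(rng, 40)
            r = np.linspace(0.0, p.window.shortest_side() / 4.0, 20)
            k_t = k3_estimate(p, r_grid=r, correction="translation").k_hat
            k_n = k3_estimate(p, r_grid=r, correction="none").k_hat
            assert np.all(k_t >= k_n - 1e-9)

    def test_k_nondecreasing_and_zero_at_origin(self):
        p = sample_null(
            NullModelSpec(kind="csr_ball", radius=400.0, n_points=100), seed=3
        ).restrict(
            ObservationWindow("box", bounds=(-700, 700, -700, 700, -700, 700))
        )
        k = k3_estimate(p)
        assert k.k_hat[0] == 0.0
        assert np.all(np.diff(k.k_hat) >= 0.0)

    def test_csr_closed_form(self):
        """Mean corrected K over CSR-in-box simulations tracks (4/3) pi r^3.

        Checked for 50 nm <= r <= side/4; below ~50 nm the Monte-Carlo error
        of 500 simulations at n=200 exceeds a 5% band (too few close pairs).
        """
        rng = np.random.default_rng(11)
        side = 1000.0
        r = np.linspace(0.0, side / 4.0, 26)
        ks = []
        for _ in range(500):
            p = box_pattern(rng.uniform(0, side, (200, 3)), (0, side, 0, side, 0, side))
            ks.append(k3_estimate(p, r_grid=r, correction="translation").k_hat)
        mean_k = np.mean(ks, axis=0)
        theory = csr_k_theoretical(r)
        sel = r >= 50.0
        assert np.all(np.abs(mean_k[sel] / theory[sel] - 1.0) < 0.05)

    def test_preconditions(self):
        w = ObservationWindow("box", bounds=(0, 100, 0, 100, 0, 100))
        with pytest.raises(ValueError, match="n >= 2"):
            k3_estimate(PointPattern3D.from_points([[1, 1, 1]], w))
        ball = PointPattern3D.from_points(
            [[0, 0, 0], [1, 1, 1]],
            ObservationWindow("ball", center=(0, 0, 0), radius=10.0),
        )
        with pytest.raises(ValueError, match="box windows"):
            k3_estimate(ball, correction="translation")
        p = box_pattern([[1, 1, 1], [2, 2, 2]], (0, 100, 0, 100, 0, 100))
        with pytest.raises(ValueError, match="shortest window side"):
            k3_estimate(p, r_grid=np.array([0.0, 200.0]), correction="translation")


class TestEnvelope:
    SPEC = NullModelSpec(kind="csr_ball", radius=300.0, n_points=60,
                         jitter=JitterSpec(mean_distance=0.0))

    def test_too_few_sims_rejected_naming_minimum(self):
        with pytest.raises(ValueError, match="39"):
            simulate_envelope(self.SPEC, m_sims=1, level=0.95, seed=0)

    def test_band_ordering_and_determinism(self):
        a = simulate_envelope(self.SPEC, m_sims=49, seed=5)
        b = simulate_envelope(self.SPEC, m_sims=49, seed=5)
        assert np.all(a.lo <= a.hi)
        assert np.array_equal(a.lo, b.lo) and np.array_equal(a.hi, b.hi)

    def test_mismatched_grid_rejected(self):
        env = simulate_envelope(self.SPEC, m_sims=49, seed=1)
        k = k3_estimate(
            sample_null(self.SPEC, 2).restrict(env_window(env)), np.linspace(0, 50, 4)
        )
        with pytest.raises(ValueError, match="r-grids"):
            env.contains(k)


def env_window(env):
    from immunogold3d import generation_window

    return generation_window(env.model)


class TestClassifyPattern:
    def test_single_model_is_best_regardless_of_fraction(self):
        spec = NullModelSpec(kind="sphere", radius=300.0, n_points=80)
        ring = NullModelSpec(kind="ring", radius=300.0, n_points=80)
        pattern = sample_null(spec, seed=1)
        report = classify_pattern(pattern, [ring], ClassifySettings(m_sims=39, seed=0))
        assert report.best_model == "ring"

    def test_duplicate_kinds_rejected(self):
        spec = NullModelSpec(kind="sphere", radius=300.0, n_points=80)
        with pytest.raises(ValueError, match="distinct"):
            classify_pattern(sample_null(spec, 1), [spec, spec])

    def test_report_json_provenance(self):
        spec = NullModelSpec(kind="sphere", radius=300.0, n_points=60)
        report = classify_pattern(
            sample_null(spec, seed=2), [spec], ClassifySettings(m_sims=39, seed=17)
        )
        d = report.to_dict()
        assert d["settings"]["seed"] == 17
        assert d["settings"]["m_sims"] == 39
        assert d["settings"]["level"] == 0.95
        assert set(d["inside_fractions"]) == {"sphere"}
        assert 0.0 <= d["inside_fractions"]["sphere"] <= 1.0

    def test_determinism_identical_reports(self):
        spec = NullModelSpec(kind="sphere", radius=300.0, n_points=60)
        pattern = sample_null(spec, seed=3)
        settings = ClassifySettings(m_sims=39, seed=4)
        a = classify_pattern(pattern, [spec], settings)
        b = classify_pattern(pattern, [spec], settings)
        assert a.to_json() == b.to_json()

    def test_errors_propagate_from_k_estimation(self):
        spec = NullModelSpec(kind="sphere", radius=300.0, n_points=1)
        pattern = sample_null(spec, seed=5)
        with pytest.raises(ValueError, match="n >= 2"):
            classify_pattern(pattern, [spec], ClassifySettings(m_sims=39))
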