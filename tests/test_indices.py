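"""Hemodynamic index formulas on constructed and analytic fields."""

import numpy as np
import pandas as pd
import pytest

import hemoflow as hf
from conftest import make_wall


class TestOSI:
    def test_unidirectional_zero(self):
        rng = np.random.default_rng(0)
        wall = make_wall(rng.uniform(0.5, 3.0, size=(64, 7)))
        assert np.allclose(hf.compute_osi(wall), 0.0)

    def test_fully_oscillatory_half(self):
        ess = np.concatenate([np.full((32, 5), 2.0), np.full((32, 5), -2.0)])
        assert np.allclose(hf.compute_osi(make_wall(ess)), 0.5)

    def test_partial_reversal_one_third(self):
        # +2 Pa half cycle, -1 Pa half cycle: 0.5 (1 - |2-1|/(2+1)) = 1/3
        ess = np.concatenate([np.full((32, 3), 2.0), np.full((32, 3), -1.0)])
        assert np.allclose(hf.compute_osi(make_wall(ess)), 1.0 / 3.0)

    def test_stagnant_point_defined_zero(self):
        wall = make_wall(np.zeros((16, 2)))
        assert np.allclose(hf.compute_osi(wall), 0.0)

    def test_bounds_on_random_fields(self):
        rng = np.random.default_rng(3)
        osi = hf.compute_osi(make_wall(rng.standard_normal((64, 40))))
        assert np.all(osi >= 0.0) and np.all(osi <= 0.5)


class TestTimeAverage:
    def test_constant(self):
        assert np.allclose(hf.time_average_ess(make_wall(np.full((10, 4), 1.7))), 1.7)

    def test_two_level(self):
        ess = np.concatenate([np.full((32, 2), 3.0), np.full((32, 2), 1.0)])
        assert np.allclose(hf.time_average_ess(make_wall(ess)), 2.0)

    def test_sinusoid_exact_at_64_samples(self):
        t = np.arange(64) / 64.0
        series = 1.5 + 0.5 * np.sin(2 * np.pi * t)
        ta = hf.time_average_ess(make_wall(series[:, None]))
        # uniform periodic sampling integrates pure harmonics exactly
        assert ta[0] == pytest.approx(1.5, rel=1e-9)


class TestESSG:
    def test_uniform_zero(self):
        assert np.allclose(hf.compute_essg(make_wall(np.full((4, 9), 2.0))), 0.0)

    def test_linear_ramp(self):
        s = np.arange(9, dtype=float)
        wall = make_wall((0.25 * s)[None, :], s=s)
        g = hf.compute_essg(wall) * 1000.0  # back to Pa/m
        assert np.allclose(g, 0.25)

    def test_quadratic_exact_central(self):
        s = np.arange(9, dtype=float)
        wall = make_wall((s ** 2)[None, :], s=s)
        g = hf.compute_essg(wall) * 1000.0
        assert np.allclose(g[1:-1], 2.0 * s[1:-1])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            hf.compute_essg(make_wall(np.ones((2, 2))))


class TestNormalizedESS:
    def test_simple_series(self):
        wall = make_wall(np.array([[1.0], [2.0], [4.0]]))
        assert np.allclose(hf.normalize_ess(wall).ravel(), [0.25, 0.5, 1.0])

    def test_constant_series(self):
        assert np.allclose(hf.normalize_ess(make_wall(np.full((5, 3), 2.2))), 1.0)

    def test_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(1)
        ess = rng.uniform(0.1, 5.0, size=(16, 8))
        n1 = hf.normalize_ess(make_wall(ess))
        n2 = hf.normalize_ess(make_wall(17.3 * ess))
        assert np.allclose(n1, n2)
        assert np.all((n1 >= 0) & (n1 <= 1))
        assert np.allclose(n1.max(axis=0), 1.0)

    def test_zero_point_defined_zero(self):
        ess = np.zeros((4, 2))
        ess[:, 1] = 1.0
        out = hf.normalize_ess(make_wall(ess))
        assert np.allclose(out[:, 0], 0.0)


class TestLowESSArea:
    def test_uniform_fields(self):
        assert hf.low_ess_area_fraction(make_wall(np.full((3, 6), 0.5))) == 100.0
        assert hf.low_ess_area_fraction(make_wall(np.full((3, 6), 2.0))) == 0.0

    def test_half_half_by_area(self):
        ess = np.array([[0.5, 0.5, 1.5, 1.5]])
        assert hf.low_ess_area_fraction(make_wall(ess)) == pytest.approx(50.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        wall = make_wall(rng.uniform(0.0, 3.0, size=(8, 50)))
        fracs = [hf.low_ess_area_fraction(wall, threshold=th)
                 for th in (0.5, 1.0, 1.5, 2.5)]
        assert np.all(np.diff(fracs) >= 0)


class TestSegmentStats:
    def test_median_iqr_convention(self):
        vals = np.array([[1.0, 2, 3, 4, 5] * 4])
        seg = np.repeat([1, 2, 3, 4], 5)
        wall = make_wall(vals, segment=seg)
        tab = hf.segment_stats(wall)
        assert tab.loc[1, "median"] == pytest.approx(3.0)
        assert tab.loc[1, "iqr"] == pytest.approx(2.0)

    def test_constant_segment_zero_iqr(self):
        wall = make_wall(np.full((2, 8), 0.6618), segment=np.repeat([1, 2, 3, 4], 2))
        assert np.allclose(hf.segment_stats(wall)["iqr"], 0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 2, size=20)
        seg = np.repeat([1, 2, 3, 4], 5)
        w1 = make_wall(vals[None, :], segment=seg)
        perm = rng.permutation(20)
        w2 = make_wall(vals[perm][None, :], segment=seg[perm])
        pd.testing.assert_frame_equal(hf.segment_stats(w1), hf.segment_stats(w2))

    def test_missing_labels_raise(self):
        with pytest.raises(ValueError):
            hf.segment_stats(make_wall(np.ones((2, 4))))


class TestOnAnalyticFields:
    def test_poiseuille_ess_value(self, poiseuille_flow):
        # tau_w = 32 mu Q / (pi D^3) = 1.096 Pa at every wall point
        ess = hf.compute_ess(poiseuille_flow)
        assert np.allclose(ess, 1.0959, rtol=2e-3)

    def test_poiseuille_linearity(self):
        e1 = hf.compute_ess(hf.poiseuille_fixture(Q=0.83e-6))
        e2 = hf.compute_ess(hf.poiseuille_fixture(Q=1.66e-6))
        assert np.allclose(e2, 2.0 * e1, rtol=1e-9)

    def test_poiseuille_osi_zero(self, poiseuille_flow):
        wall = hf.compute_wall_field(poiseuille_flow)
        assert np.allclose(hf.compute_osi(wall), 0.0)

    def test_newtonian_lbv_unity(self, poiseuille_flow):
        s = hf.lbv_summary(poiseuille_flow)
        assert s["mean_lbv"] == pytest.approx(1.0)
        assert s["peak_lbv"] == pytest.approx(1.0)

    def test_uniform_viscosity_ratio(self, poiseuille_flow):
        flow = hf.poiseuille_fixture(mu=0.0035)
        flow.mu[...] = 0.00507
        flow.rheology = hf.RheologyParams(model="quemada")
        s = hf.lbv_summary(flow)
        assert s["mean_lbv"] == pytest.approx(0.00507 / 0.0035)

    def test_translation_invariance(self, poiseuille_flow):
        wall = hf.compute_wall_field(poiseuille_flow)
        ta1 = hf.time_average_ess(wall)
        osi1 = hf.compute_osi(wall)
        flow2 = hf.poiseuille_fixture()
        flow2.x = flow2.x + 0.05  # rigid axial translation
        flow2.geometry.x = flow2.geometry.x + 0.05
        wall2 = hf.compute_wall_field(flow2)
        assert np.allclose(hf.time_average_ess(wall2), ta1)
        assert np.allclose(hf.compute_osi(wall2), osi1)
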