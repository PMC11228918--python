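"""Cluster occupancy, growth rates, regime diagnostics, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prenuc.growth import (
    SALICYLAMIDE,
    RegimeThresholds,
    SizeSeries,
    SolutionSpec,
    interpolate_size,
    normalize_saturation,
    nsmc,
    nsmc_rate,
    regime_statistics,
    saturation_label,
)
from prenuc.synth import GrowthSimSpec, gen_growth_series, growth_closed_form_radius

SOL = SolutionSpec(solvent="synthetic", x_mol_l=1.0, x_star_mol_l=1.0)


class TestNsmc:
    def test_empty_cluster(self):
        assert nsmc(0.0, SALICYLAMIDE) == 0.0

    def test_single_molecule_sphere(self):
        d1 = (6 * 0.169 / np.pi) ** (1 / 3)  # sphere holding exactly one molecule
        assert d1 == pytest.approx(0.686, abs=1e-3)
        assert nsmc(d1, SALICYLAMIDE) == pytest.approx(1.0, rel=1e-12)

    def test_400nm_occupancy(self):
        expected = (np.pi / 6) * 400.0**3 / 0.169  # independent arithmetic
        value = nsmc(400.0, SALICYLAMIDE)
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(1.98e8, rel=0.01)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            nsmc(-1.0, SALICYLAMIDE)

    @given(st.floats(min_value=0.1, max_value=1e4))
    @settings(max_examples=50, derandomize=True)
    def test_cubic_scaling(self, d):
        assert nsmc(2 * d, SALICYLAMIDE) == pytest.approx(8 * nsmc(d, SALICYLAMIDE), rel=1e-9)


class TestNsmcRate:
    def test_constant_series_zero_rate(self):
        s = SizeSeries(SOL, np.arange(1.0, 6.0), np.full(5, 300.0))
        _, rate = nsmc_rate(s, SALICYLAMIDE)
        assert np.all(rate == 0)

    def test_two_point_hand_computation(self):
        # diameters chosen so occupancy goes 1 -> 1001 over one hour
        v = SALICYLAMIDE.molecular_volume_nm3
        d_a = (6 * v / np.pi) ** (1 / 3)
        d_b = (6 * 1001 * v / np.pi) ** (1 / 3)
        s = SizeSeries(SOL, np.array([0.001, 1.001]), np.array([d_a, d_b]))
        t_mid, rate = nsmc_rate(s, SALICYLAMIDE)
        assert rate[0] == pytest.approx(1000.0, rel=1e-9)
        assert t_mid[0] == pytest.approx(0.501)

    def test_linear_occupancy_gives_constant_rate(self):
        v = SALICYLAMIDE.molecular_volume_nm3
        t = np.linspace(1, 10, 10)
        n = 1e6 + 5e4 * t
        d = (6 * v * n / np.pi) ** (1 / 3)
        s = SizeSeries(SOL, t, d)
        _, rate = nsmc_rate(s, SALICYLAMIDE)
        assert np.allclose(rate, 5e4, rtol=1e-8)

    def test_telescoping_conservation(self, rng):
        t = np.sort(rng.uniform(1, 72, 15))
        d = rng.uniform(100, 2000, 15)
        s = SizeSeries(SOL, t, d)
        _, rate = nsmc_rate(s, SALICYLAMIDE)
        n = nsmc(d, SALICYLAMIDE)
        assert np.sum(rate * np.diff(t)) == pytest.approx(n[-1] - n[0], rel=1e-12)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            SizeSeries(SOL, np.array([1.0, 1.0, 2.0]), np.array([10.0, 11.0, 12.0]))


class TestRegimeDiagnostic:
    @pytest.mark.parametrize("regime", ["diffusion", "interface_transfer"])
    def test_noise_free_classification(self, regime):
        res = gen_growth_series(GrowthSimSpec(regime=regime, noise_sigma=0.0))
        out = regime_statistics(res.series, SALICYLAMIDE)
        assert out.classification == regime
        flat = out.trend_diff if regime == "diffusion" else out.trend_int
        steep = out.trend_int if regime == "diffusion" else out.trend_diff
        assert abs(flat) < 0.01
        assert abs(steep) > 0.5

    def test_diffusion_q_int_decreases(self):
        res = gen_growth_series(GrowthSimSpec(regime="diffusion", noise_sigma=0.0))
        out = regime_statistics(res.series, SALICYLAMIDE)
        assert out.trend_int < 0

    def test_interface_q_diff_increases(self):
        res = gen_growth_series(GrowthSimSpec(regime="interface_transfer", noise_sigma=0.0))
        out = regime_statistics(res.series, SALICYLAMIDE)
        assert out.trend_diff > 0

    def test_constant_series_indeterminate(self):
        s = SizeSeries(SOL, np.arange(1.0, 11.0), np.full(10, 500.0))
        out = regime_statistics(s, SALICYLAMIDE)
        assert out.classification == "indeterminate"
        assert np.all(out.q_diff == 0) and np.all(out.q_int == 0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            s = SizeSeries(SOL, np.arange(1.0, 6.0), np.array([1, 2, np.nan, 4, 5.0]))
            regime_statistics(s, SALICYLAMIDE)

    def test_series_lengths(self):
        res = gen_growth_series(GrowthSimSpec(regime="diffusion", seed=7))
        out = regime_statistics(res.series, SALICYLAMIDE)
        n = res.series.times_h.size
        assert out.q_diff.size == out.q_int.size == n - 1

    def test_thresholds_configurable(self):
        res = gen_growth_series(GrowthSimSpec(regime="diffusion", noise_sigma=0.0))
        strict = RegimeThresholds(flat_threshold=1e-6, margin=1e-9)
        out = regime_statistics(res.series, SALICYLAMIDE, strict)
        assert out.classification == "indeterminate"


class TestGrowthGenerator:
    @pytest.mark.parametrize("regime", ["diffusion", "interface_transfer"])
    def test_integrator_matches_closed_form(self, regime):
        spec = GrowthSimSpec(regime=regime, noise_sigma=0.0)
        res = gen_growth_series(spec)
        r_exact = growth_closed_form_radius(spec, res.series.times_h)
        assert np.allclose(res.series.diameters_nm / 2, r_exact, rtol=1e-6)

    def test_determinism(self):
        a = gen_growth_series(GrowthSimSpec(regime="diffusion", seed=42))
        b = gen_growth_series(GrowthSimSpec(regime="diffusion", seed=42))
        assert np.array_equal(a.series.diameters_nm, b.series.diameters_nm)

    def test_truth_embedded(self):
        res = gen_growth_series(GrowthSimSpec(regime="interface_transfer", seed=3))
        assert res.truth["regime"] == "interface_transfer"
        assert "clean_diameters_nm" in res.truth


class TestSaturation:
    def test_saturated_is_one(self):
        assert normalize_saturation(SolutionSpec("s", 0.5, 0.5)) == 1.0

    def test_ratio(self):
        assert normalize_saturation(SolutionSpec("s", 0.666, 0.6)) == pytest.approx(1.11)

    def test_labels(self):
        assert saturation_label(0.9) == "undersaturated"
        assert saturation_label(1.0) == "saturated"
        assert saturation_label(1.2) == "supersaturated"

    def test_zero_solubility_rejected(self):
        with pytest.raises(ValueError):
            SolutionSpec("s", 1.0, 0.0)


class TestInterpolateSize:
    def test_midpoint(self):
        d, flag = interpolate_size([(1.0, 100.0), (1.1, 200.0)], 1.05)
        assert d == pytest.approx(150.0)
        assert flag is False

    def test_identity_at_node(self):
        d, _ = interpolate_size([(1.0, 100.0), (1.1, 200.0), (1.2, 500.0)], 1.1)
        assert d == 200.0

    def test_two_point_linear_rule(self):
        # hand interpolation between (1.02, 1439) and (1.07, 2807) at 1.05
        d, _ = interpolate_size([(1.02, 1439.0), (1.07, 2807.0)], 1.05)
        assert d == pytest.approx(1439 + (2807 - 1439) * 0.03 / 0.05, rel=1e-12)
        assert d == pytest.approx(2259.8, abs=0.1)

    def test_order_invariance(self):
        pts = [(1.1, 200.0), (1.0, 100.0), (1.3, 50.0)]
        d1, _ = interpolate_size(pts, 1.05)
        d2, _ = interpolate_size(list(reversed(pts)), 1.05)
        assert d1 == d2

    def test_extrapolation_flagged(self):
        d, flag = interpolate_size([(1.0, 100.0), (1.1, 200.0)], 1.2)
        assert flag is True
        assert d == pytest.approx(300.0)

    def test_duplicate_s_rejected(self):
        with pytest.raises(ValueError):
            interpolate_size([(1.0, 100.0), (1.0, 150.0)], 1.0)

    @given(
        st.floats(min_value=-50, max_value=50),
        st.floats(min_value=1, max_value=100),
        st.floats(min_value=1.0, max_value=1.2),
    )
    @settings(max_examples=50, derandomize=True)
    def test_exact_on_affine_data(self, slope, intercept, target):
        pts = [(s, slope * s + intercept) for s in (0.9, 1.0, 1.1, 1.25)]
        d, _ = interpolate_size(pts, target)
        assert d == pytest.approx(slope * target + intercept, rel=1e-9, abs=1e-9)
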