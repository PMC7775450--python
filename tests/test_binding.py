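"""Condensation-gated binding model: simulation, normalization, slopes, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycobind.binding import (BindingModelParams, ChainGeometry,
                               DoseBindingCurve, available_site_fraction,
                               cooperativity_index, estimate_chain_length,
                               fit_condensation_model, initial_slope,
                               mean_binding_curve, normalize_curve,
                               simulate_binding_curve)

T24 = BindingModelParams(xi0=4.2, c_star=2.6e11, b_max=100.0,
                         slope_high=2.772e-10)


def euler_binding_oracle(concentrations, params, n_steps=200_000):
    """Brute-force accumulation dB = slope * f(c) * (1 - B/b_max) dc."""
    cmax = max(concentrations)
    grid = np.linspace(0.0, cmax, n_steps)
    dc = grid[1] - grid[0]
    f = available_site_fraction(grid, params)
    b = np.empty_like(grid)
    b[0] = 0.0
    for i in range(1, grid.size):
        b[i] = b[i - 1] + params.slope_high * f[i - 1] \
            * (1.0 - b[i - 1] / params.b_max) * dc
    return np.interp(concentrations, grid, b)


class TestAvailableSiteFraction:
    def test_low_dose_limit(self):
        assert available_site_fraction(0.0, T24) == pytest.approx(1 / 4.2)
        assert available_site_fraction(T24.c_star * 1e-4, T24) \
            == pytest.approx(1 / 4.2, rel=1e-3)

    def test_subcritical_charge_density_is_unity(self):
        p = BindingModelParams(xi0=0.9, c_star=1e11)
        c = np.logspace(9, 13, 20)
        assert np.all(available_site_fraction(c, p) == 1.0)

    def test_geometric_midpoint_at_c_star(self):
        assert available_site_fraction(T24.c_star, T24) \
            == pytest.approx(1 / np.sqrt(4.2))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            available_site_fraction(-1.0, T24)

    @given(seed=st.integers(0, 100))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_monotone_in_c_and_antitone_in_xi0(self, seed):
        rng = np.random.default_rng(seed)
        xi0 = rng.uniform(1.1, 10.0)
        p = BindingModelParams(xi0=xi0, c_star=10 ** rng.uniform(10, 12))
        c = np.logspace(9, 13, 50)
        f = available_site_fraction(c, p)
        assert np.all(np.diff(f) >= -1e-12)
        p_hi = BindingModelParams(xi0=xi0 + 1.0, c_star=p.c_star)
        assert np.all(available_site_fraction(c, p_hi) <= f + 1e-12)


class TestSimulateBindingCurve:
    def test_linear_taylor_limit(self):
        p = BindingModelParams(xi0=0.5, c_star=1e11, b_max=1e6,
                               slope_high=1e-10)
        c = np.array([1e9, 5e9, 1e10])
        curve = simulate_binding_curve(p, c, noise_cv=0.0)
        assert curve.signal == pytest.approx(p.slope_high * c, rel=1e-3)

    def test_saturation_limit(self):
        c = np.array([1e14, 5e14])
        curve = simulate_binding_curve(T24, c, noise_cv=0.0)
        assert curve.signal == pytest.approx([100.0, 100.0], rel=1e-3)

    def test_two_regime_slopes_against_euler_oracle(self):
        """Closed-form mean agrees with brute-force Euler accumulation."""
        c = np.logspace(10, 12.2, 15)
        closed = mean_binding_curve(c, T24)
        brute = euler_binding_oracle(c, T24)
        assert closed == pytest.approx(brute, rel=1e-3)
        # low-dose slope = slope_high/xi0, high-dose slope -> slope_high
        lo = closed[0] / c[0]
        assert lo == pytest.approx(T24.slope_high / 4.2, rel=0.02)

    def test_noiseless_mean_monotone(self):
        c = np.logspace(9.5, 13, 60)
        b = mean_binding_curve(c, T24)
        assert np.all(np.diff(b) >= -1e-9)

    def test_seed_reproducibility(self):
        c = np.logspace(10, 12, 9)
        a = simulate_binding_curve(T24, c, 0.05, 4, seed=7)
        b = simulate_binding_curve(T24, c, 0.05, 4, seed=7)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_empty_doses_rejected(self):
        with pytest.raises(ValueError):
            simulate_binding_curve(T24, np.array([]), 0.0)


class TestNormalizeCurve:
    def test_linear_rescale(self):
        curve = DoseBindingCurve(np.array([1.0, 2.0, 3.0]),
                                 np.array([2.0, 4.0, 8.0]))
        out = normalize_curve(curve)
        assert out.signal == pytest.approx([25.0, 50.0, 100.0])
        assert out.signal.max() == 100.0

    def test_idempotent(self):
        curve = DoseBindingCurve(np.array([1.0, 2.0, 3.0]),
                                 np.array([10.0, 60.0, 100.0]))
        out = normalize_curve(normalize_curve(curve))
        assert out.signal == pytest.approx(curve.signal)

    def test_arbitrary_units_ratios_preserved(self):
        sig = np.array([1.1e4, 2.0e4, 3.7e4])
        curve = DoseBindingCurve(np.array([1.0, 2.0, 3.0]), sig)
        out = normalize_curve(curve)
        assert out.signal.max() == 100.0
        assert out.signal / out.signal[0] == pytest.approx(sig / sig[0])

    def test_all_zero_rejected(self):
        curve = DoseBindingCurve(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        with pytest.raises(ValueError):
            normalize_curve(curve)


class TestInitialSlope:
    def test_recovers_noiseless_linear_slope(self):
        c = np.array([1e10, 2e10, 3e10, 4e10])
        curve = DoseBindingCurve(c, 17.0e-11 * c)
        slope, se = initial_slope(curve)
        assert slope == pytest.approx(17.0e-11, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-20)

    def test_zero_signal_gives_zero_slope(self):
        curve = DoseBindingCurve(np.array([1e10, 2e10, 3e10]), np.zeros(3))
        assert initial_slope(curve)[0] == 0.0

    def test_slope_ratio_preserved(self):
        """Two generators with slope ratio 2.576 fit back to the same ratio."""
        c = np.array([1e10, 2e10, 3e10])
        s = 6.6e-11
        r1 = initial_slope(DoseBindingCurve(c, s * c))[0]
        r2 = initial_slope(DoseBindingCurve(c, 2.576 * s * c))[0]
        assert r2 / r1 == pytest.approx(2.576, rel=1e-9)

    def test_window_from_c_star(self):
        c = np.logspace(10, 12, 9)
        curve = DoseBindingCurve(c, 1e-10 * c)
        # window <= c*/2 must contain >= 3 points, else lowest 3 are used
        slope, _ = initial_slope(curve, c_star=2.6e11)
        assert slope == pytest.approx(1e-10, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            initial_slope(DoseBindingCurve(np.array([1.0, 2.0]),
                                           np.array([1.0, 2.0])))


class TestFitCondensationModel:
    def test_noiseless_self_consistency(self):
        c = np.logspace(np.log10(4.97e10), np.log10(1.27e12), 9)
        curve = simulate_binding_curve(T24, c, noise_cv=0.0)
        fit = fit_condensation_model(curve)
        assert fit.converged
        assert fit.params.xi0 == pytest.approx(4.2, rel=1e-3)
        assert fit.params.c_star == pytest.approx(2.6e11, rel=1e-3)

    def test_narrow_dose_range_rejected(self):
        c = np.linspace(1e11, 3e11, 6)
        curve = simulate_binding_curve(T24, c, noise_cv=0.0)
        with pytest.raises(ValueError, match="dose range"):
            fit_condensation_model(curve)

    def test_uncertainties_reported(self):
        c = np.logspace(10.7, 12.1, 9)
        curve = simulate_binding_curve(T24, c, noise_cv=0.05,
                                       n_replicates=4, seed=11)
        fit = fit_condensation_model(curve)
        assert set(fit.uncertainties) == {"xi0", "c_star", "b_max",
                                          "slope_high"}
        assert all(v >= 0 for v in fit.uncertainties.values())


class TestCooperativityIndex:
    def test_linear_curve_ratio_one(self):
        c = np.linspace(1e10, 1e12, 10)
        curve = DoseBindingCurve(c, 1e-10 * c)
        res = cooperativity_index(curve)
        assert res.ratio == pytest.approx(1.0, rel=1e-9)
        assert not res.cooperative

    def test_ratio_estimates_xi0_in_sharp_presaturation_limit(self):
        p = BindingModelParams(xi0=4.2, c_star=2.6e11, b_max=1e5,
                               slope_high=2.772e-10, transition_width=0.15)
        c = np.logspace(10, 12.6, 30)
        curve = simulate_binding_curve(p, c, noise_cv=0.0)
        res = cooperativity_index(curve)
        assert res.ratio == pytest.approx(4.2, rel=0.05)
        assert res.cooperative

    def test_condensation_disabled_is_attenuated(self):
        """Salt-free-like scenario: no condensation, ratio near 1."""
        p = BindingModelParams(xi0=1.0, c_star=2.6e11, b_max=100.0,
                               slope_high=2.772e-10)
        c = np.logspace(10, 12.1, 24)
        res = cooperativity_index(simulate_binding_curve(p, c, 0.0))
        assert res.ratio == pytest.approx(1.0, abs=0.15)
        assert not res.cooperative

    def test_saturated_curve_unidentifiable(self):
        c = np.linspace(1e13, 2e13, 8)
        curve = simulate_binding_curve(T24, c, noise_cv=0.0)
        with pytest.raises(ValueError, match="saturated"):
            cooperativity_index(curve)


class TestEstimateChainLength:
    GEOM = ChainGeometry(charges_per_particle=4e4, cells_per_ml=6.67e5,
                         chains_per_cell=1e6, charges_per_nm=4.0)

    def test_unit_scaling(self):
        geom = ChainGeometry(charges_per_particle=1.0, cells_per_ml=1.0,
                             chains_per_cell=1.0, charges_per_nm=1.0)
        assert estimate_chain_length(3.7, geom) == pytest.approx(3.7)

    def test_length_ratio_equals_c_star_ratio(self):
        l1 = estimate_chain_length(2.6e11, self.GEOM)
        l2 = estimate_chain_length(1.2e11, self.GEOM)
        assert l1 / l2 == pytest.approx(2.6 / 1.2, rel=1e-12)

    def test_inverse_in_chains_per_cell(self):
        double = ChainGeometry(charges_per_particle=4e4, cells_per_ml=6.67e5,
                               chains_per_cell=2e6, charges_per_nm=4.0)
        assert estimate_chain_length(2.6e11, double) == pytest.approx(
            estimate_chain_length(2.6e11, self.GEOM) / 2)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ChainGeometry(charges_per_particle=0.0, cells_per_ml=1.0,
                          chains_per_cell=1.0)


@given(seed=st.integers(0, 50))
@settings(deadline=None, derandomize=True, max_examples=15)
def test_normalization_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    c = np.sort(rng.uniform(1e10, 1e12, 8))
    c = np.unique(c)
    sig = rng.uniform(0.1, 50.0, c.size)
    out = normalize_curve(DoseBindingCurve(c, sig))
    assert out.signal.max() == 100.0
    again = normalize_curve(out)
    np.testing.assert_allclose(again.signal, out.signal)
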