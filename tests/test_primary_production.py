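"""Photosynthesis-irradiance modelling, light attenuation and integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coastbalance.primary_production import (
    AttenuationFit,
    DepthProfile,
    LightField,
    PICurve,
    annual_production,
    daily_fixation_incubator,
    daily_fixation_insitu,
    diel_surface_irradiance,
    fit_attenuation,
    fit_pi_curve,
    integrate_depth,
    irradiance_at_depth,
    pi_model,
    specific_growth_rate,
)


class TestPIModel:
    @pytest.mark.parametrize(
        "irradiance, expected",
        [
            (0.0, 0.0),  # tanh(0) = 0
            (1e9, 10.0),  # saturates at p_max
            (10.0, 10.0 * np.tanh(0.5)),  # hand evaluation, ~4.6212
        ],
    )
    def test_closed_form(self, irradiance, expected):
        curve = PICurve(p_max=10.0, alpha=0.5)
        assert pi_model(irradiance, curve) == pytest.approx(expected, rel=1e-9)

    def test_monotone_and_bounded(self):
        curve = PICurve(p_max=8.0, alpha=0.3)
        irr = np.linspace(0, 2000, 400)
        p = pi_model(irr, curve)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= curve.p_max))

    def test_initial_slope_equals_alpha(self):
        curve = PICurve(p_max=8.0, alpha=0.3)
        eps = 1e-7
        assert pi_model(eps, curve) / eps == pytest.approx(0.3, rel=1e-5)

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError):
            pi_model(-1.0, PICurve(p_max=1.0, alpha=0.1))


class TestFitPICurve:
    def test_noiseless_self_consistency(self):
        truth = PICurve(p_max=8.0, alpha=0.3)
        irr = np.array([10, 25, 50, 100, 200, 400, 800, 1500], dtype=float)
        pairs = list(zip(irr, pi_model(irr, truth)))
        fit = fit_pi_curve(pairs)
        assert fit.p_max == pytest.approx(8.0, rel=1e-6)
        assert fit.alpha == pytest.approx(0.3, rel=1e-6)
        assert fit.fit_rss == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pi_curve([(100.0, 1.0), (100.0, 1.1), (100.0, 0.9)])
        with pytest.raises(ValueError):
            fit_pi_curve([(10.0, 0.0), (100.0, 0.0), (1000.0, 0.0)])

    def test_noisy_recovery_median_error_below_10pct(self):
        # CV 20% multiplicative noise, 8 light levels; median |error| of
        # p_max over repeated draws stays under 10%.
        truth = PICurve(p_max=8.0, alpha=0.3)
        irr = np.array([10, 25, 50, 100, 200, 400, 800, 1500], dtype=float)
        clean = pi_model(irr, truth)
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = clean * rng.lognormal(mean=-0.02, sigma=0.2, size=irr.size)
            fit = fit_pi_curve(list(zip(irr, noisy)))
            errors.append(abs(fit.p_max - 8.0) / 8.0)
        assert np.median(errors) < 0.10


class TestAttenuation:
    def test_exact_log_linear_profile(self):
        z = np.array([1.0, 2.0, 5.0, 10.0])
        prof = DepthProfile(depths=z, values=100.0 * np.exp(-0.4 * z))
        fit = fit_attenuation(prof)
        assert fit.attenuation_k == pytest.approx(0.4, rel=1e-10)
        assert fit.excluded_depths == ()

    def test_surface_outlier_excluded(self):
        z = np.array([1.0, 2.0, 5.0, 10.0, 15.0])
        values = 100.0 * np.exp(-0.4 * z)
        values[0] *= 0.25  # ship-shadowed surface bottle
        fit = fit_attenuation(DepthProfile(depths=z, values=values))
        assert 1.0 in fit.excluded_depths
        assert fit.attenuation_k == pytest.approx(0.4, rel=0.01)

    def test_increasing_irradiance_is_an_error(self):
        z = np.array([1.0, 2.0, 5.0, 10.0])
        with pytest.raises(ValueError, match="attenuation"):
            fit_attenuation(DepthProfile(depths=z, values=10.0 * np.exp(0.3 * z)))


class TestIrradianceAtDepth:
    def test_surface_transmittance(self):
        lf = LightField(surface_irradiance=np.full(24, 500.0), attenuation_k=0.5)
        assert irradiance_at_depth(lf, 0.0, 12) == pytest.approx(0.82 * 500.0)

    def test_hand_value(self):
        lf = LightField(surface_irradiance=np.full(24, 1000.0), attenuation_k=0.2)
        assert irradiance_at_depth(lf, 5.0, 0) == pytest.approx(
            0.82 * 1000.0 * np.exp(-1.0), rel=1e-12
        )

    def test_deep_limit(self):
        lf = LightField(surface_irradiance=np.full(24, 1000.0), attenuation_k=0.5)
        assert irradiance_at_depth(lf, 500.0, 6) == pytest.approx(0.0, abs=1e-30)


class TestDailyFixation:
    def test_dark_day_is_zero(self):
        curve = PICurve(p_max=5.0, alpha=0.05)
        lf = LightField(surface_irradiance=np.zeros(24), attenuation_k=0.3)
        prof = daily_fixation_incubator(curve, lf, [0, 5, 10, 20])
        assert np.allclose(prof.values, 0.0)

    def test_saturating_light_no_attenuation(self):
        # k -> 0 and saturating light at all hours: every depth fixes
        # 24 * p_max per day.
        curve = PICurve(p_max=5.0, alpha=0.5)
        lf = LightField(
            surface_irradiance=np.full(24, 1e7), attenuation_k=1e-9
        )
        prof = daily_fixation_incubator(curve, lf, [0, 5, 10, 20])
        assert np.allclose(prof.values, 24 * 5.0, rtol=1e-9)

    def test_matches_fine_step_quadrature(self):
        # Smooth diurnal sine irradiance: hourly-mean discretization agrees
        # with a 1-minute / 0.1 m brute-force oracle within 2%.
        curve = PICurve(p_max=5.0, alpha=0.05)
        k = 0.3
        noon = 1200.0

        def analytic(t_hours):
            return noon * np.maximum(np.sin(np.pi * (t_hours - 4.0) / 16.0), 0.0) * (
                (t_hours >= 4.0) & (t_hours <= 20.0)
            )

        minutes = np.arange(0, 24 * 60) / 60.0 + 0.5 / 60.0
        hourly_means = analytic(minutes).reshape(24, 60).mean(axis=1)
        lf = LightField(surface_irradiance=hourly_means, attenuation_k=k)
        coarse = daily_fixation_incubator(curve, lf, np.linspace(0, 20, 9))
        coarse_areal = integrate_depth(coarse, 20.0)

        z = np.arange(0, 20.0 + 1e-9, 0.1)
        irr = 0.82 * analytic(minutes)[None, :] * np.exp(-k * z[:, None])
        fine = np.trapezoid(pi_model(irr, curve) / 60.0, axis=1)
        fine_areal = float(np.trapezoid(fine, z))
        assert coarse_areal == pytest.approx(fine_areal, rel=0.02)

    def test_insitu_diel_scaling(self):
        prof = DepthProfile(depths=[1, 5, 10], values=[5.0, 5.0, 5.0])
        scaled = daily_fixation_insitu(prof, 40.0, 10.0)
        assert np.allclose(scaled.values, 20.0)
        unchanged = daily_fixation_insitu(prof, 10.0, 10.0)
        assert np.allclose(unchanged.values, prof.values)
        dark = daily_fixation_insitu(prof, 0.0, 10.0)
        assert np.allclose(dark.values, 0.0)
        with pytest.raises(ValueError):
            daily_fixation_insitu(prof, 10.0, 0.0)


class TestIntegrateDepth:
    def test_hand_trapezoid(self):
        prof = DepthProfile(depths=[0, 10, 20], values=[2.0, 1.0, 0.0])
        assert integrate_depth(prof, 20.0) == pytest.approx(20.0)

    def test_constant_profile(self):
        prof = DepthProfile(depths=[0, 7, 20], values=[3.0, 3.0, 3.0])
        assert integrate_depth(prof, 20.0) == pytest.approx(60.0)

    def test_constant_extrapolation_below_deepest(self):
        prof = DepthProfile(depths=[0, 10], values=[1.0, 1.0])
        assert integrate_depth(prof, 20.0) == pytest.approx(20.0)

    def test_unsorted_depths_rejected(self):
        with pytest.raises(ValueError):
            integrate_depth(DepthProfile(depths=[5, 1, 10], values=[1, 1, 1]), 20.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0.1, 50.0), min_size=2, max_size=6, unique=True),
        st.lists(st.floats(0.0, 100.0), min_size=6, max_size=6),
    )
    def test_piecewise_linear_exactness(self, depths, values):
        # Trapezoid integration is exact for piecewise-linear profiles:
        # doubling the values doubles the integral, and splitting a segment
        # at its midpoint leaves the integral unchanged.
        z = np.array(sorted(depths))
        v = np.array(values[: z.size])
        base = integrate_depth(DepthProfile(depths=z, values=v), float(z[-1]))
        doubled = integrate_depth(DepthProfile(depths=z, values=2 * v), float(z[-1]))
        assert doubled == pytest.approx(2 * base, rel=1e-12, abs=1e-9)
        mid = (z[0] + z[1]) / 2.0
        vmid = np.interp(mid, z, v)
        z2 = np.insert(z, 1, mid)
        v2 = np.insert(v, 1, vmid)
        refined = integrate_depth(DepthProfile(depths=z2, values=v2), float(z[-1]))
        assert refined == pytest.approx(base, rel=1e-12, abs=1e-9)

    def test_monotone_in_p_max(self):
        lf = LightField(
            surface_irradiance=diel_surface_irradiance(180.0, 1200.0),
            attenuation_k=0.3,
        )
        areal = [
            integrate_depth(
                daily_fixation_incubator(PICurve(p_max=p, alpha=0.05), lf,
                                         np.linspace(0, 20, 9)),
                20.0,
            )
            for p in (2.0, 4.0, 8.0)
        ]
        assert areal[0] < areal[1] < areal[2]


class TestAnnualProduction:
    def test_constant_rate_full_year(self):
        dates = pd.date_range("1995-01-15", "1995-12-15", freq="MS") + pd.Timedelta(days=14)
        ap = annual_production(dates, [100.0] * len(dates), year=1995)
        assert ap.value == pytest.approx(36.5)

    def test_triangle_hand_value(self):
        # Two dates forming a triangle plus flat extensions to the year ends.
        dates = [pd.Timestamp("1995-04-10"), pd.Timestamp("1995-07-19")]
        doys = [100.0, 200.0]
        vals = [0.0, 1000.0]
        ap = annual_production(dates, vals, year=1995)
        expected = (0.5 * 100 * 1000 + 1000 * 165) / 1000.0  # g C m^-2
        assert ap.value == pytest.approx(expected)

    def test_single_date_rejected(self):
        with pytest.raises(ValueError):
            annual_production([pd.Timestamp("1995-06-01")], [10.0], year=1995)


class TestSpecificGrowthRate:
    def test_hand_division(self):
        assert specific_growth_rate(50.0, 5.0) == pytest.approx(10.0)
        assert specific_growth_rate(0.0, 5.0) == 0.0

    def test_zero_biomass_rejected(self):
        with pytest.raises(ValueError):
            specific_growth_rate(50.0, 0.0)


def test_method_equivalence_incubator_vs_insitu(quiet_truth):
    """Same synthetic truth through both daily-fixation strategies.

    The in situ path measures a midday 3 h incubation and scales by the
    diel irradiance quotient; it should agree with the modelled incubator
    path within the band established by between-method calibration
    (annual ratio in [0.8, 1.35]) at realistic noise.
    """
    from coastbalance.synthetic_data import hourly_surface_irradiance, seasonal_p_max

    rng = np.random.default_rng(42)
    truth = quiet_truth
    doys = np.linspace(40, 330, 16)
    k = truth.true_attenuation_base
    depth_grid = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
    incubator_daily, insitu_daily, dates = [], [], []
    for doy in doys:
        surf = hourly_surface_irradiance(doy)
        curve = PICurve(p_max=seasonal_p_max(doy, truth), alpha=truth.true_alpha)
        lf = LightField(surface_irradiance=surf, attenuation_k=k)
        prof = daily_fixation_incubator(curve, lf, depth_grid)
        incubator_daily.append(integrate_depth(prof, 20.0))
        # 3 h morning in situ incubation at the measured depths
        hours = [8, 9, 10]
        uptake = np.array([
            sum(pi_model(irradiance_at_depth(lf, z, h), curve) for h in hours)
            for z in depth_grid
        ]) * rng.lognormal(-0.02, 0.2, size=depth_grid.size)
        diel = float(surf.sum())
        incub = float(surf[hours].sum())
        daily = daily_fixation_insitu(
            DepthProfile(depths=depth_grid, values=uptake), diel, incub
        )
        insitu_daily.append(integrate_depth(daily, 20.0))
        dates.append(pd.Timestamp("2000-01-01") + pd.Timedelta(days=int(doy) - 1))
    a_inc = annual_production(dates, incubator_daily, year=2000).value
    a_ins = annual_production(dates, insitu_daily, year=2000).value
    assert 0.8 <= a_ins / a_inc <= 1.35
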