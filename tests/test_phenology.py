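"""DVR model and CBM day-length unit tests.

The reference values here are computed by independent oracles coded in
this file (hour-angle astronomy, day-by-day Euler accumulation,
arbitrary-precision formula evaluation), not by the library under test.
"""

import math

import numpy as np
import pytest
import sympy

from phenobridge.phenology import (
    CardinalConstants,
    DVRParams,
    EnvironmentSeries,
    day_length,
    day_length_series,
    dth_batch,
    phase_thresholds,
    photoperiod_response,
    simulate_heading,
    temperature_response,
)
from conftest import constant_env


# ---------------------------------------------------------------------------
# Independent oracles


def solar_day_length(lat_deg, doy):
    """Hour-angle/declination day length, coded independently of the CBM path.

    Declination from the Spencer Fourier series; sunrise/sunset at zero
    solar elevation of the sun's centre.
    """
    g = 2 * math.pi * (doy - 1) / 365.0
    decl = (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    lat = math.radians(lat_deg)
    cos_w = -math.tan(lat) * math.tan(decl)
    cos_w = min(1.0, max(-1.0, cos_w))
    return 2.0 * math.degrees(math.acos(cos_w)) / 15.0


def euler_dth(temps, photos, alpha, beta, g, cards=None, max_days=200):
    """Day-by-day accumulation with explicit branch logic (plain Python)."""
    c = cards or CardinalConstants()

    def f(t):
        if not (c.t_base < t < c.t_ceil):
            return 0.0
        e2 = (c.t_ceil - c.t_opt) / (c.t_opt - c.t_base)
        base = ((t - c.t_base) / (c.t_opt - c.t_base)) * \
            ((c.t_ceil - t) / (c.t_ceil - c.t_opt)) ** e2
        return base ** alpha

    def gp(p):
        if p <= c.p_opt:
            return 1.0
        if p >= c.p_ceil:
            return 0.0
        e2 = (c.p_ceil - c.p_opt) / (c.p_opt - c.p_base)
        base = ((p - c.p_base) / (c.p_opt - c.p_base)) * \
            ((c.p_ceil - p) / (c.p_ceil - c.p_opt)) ** e2
        return base ** beta

    dvs1, dvs2 = 0.145 + 0.005 * g, 0.345 + 0.005 * g
    dvs = 0.0
    for d in range(1, max_days + 1):
        t, p = temps[d - 1], photos[d - 1]
        if dvs1 <= dvs < dvs2:
            dvs += f(t) * gp(p) / g
        else:
            dvs += f(t) / g
        if dvs >= 1.0 - 1e-9:
            return d
    return None


# ---------------------------------------------------------------------------
# Day length


class TestDayLength:
    def test_equator_is_12h(self):
        for doy in (1, 80, 172, 355):
            assert day_length(0.0, doy, 0.0) == pytest.approx(12.0, abs=0.01)

    def test_solstice_against_declination_oracle(self):
        assert day_length(36.0, 172, 0.0) == pytest.approx(
            solar_day_length(36.0, 172), abs=0.1)

    def test_hemispheric_symmetry(self):
        assert day_length(-36.0, 172, 0.0) == pytest.approx(
            24.0 - day_length(36.0, 172, 0.0), abs=1e-9)

    def test_matches_oracle_over_latitudes_and_days(self):
        for lat in np.linspace(-45, 45, 13):
            for doy in range(1, 366, 7):
                assert day_length(lat, doy) == pytest.approx(
                    solar_day_length(lat, doy), abs=0.1), (lat, doy)

    def test_bell_shape_in_northern_summer(self):
        curve = day_length_series(40.0, np.arange(1, 366))
        peak = int(np.argmax(curve)) + 1
        assert 165 < peak < 180  # near the June solstice
        assert np.all(np.diff(curve[:peak - 1]) > -1e-9)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            day_length(70.0, 172)
        with pytest.raises(ValueError, match="latitude"):
            day_length(-80.0, 10)

    def test_coefficient_extends_day(self):
        assert day_length(36.0, 172, 6.0) > day_length(36.0, 172, 0.0)


# ---------------------------------------------------------------------------
# Response functions


class TestResponses:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 3.7])
    def test_temperature_cardinal_points(self, alpha):
        assert temperature_response(30.0, alpha=alpha) == pytest.approx(1.0)
        assert temperature_response(8.0, alpha=alpha) == 0.0
        assert temperature_response(42.0, alpha=alpha) == 0.0
        assert temperature_response(-3.0, alpha=alpha) == 0.0
        assert temperature_response(50.0, alpha=alpha) == 0.0

    def test_temperature_printed_value(self):
        # 0.5 * (23/12)^(12/22), evaluated independently
        expected = 0.5 * (23.0 / 12.0) ** (12.0 / 22.0)
        assert temperature_response(19.0, alpha=1.0) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.7130, abs=1e-4)

    def test_temperature_matches_arbitrary_precision_grid(self):
        """f agrees with exact symbolic evaluation to 1e-10 on a (t, alpha) grid."""
        t_sym, a_sym = sympy.symbols("t a", positive=True)
        tb, to, tc = sympy.Integer(8), sympy.Integer(30), sympy.Integer(42)
        expr = (((t_sym - tb) / (to - tb))
                * ((tc - t_sym) / (tc - to)) ** ((tc - to) / (to - tb))) ** a_sym
        for t in [8.5, 12.0, 19.0, 25.0, 30.0, 33.3, 41.5]:
            for alpha in [0.2, 1.0, 2.5, 7.0]:
                exact = float(expr.subs({t_sym: sympy.Rational(str(t)),
                                         a_sym: sympy.Rational(str(alpha))})
                              .evalf(30))
                assert temperature_response(t, alpha=alpha) == pytest.approx(
                    exact, abs=1e-10), (t, alpha)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 4.0])
    def test_photoperiod_branches(self, beta):
        assert photoperiod_response(9.0, beta=beta) == 1.0
        assert photoperiod_response(10.0, beta=beta) == 1.0
        assert photoperiod_response(24.0, beta=beta) == 0.0

    def test_photoperiod_printed_value(self):
        expected = (1.4 * (10.0 / 14.0) ** 1.4) ** 1.0
        assert photoperiod_response(14.0, beta=1.0) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.8741, abs=1e-4)

    def test_photoperiod_matches_arbitrary_precision_grid(self):
        p_sym, b_sym = sympy.symbols("p b", positive=True)
        pb, po, pc = sympy.Integer(0), sympy.Integer(10), sympy.Integer(24)
        expr = (((p_sym - pb) / (po - pb))
                * ((pc - p_sym) / (pc - po)) ** ((pc - po) / (po - pb))) ** b_sym
        for p in [10.5, 12.0, 14.0, 16.0, 20.0, 23.5]:
            for beta in [0.3, 1.0, 4.0, 9.0]:
                exact = float(expr.subs({p_sym: sympy.Rational(str(p)),
                                         b_sym: sympy.Rational(str(beta))})
                              .evalf(30))
                assert photoperiod_response(p, beta=beta) == pytest.approx(
                    exact, abs=1e-10), (p, beta)

    def test_photoperiod_non_increasing_above_optimum(self):
        grid = np.linspace(10, 24, 200)
        vals = photoperiod_response(grid, beta=2.0)
        assert np.all(np.diff(vals) <= 1e-12)


class TestPhaseThresholds:
    @pytest.mark.parametrize("g,expected", [(50, (0.395, 0.595)),
                                            (35, (0.320, 0.520))])
    def test_printed_values(self, g, expected):
        thr = phase_thresholds(DVRParams(1, 1, g))
        assert (thr.dvs1, thr.dvs2) == pytest.approx(expected)

    @pytest.mark.parametrize("g", [30, 47.3, 90, 120])
    def test_window_width_is_02(self, g):
        thr = phase_thresholds(DVRParams(1, 1, g))
        assert thr.dvs2 - thr.dvs1 == pytest.approx(0.2, abs=1e-12)


# ---------------------------------------------------------------------------
# Simulation


class TestSimulateHeading:
    @pytest.mark.parametrize("alpha,beta,g", [(1, 1, 40), (3, 0.5, 40),
                                              (0.7, 6, 55.5), (2, 2, 33)])
    def test_optimal_conditions_give_ceil_g(self, alpha, beta, g):
        env = constant_env(t=30, p=10)
        trace = simulate_heading(env, DVRParams(alpha, beta, g))
        assert trace.dth == math.ceil(g)

    def test_base_temperature_censors(self):
        env = constant_env(t=8, p=10)
        trace = simulate_heading(env, DVRParams(1, 1, 40))
        assert trace.censored and trace.dth is None
        assert np.all(trace.dvs_by_day == 0)

    def test_long_day_case_matches_euler_oracle(self):
        """Constant T=30, P=14, (1, 1, 40): the day-by-day hand accumulation."""
        env = constant_env(t=30, p=14)
        expected = euler_dth(env.temperatures, env.photoperiods, 1, 1, 40)
        trace = simulate_heading(env, DVRParams(1, 1, 40))
        assert expected == 42  # 14 juvenile + 9 sensitive + 19 post days
        assert trace.dth == expected

    def test_matches_euler_oracle_on_random_weather(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            temps = rng.uniform(10, 34, 250)
            photos = rng.uniform(9, 16, 250)
            env = EnvironmentSeries("r", 36, 135, None, temps, photos)
            a, b, g = rng.uniform(0.3, 3), rng.uniform(0.2, 6), rng.uniform(31, 90)
            expected = euler_dth(temps, photos, a, b, g)
            got = simulate_heading(env, DVRParams(a, b, g)).dth
            assert got == expected, (a, b, g)

    def test_dvs_non_decreasing_and_consistent(self):
        rng = np.random.default_rng(1)
        env = EnvironmentSeries("r", 36, 135, None,
                                rng.uniform(5, 40, 250), rng.uniform(8, 17, 250))
        trace = simulate_heading(env, DVRParams(1.3, 2.2, 50))
        assert np.all(np.diff(trace.dvs_by_day) >= -1e-15)
        np.testing.assert_allclose(trace.dvs_by_day,
                                   np.cumsum(trace.dvr_by_day), rtol=1e-12)

    def test_longer_days_with_higher_beta_never_earlier(self):
        env = constant_env(t=30, p=13)
        dths = [simulate_heading(env, DVRParams(1, b, 45)).dth
                for b in (0.5, 1, 2, 4, 8)]
        assert all(x <= y for x, y in zip(dths, dths[1:]) if y is not None)

    def test_tiny_beta_removes_photoperiod_dependence(self):
        p_short = constant_env(t=28, p=11)
        p_long = constant_env(t=28, p=16)
        for env in (p_short, p_long):
            env_dth = simulate_heading(env, DVRParams(1, 1e-9, 50)).dth
            ref = simulate_heading(constant_env(t=28, p=9),
                                   DVRParams(1, 1e-9, 50)).dth
            assert env_dth == ref

    def test_short_series_rejected(self):
        env = constant_env(n=100)
        with pytest.raises(ValueError, match="needs >= 200"):
            simulate_heading(env, DVRParams(1, 1, 40))

    def test_batch_agrees_with_scalar_path(self, cardinals):
        rng = np.random.default_rng(11)
        envs, params = [], []
        for _ in range(40):
            envs.append(EnvironmentSeries(
                "b", 36, 135, None, rng.uniform(4, 38, 220),
                rng.uniform(8, 17, 220)))
            params.append((rng.uniform(0, 4), rng.uniform(0, 8),
                           rng.uniform(30, 119)))
        from phenobridge.phenology import _dth_batch_numpy

        for env, (a, b, g) in zip(envs, params):
            lf, lg = env.response_logs(cardinals, 200)
            batch = dth_batch(lf[None, :], lg[None, :], a, b, g)[0]
            fallback = _dth_batch_numpy(lf[None, :], lg[None, :], a, b, g)[0]
            scalar = simulate_heading(env, DVRParams(a, b, g)).dth
            assert batch == (scalar if scalar is not None else -1)
            assert fallback == batch

    def test_zero_alpha_edge_is_finite(self, cardinals):
        # alpha = 0 sits on the prior bound: f = 1 inside the cardinal range,
        # 0 outside, never NaN
        env = constant_env(t=5, p=10)  # below base temperature
        trace = simulate_heading(env, DVRParams(0.0, 1.0, 40))
        assert trace.censored
        env2 = constant_env(t=20, p=10)
        assert simulate_heading(env2, DVRParams(0.0, 1.0, 40)).dth == 40
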