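"""Developmental-rate (DVR) phenology model for rice heading.

The model divides pre-heading development into three sub-phases: a
juvenile phase insensitive to photoperiod, a photoperiod-sensitive
phase, and a post-sensitive phase.  Development is tracked by a
dimensionless developmental stage (DVS) that accumulates a daily
developmental rate (DVR); heading occurs when DVS reaches 1.

Each day's DVR is a multiplicative response to that day's mean
temperature and photoperiod::

    DVR_i = f(T_i) / G                 outside the sensitive window
    DVR_i = f(T_i) * g(P_i) / G        inside the sensitive window

where ``f`` and ``g`` are beta-function responses bounded by cardinal
temperatures/photoperiods, and ``G`` (days) is the time to heading under
permanently optimal conditions.  Rice is a short-day plant: ``g`` equals
1 at or below the optimum photoperiod and decays toward 0 at the
ceiling, so long days slow development.

The sensitive window is expressed in DVS units and tied to ``G``::

    DVS1 = 0.145 + 0.005 G
    DVS2 = 0.345 + 0.005 G

Day length is computed from latitude and day of year with the CBM
model (revolution angle -> solar declination -> day length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CardinalConstants",
    "DVRParams",
    "PhaseThresholds",
    "EnvironmentSeries",
    "PhenologyTrace",
    "day_length",
    "day_length_series",
    "temperature_response",
    "photoperiod_response",
    "phase_thresholds",
    "simulate_heading",
    "predict_dth",
]

#: Longest supported simulation horizon (days after sowing).
DEFAULT_MAX_DAYS = 200

#: Accumulated-rounding tolerance when testing DVS >= 1 (sums of ~100 terms).
_CROSS_EPS = 1e-9


@dataclass(frozen=True)
class CardinalConstants:
    """Base/optimum/ceiling temperatures (degC) and photoperiods (h).

    Defaults follow the rice DVR literature: 8/30/42 degC and 0/10/24 h.
    They are held fixed during calibration; only (alpha, beta, G) are
    genotype specific.
    """

    t_base: float = 8.0
    t_opt: float = 30.0
    t_ceil: float = 42.0
    p_base: float = 0.0
    p_opt: float = 10.0
    p_ceil: float = 24.0

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt < self.t_ceil):
            raise ValueError("cardinal temperatures must satisfy base < opt < ceil")
        if not (self.p_base < self.p_opt < self.p_ceil):
            raise ValueError("cardinal photoperiods must satisfy base < opt < ceil")


@dataclass(frozen=True)
class DVRParams:
    """Genotype-specific DVR parameters.

    alpha : temperature sensitivity exponent (dimensionless, > 0)
    beta : photoperiod sensitivity exponent (dimensionless, > 0)
    g_days : days to heading under optimal temperature and photoperiod
    """

    alpha: float
    beta: float
    g_days: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.g_days <= 0:
            raise ValueError("g_days must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.g_days], dtype=float)


@dataclass(frozen=True)
class PhaseThresholds:
    """DVS values ending the juvenile and photoperiod-sensitive phases."""

    dvs1: float
    dvs2: float


@dataclass
class EnvironmentSeries:
    """Daily weather for one location-year-sowing context.

    ``temperatures[0]`` and ``photoperiods[0]`` belong to the sowing day
    (day offset 0); subsequent entries are consecutive calendar days.
    """

    env_id: str
    latitude: float
    longitude: float
    sowing_date: object  # datetime.date; kept loose for synthetic use
    temperatures: np.ndarray
    photoperiods: np.ndarray
    # cache of log-response bases keyed by cardinal constants
    _log_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.photoperiods = np.asarray(self.photoperiods, dtype=float)
        if self.temperatures.shape != self.photoperiods.shape:
            raise ValueError("temperatures and photoperiods must be equally long")
        if np.any(~np.isfinite(self.temperatures)):
            raise ValueError(f"environment {self.env_id}: non-finite temperature")
        if np.any((self.photoperiods < 0) | (self.photoperiods > 24)):
            raise ValueError(f"environment {self.env_id}: photoperiod outside [0, 24]")

    def __len__(self) -> int:
        return len(self.temperatures)

    def response_logs(self, cardinals: CardinalConstants, max_days: int):
        """Log of the alpha/beta-independent response bases, truncated to max_days.

        Returns ``(log_f_base, log_g_base)`` where ``f = exp(alpha*log_f_base)``
        and ``g = exp(beta*log_g_base)`` (with -inf encoding a zero response
        and 0 encoding the insensitive g = 1 branch).  Cached per cardinals.
        """
        key = (cardinals, max_days)
        hit = self._log_cache.get(key)
        if hit is None:
            lf = _log_f_base(self.temperatures[:max_days], cardinals)
            lg = _log_g_base(self.photoperiods[:max_days], cardinals)
            hit = self._log_cache[key] = (lf, lg)
        return hit


@dataclass
class PhenologyTrace:
    """Daily DVR/DVS trajectory and the resulting days to heading."""

    dvr_by_day: np.ndarray
    dvs_by_day: np.ndarray
    dth: int | None
    censored: bool


# ---------------------------------------------------------------------------
# CBM day length


def day_length(latitude: float, day_of_year: int, daylength_coef: float = 0.0) -> float:
    """Theoretical day length (hours) from the CBM model.

    Parameters
    ----------
    latitude : degrees, must lie strictly inside +-66.5 (no polar day/night).
    day_of_year : 1..366.
    daylength_coef : sun-position coefficient p in degrees; 0 gives the
        geometric sunrise-to-sunset interval of the solar centre, larger
        values extend the day into twilight.
    """
    if abs(latitude) >= 66.5:
        raise ValueError(
            f"latitude {latitude} is outside the supported range (|lat| < 66.5)"
        )
    if daylength_coef < 0:
        raise ValueError("daylength_coef must be non-negative")
    return float(_cbm(np.asarray(float(latitude)), np.asarray(float(day_of_year)),
                      daylength_coef))


def day_length_series(latitude: float, days_of_year: np.ndarray,
                      daylength_coef: float = 0.0) -> np.ndarray:
    """Vectorized :func:`day_length` over an array of days of year."""
    if abs(latitude) >= 66.5:
        raise ValueError(
            f"latitude {latitude} is outside the supported range (|lat| < 66.5)"
        )
    return _cbm(np.asarray(float(latitude)), np.asarray(days_of_year, dtype=float),
                daylength_coef)


def _cbm(lat_deg, doy, p_deg):
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    lat = np.deg2rad(lat_deg)
    p = np.deg2rad(p_deg)
    arg = (np.sin(p) + np.sin(lat) * np.sin(phi)) / (np.cos(lat) * np.cos(phi))
    arg = np.clip(arg, -1.0, 1.0)
    return 24.0 - (24.0 / np.pi) * np.arccos(arg)


# ---------------------------------------------------------------------------
# Response functions

def _log_f_base(t: np.ndarray, c: CardinalConstants) -> np.ndarray:
    """log of the temperature beta-function base; -inf outside [t_base, t_ceil]."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, -np.inf)
    inside = (t > c.t_base) & (t < c.t_ceil)
    if np.any(inside):
        ti = t[inside]
        exp2 = (c.t_ceil - c.t_opt) / (c.t_opt - c.t_base)
        out[inside] = (
            np.log((ti - c.t_base) / (c.t_opt - c.t_base))
            + exp2 * np.log((c.t_ceil - ti) / (c.t_ceil - c.t_opt))
        )
    return out


def _log_g_base(p: np.ndarray, c: CardinalConstants) -> np.ndarray:
    """log of the photoperiod base: 0 (g=1) for p <= p_opt, -inf at/above p_ceil."""
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape)
    long_day = (p > c.p_opt) & (p < c.p_ceil)
    if np.any(long_day):
        pi = p[long_day]
        exp2 = (c.p_ceil - c.p_opt) / (c.p_opt - c.p_base)
        out[long_day] = (
            np.log((pi - c.p_base) / (c.p_opt - c.p_base))
            + exp2 * np.log((c.p_ceil - pi) / (c.p_ceil - c.p_opt))
        )
    out[p >= c.p_ceil] = -np.inf  # defensive; p_ceil = 24 h is unreachable
    return out


def temperature_response(t, cardinals: CardinalConstants | None = None,
                         alpha: float = 1.0):
    """Beta-function temperature response f(T) in [0, 1].

    Zero at or outside the base/ceiling temperatures, 1 at the optimum;
    ``alpha`` sharpens (>1) or flattens (<1) the curve.
    """
    c = cardinals or CardinalConstants()
    scalar = np.isscalar(t)
    val = np.exp(alpha * _log_f_base(np.atleast_1d(np.asarray(t, dtype=float)), c))
    return float(val[0]) if scalar else val


def photoperiod_response(p, cardinals: CardinalConstants | None = None,
                         beta: float = 1.0):
    """Photoperiod response g(P): 1 for P <= p_opt, decaying to 0 at p_ceil."""
    c = cardinals or CardinalConstants()
    scalar = np.isscalar(p)
    val = np.exp(beta * _log_g_base(np.atleast_1d(np.asarray(p, dtype=float)), c))
    return float(val[0]) if scalar else val


def phase_thresholds(params: DVRParams) -> PhaseThresholds:
    """DVS boundaries of the photoperiod-sensitive window (width 0.2)."""
    g = params.g_days
    return PhaseThresholds(dvs1=0.145 + 0.005 * g, dvs2=0.345 + 0.005 * g)


# ---------------------------------------------------------------------------
# Simulation

def _accumulate(f_over_g: np.ndarray, fg_over_g: np.ndarray, dvs1: float,
                dvs2: float) -> np.ndarray:
    """Daily DVR with the branch chosen from the previous day's DVS.

    Phase switching uses the DVS accumulated through the previous day
    (daily Euler step): the photoperiod-sensitive rate applies on days
    whose previous-day DVS lies in [dvs1, dvs2).
    """
    n = f_over_g.shape[0]
    dvr = np.empty(n)
    # phase 1: previous DVS < dvs1
    cum = np.cumsum(f_over_g)
    j1 = int(np.searchsorted(cum, dvs1, side="left")) + 1  # first sensitive day
    j1 = min(j1, n)
    dvr[:j1] = f_over_g[:j1]
    base = cum[j1 - 1] if j1 > 0 else 0.0
    if j1 >= n:
        return dvr
    # phase 2: dvs1 <= previous DVS < dvs2
    cum2 = base + np.cumsum(fg_over_g[j1:])
    j2 = j1 + int(np.searchsorted(cum2, dvs2, side="left")) + 1
    j2 = min(j2, n)
    dvr[j1:j2] = fg_over_g[j1:j2]
    base2 = cum2[j2 - j1 - 1] if j2 > j1 else base
    if j2 >= n:
        return dvr
    # phase 3: previous DVS >= dvs2
    dvr[j2:] = f_over_g[j2:]
    return dvr


def _exp_response(exponent: float, log_base: np.ndarray) -> np.ndarray:
    """exp(exponent * log_base) with -inf log bases mapping to 0.

    A -inf entry encodes a zero response outside the cardinal range,
    which stays 0 for every exponent (including 0, where the naive
    product 0 * -inf would be NaN).
    """
    with np.errstate(over="ignore", invalid="ignore"):
        v = np.exp(exponent * log_base)
    if exponent == 0.0:
        v = np.where(np.isneginf(log_base), 0.0, v)
    return v


def _dth_from_logs(log_f: np.ndarray, log_g: np.ndarray, alpha: float,
                   beta: float, g_days: float) -> tuple[np.ndarray, np.ndarray, int | None]:
    f = _exp_response(alpha, log_f)
    gp = _exp_response(beta, log_g)
    f_over_g = f / g_days
    dvr = _accumulate(f_over_g, f_over_g * gp,
                      0.145 + 0.005 * g_days, 0.345 + 0.005 * g_days)
    dvs = np.cumsum(dvr)
    k = int(np.searchsorted(dvs, 1.0 - _CROSS_EPS, side="left"))
    dth = k + 1 if k < dvs.shape[0] else None
    return dvr, dvs, dth


try:  # pragma: no cover - exercised through dth_batch
    from numba import njit

    @njit(cache=False)
    def _dth_batch_jit(log_f, log_g, alpha, beta, g_days):  # pragma: no cover
        n, m = log_f.shape
        out = np.full(n, -1, dtype=np.int64)
        dvs1 = 0.145 + 0.005 * g_days
        dvs2 = dvs1 + 0.2
        thresh = 1.0 - 1e-9
        for i in range(n):
            dvs = 0.0
            for j in range(m):
                lf = log_f[i, j]
                f = 0.0 if lf == -np.inf else np.exp(alpha * lf)
                if dvs1 <= dvs < dvs2:
                    lg = log_g[i, j]
                    gp = 0.0 if lg == -np.inf else np.exp(beta * lg)
                    dvs += f * gp / g_days
                else:
                    dvs += f / g_days
                if dvs >= thresh:
                    out[i] = j + 1
                    break
        return out

except ImportError:  # pragma: no cover
    _dth_batch_jit = None


def dth_batch(log_f: np.ndarray, log_g: np.ndarray, alpha: float, beta: float,
              g_days: float) -> np.ndarray:
    """Days to heading for many environments at once.

    ``log_f``/``log_g`` are (n_env, n_days) stacks of cached response log
    bases.  Returns an integer array with -1 marking censored rows.
    Shares the branch convention of :func:`simulate_heading` (previous
    day's DVS, sensitive window [DVS1, DVS2)).  Uses a compiled kernel
    when numba is available, else the vectorized fallback.
    """
    if _dth_batch_jit is not None:
        return _dth_batch_jit(np.ascontiguousarray(log_f),
                              np.ascontiguousarray(log_g),
                              float(alpha), float(beta), float(g_days))
    return _dth_batch_numpy(log_f, log_g, alpha, beta, g_days)


def _dth_batch_numpy(log_f: np.ndarray, log_g: np.ndarray, alpha: float, beta: float,
                     g_days: float) -> np.ndarray:
    """Days to heading for many environments at once.

    ``log_f``/``log_g`` are (n_env, n_days) stacks of cached response log
    bases.  Returns an integer array with -1 marking censored rows.
    Shares the branch convention of :func:`simulate_heading` (previous
    day's DVS, sensitive window [DVS1, DVS2)); the cumulative sums per
    phase are closed-form, so the cost is a few matrix operations.

    Relies on the single-day DVS increment being at most 1/G < 0.2 (the
    sensitive-window width), which holds for G >= 30.
    """
    f = _exp_response(alpha, log_f)
    gp = _exp_response(beta, log_g)
    n, m = f.shape
    dvs1 = 0.145 + 0.005 * g_days
    dvs2 = dvs1 + 0.2
    rows = np.arange(n)
    dth = np.full(n, -1, dtype=np.int64)

    a = np.cumsum(f, axis=1) / g_days          # phase-1/3 rate accumulation
    hit1 = a >= dvs1
    act = hit1.any(axis=1)
    if not act.any():
        return dth
    i1 = np.where(act, hit1.argmax(axis=1), m - 1)  # last juvenile day
    # a one-day step cannot clear the whole window, so i1 + 1 < m whenever
    # the trajectory can still reach DVS = 1
    b = np.cumsum(f * gp, axis=1) / g_days     # phase-2 rate accumulation
    base1 = a[rows, i1]
    th2 = dvs2 - base1 + b[rows, i1]
    hit2 = b >= th2[:, None]
    act &= hit2.any(axis=1)
    i2 = np.where(act, hit2.argmax(axis=1), m - 1)  # last sensitive day
    base2 = base1 + b[rows, i2] - b[rows, i1]
    th3 = 1.0 - _CROSS_EPS - base2 + a[rows, i2]
    hit3 = a >= th3[:, None]
    act &= hit3.any(axis=1)
    k = hit3.argmax(axis=1)
    dth[act] = k[act] + 1
    return dth


def simulate_heading(env: EnvironmentSeries, params: DVRParams,
                     cardinals: CardinalConstants | None = None,
                     max_days: int = DEFAULT_MAX_DAYS) -> PhenologyTrace:
    """Integrate daily DVR from sowing and return the trajectory and DTH.

    DVS starts at 0 on the sowing day and day offset 0 is the first
    integrated day; DTH is the 1-based index of the first day whose
    cumulative DVS reaches 1.  If DVS never reaches 1 within ``max_days``
    the trace is censored.
    """
    c = cardinals or CardinalConstants()
    if len(env) < max_days:
        raise ValueError(
            f"environment {env.env_id} has {len(env)} days, needs >= {max_days}"
        )
    log_f, log_g = env.response_logs(c, max_days)
    dvr, dvs, dth = _dth_from_logs(log_f, log_g, params.alpha, params.beta,
                                   params.g_days)
    return PhenologyTrace(dvr_by_day=dvr, dvs_by_day=dvs, dth=dth,
                          censored=dth is None)


def predict_dth(env: EnvironmentSeries, params: DVRParams,
                cardinals: CardinalConstants | None = None,
                max_days: int = DEFAULT_MAX_DAYS) -> int | None:
    """Days to heading only (None when censored); fast path used in fitting."""
    c = cardinals or CardinalConstants()
    if len(env) < max_days:
        raise ValueError(
            f"environment {env.env_id} has {len(env)} days, needs >= {max_days}"
        )
    log_f, log_g = env.response_logs(c, max_days)
    return _dth_from_logs(log_f, log_g, params.alpha, params.beta, params.g_days)[2]
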