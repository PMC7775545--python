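"""Synthetic multi-environment rice heading studies with known ground truth.

The generator emulates the structure of a Japanese multi-location
heading-date trial: a panel of inbred cultivars genotyped at a small set
of heading-related markers, grown at several sites spanning the latitude
range of Japan over multiple years, with one sowing per site-year and
the days to heading (DTH) recorded as an integer.

The genetic architecture is additive on the DVR parameters: a handful of
large-effect markers act mostly on the photoperiod sensitivity beta
(echoing the observed spread between photoperiod-insensitive northern
and sensitive southern cultivars), with small effects on alpha and
moderate effects on G.  Weather is a latitude-dependent annual sinusoid
plus AR(1) noise; photoperiods are the CBM day lengths.  Sowing dates
alternate between mid-April and early June so that post-sowing windows
include both long and short days, which is what makes beta identifiable.

Every observation equals the DVR-model simulation under the genotype's
true parameters plus rounded Gaussian day-scale noise, so recovery can
be checked exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology import (
    DEFAULT_MAX_DAYS,
    CardinalConstants,
    DVRParams,
    EnvironmentSeries,
    day_length_series,
    predict_dth,
)
from .ml import MarkerMatrix

__all__ = [
    "TruthModel",
    "SyntheticStudy",
    "gen_sites",
    "gen_weather",
    "gen_marker_truth",
    "gen_observations",
    "generate_study",
]

#: April / June sowing days of year, alternated across years within a site.
SOWING_DOYS = (105, 155)
#: Days of weather generated after each sowing date.
SERIES_DAYS = 260


@dataclass
class TruthModel:
    """Additive marker -> parameter effect model with clipping."""

    intercepts: dict
    effects: pd.DataFrame  # marker x parameter per-dose effects
    clip: dict = field(default_factory=lambda: {
        "alpha": (0.0, 20.0), "beta": (0.0, 25.0), "g_days": (30.0, 120.0)})

    def params_for(self, codes: np.ndarray) -> pd.Series:
        """True parameters for one genotype's dose vector."""
        out = {}
        for name in ("alpha", "beta", "g_days"):
            v = self.intercepts[name] + float(codes @ self.effects[name].to_numpy())
            lo, hi = self.clip[name]
            out[name] = float(np.clip(v, lo, hi))
        return pd.Series(out)


@dataclass
class SyntheticStudy:
    sites: pd.DataFrame
    environments: dict            # env_id -> EnvironmentSeries
    markers: MarkerMatrix
    linkage_map: pd.DataFrame     # marker_id, chromosome, position_cm
    truth: TruthModel
    true_params: pd.DataFrame     # genotype x (alpha, beta, g_days)
    observations: pd.DataFrame    # genotype_id, env_id, dth
    env_locations: dict           # env_id -> location_id
    noise_sd: float
    seed: int
    n_censored: int = 0

    def observation_envs(self, genotype_id) -> list:
        rows = self.observations[self.observations.genotype_id == genotype_id]
        return [self.environments[e] for e in rows.env_id]


def gen_sites(n_sites: int, latitude_range=(31.0, 43.0),
              longitude_range=(129.0, 143.0), seed: int = 0) -> pd.DataFrame:
    """Site table with uniform latitudes across the configured span."""
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    lo, hi = latitude_range
    if not lo < hi:
        raise ValueError("empty latitude range")
    rng = np.random.default_rng(seed)
    # spread deterministically over the range, jittered, so small panels
    # still cover north and south
    base = np.linspace(lo, hi, n_sites)
    jitter = rng.uniform(-0.5, 0.5, n_sites) if n_sites > 1 else np.zeros(1)
    lats = np.clip(base + jitter, lo, hi)
    lons = rng.uniform(*longitude_range, n_sites)
    return pd.DataFrame({
        "location_id": [f"L{i + 1:02d}" for i in range(n_sites)],
        "latitude": lats,
        "longitude": lons,
    })


def gen_weather(latitude: float, year: int, sowing_doy: int, seed: int = 0,
                n_days: int = SERIES_DAYS, noise_sd: float = 1.5,
                rho: float = 0.7) -> np.ndarray:
    """Daily mean temperatures from the sowing day onward.

    Annual sinusoid (mean ~14-18 degC, amplitude ~10-14 degC depending
    on latitude, peak near day of year 210) plus stationary AR(1) noise.
    """
    rng = np.random.default_rng(seed)
    doys = sowing_doy + np.arange(n_days)
    mean_t = 27.0 - 0.3 * latitude                  # 17.7 at 31N .. 14.1 at 43N
    amp = 10.0 + 4.0 * (latitude - 31.0) / 12.0     # 10 .. 14
    temps = mean_t + amp * np.cos(2 * np.pi * (doys - 210) / 365.25)
    if noise_sd > 0:
        innov_sd = noise_sd * np.sqrt(1 - rho ** 2)
        e = np.empty(n_days)
        e[0] = rng.normal(0, noise_sd)
        for i in range(1, n_days):
            e[i] = rho * e[i - 1] + rng.normal(0, innov_sd)
        temps = temps + e
    return temps


def _make_environment(site_row, year: int, sowing_doy: int, seed: int) -> EnvironmentSeries:
    lat = float(site_row.latitude)
    temps = gen_weather(lat, year, sowing_doy, seed=seed)
    doys = (sowing_doy - 1 + np.arange(SERIES_DAYS)) % 365 + 1
    photos = day_length_series(lat, doys)
    sowing = dt.date(year, 1, 1) + dt.timedelta(days=sowing_doy - 1)
    env_id = f"{site_row.location_id}:{year}:{sowing.isoformat()}"
    return EnvironmentSeries(env_id=env_id, latitude=lat,
                             longitude=float(site_row.longitude),
                             sowing_date=sowing, temperatures=temps,
                             photoperiods=photos)


def gen_marker_truth(n_genotypes: int, n_markers: int = 14,
                     n_large_effects: int = 5, n_chromosomes: int = 5,
                     seed: int = 0):
    """Inbred marker panel, linkage map, effect model and true parameters.

    Codes are 0/2 only (fully inbred lines), so any two genotypes can
    seed an F2 cross; heterozygotes appear only in simulated progeny.
    """
    if n_genotypes < 2:
        raise ValueError("need at least 2 genotypes")
    if n_large_effects > n_markers:
        raise ValueError("n_large_effects cannot exceed n_markers")
    rng = np.random.default_rng(seed)
    genotype_ids = [f"G{i + 1:03d}" for i in range(n_genotypes)]
    marker_ids = [f"M{j + 1:02d}" for j in range(n_markers)]

    freqs = rng.uniform(0.3, 0.7, n_markers)
    codes = 2.0 * (rng.random((n_genotypes, n_markers)) < freqs)
    markers = MarkerMatrix(genotype_ids, marker_ids, codes)

    chroms = np.sort(rng.integers(1, n_chromosomes + 1, n_markers))
    positions = np.empty(n_markers)
    pos = 0.0
    prev = None
    for j in range(n_markers):
        pos = 0.0 if chroms[j] != prev else pos + rng.uniform(5.0, 20.0)
        positions[j] = pos
        prev = chroms[j]
    linkage_map = pd.DataFrame({
        "marker_id": marker_ids,
        "chromosome": [f"chr{c}" for c in chroms],
        "position_cm": positions,
    })

    large = rng.choice(n_markers, n_large_effects, replace=False)
    eff = pd.DataFrame(0.0, index=marker_ids, columns=["alpha", "beta", "g_days"])
    signs = rng.choice([-1.0, 1.0], n_large_effects)
    eff.iloc[large, eff.columns.get_loc("beta")] = signs * rng.uniform(
        0.4, 1.5, n_large_effects)
    eff["alpha"] = rng.uniform(-0.1, 0.1, n_markers)
    eff.iloc[large, eff.columns.get_loc("g_days")] = rng.uniform(
        -4.0, 4.0, n_large_effects)
    truth = TruthModel(intercepts={"alpha": 1.0, "beta": 3.0, "g_days": 55.0},
                       effects=eff)

    true_params = pd.DataFrame(
        [truth.params_for(codes[i]) for i in range(n_genotypes)],
        index=genotype_ids)
    return markers, linkage_map, truth, true_params


def gen_observations(true_params: pd.DataFrame, environments: dict,
                     n_envs_per_genotype: int | None = None,
                     noise_sd: float = 1.0, seed: int = 0,
                     cardinals: CardinalConstants | None = None,
                     max_days: int = DEFAULT_MAX_DAYS) -> tuple[pd.DataFrame, int]:
    """Noisy integer DTH per (genotype, environment); censored cases dropped.

    Returns the observation table and the count of censored simulations.
    """
    env_ids = sorted(environments)
    if n_envs_per_genotype is not None and n_envs_per_genotype > len(env_ids):
        raise ValueError("fewer environments available than requested")
    rng = np.random.default_rng(seed)
    rows = []
    n_censored = 0
    for gid, p in true_params.iterrows():
        params = DVRParams(p.alpha, p.beta, p.g_days)
        if n_envs_per_genotype is None or n_envs_per_genotype == len(env_ids):
            chosen = env_ids
        else:
            chosen = sorted(rng.choice(env_ids, n_envs_per_genotype, replace=False))
        n_ok = 0
        for eid in chosen:
            dth = predict_dth(environments[eid], params, cardinals, max_days)
            if dth is None:
                n_censored += 1
                continue
            noisy = max(int(dth + round(rng.normal(0.0, noise_sd))), 1) \
                if noise_sd > 0 else dth
            rows.append((gid, eid, noisy))
            n_ok += 1
        if n_ok == 0:
            raise ValueError(
                f"genotype {gid}: every simulation was censored; the "
                "parameter/weather combination never reaches heading")
    obs = pd.DataFrame(rows, columns=["genotype_id", "env_id", "dth"])
    return obs, n_censored


def generate_study(n_genotypes: int = 100, n_sites: int = 5, n_years: int = 5,
                   n_envs_per_genotype: int | None = None, noise_sd: float = 1.0,
                   n_markers: int = 14, seed: int = 0,
                   start_year: int = 2010) -> SyntheticStudy:
    """Full study: sites, weather, markers, truth and observations.

    Defaults give 100 genotypes observed in 25 site-year environments
    (5 sites x 5 years, sowing alternating April/June by year within a
    site) with day-scale observation noise.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    sites = gen_sites(n_sites, seed=int(sub[0]))
    environments = {}
    env_locations = {}
    for si, site in enumerate(sites.itertuples(index=False)):
        for yi in range(n_years):
            year = start_year + yi
            sowing_doy = SOWING_DOYS[(si + yi) % len(SOWING_DOYS)]
            env = _make_environment(site, year, sowing_doy,
                                    seed=int(sub[1]) + 1000 * si + yi)
            environments[env.env_id] = env
            env_locations[env.env_id] = site.location_id
    markers, linkage_map, truth, true_params = gen_marker_truth(
        n_genotypes, n_markers=n_markers, seed=int(sub[2]))
    observations, n_censored = gen_observations(
        true_params, environments, n_envs_per_genotype=n_envs_per_genotype,
        noise_sd=noise_sd, seed=int(sub[3]))
    return SyntheticStudy(sites=sites, environments=environments,
                          markers=markers, linkage_map=linkage_map, truth=truth,
                          true_params=true_params, observations=observations,
                          env_locations=env_locations, noise_sd=noise_sd,
                          seed=seed, n_censored=n_censored)
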