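"""CSV schemas, study bundle loading/validation, and run manifests.

All interchange is plain CSV with one header row (UTF-8, ISO-8601
dates).  Day indices are 0-based offsets from sowing (day 0 = the
sowing day) everywhere.

Schemas
-------
pheno.csv    genotype_id, env_id, sowing_date, dth
weather.csv  location_id, date, tavg_c
sites.csv    location_id, latitude, longitude
markers.csv  genotype_id, <marker_id> ... (wide; codes 0/1/2, blank = missing)
map.csv      marker_id, chromosome, position_cm
params.csv   genotype_id, alpha_mean, ..., rhat_g, acceptance_rate (output)

An ``env_id`` is ``<location_id>:<label>`` -- the prefix before the
first colon must resolve to a site, and the weather table must cover a
gap-free window from each environment's sowing date.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ml import MarkerMatrix
from .phenology import EnvironmentSeries, day_length_series

__all__ = [
    "StudyBundle",
    "load_bundle",
    "write_study",
    "write_manifest",
    "read_markers",
    "read_linkage_map",
]

#: Days of weather required after each sowing date.
WINDOW_DAYS = 260


class SchemaError(ValueError):
    """A table does not match its documented schema."""


class ReferenceError(ValueError):
    """A key in one table does not resolve in another."""


@dataclass
class StudyBundle:
    pheno: pd.DataFrame
    sites: pd.DataFrame
    markers: MarkerMatrix
    linkage_map: pd.DataFrame | None
    environments: dict          # env_id -> EnvironmentSeries
    env_locations: dict         # env_id -> location_id
    warnings: list = field(default_factory=list)

    @property
    def observations(self) -> pd.DataFrame:
        return self.pheno[["genotype_id", "env_id", "dth"]]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_markers(path) -> MarkerMatrix:
    df = pd.read_csv(path)
    _require_columns(df, ["genotype_id"], path)
    marker_ids = [c for c in df.columns if c != "genotype_id"]
    if not marker_ids:
        raise SchemaError(f"{path}: no marker columns")
    return MarkerMatrix(df.genotype_id.astype(str).tolist(), marker_ids,
                        df[marker_ids].to_numpy(dtype=float))


def read_linkage_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["marker_id", "chromosome", "position_cm"], path)
    if df.marker_id.duplicated().any():
        dup = df.marker_id[df.marker_id.duplicated()].tolist()
        raise SchemaError(f"{path}: duplicate marker ids {dup}")
    for chrom, sub in df.groupby("chromosome"):
        if (sub.position_cm.diff().dropna() < 0).any():
            raise SchemaError(
                f"{path}: positions on {chrom} are not non-decreasing")
    return df


def _build_environment(env_id: str, sowing: dt.date, site_row,
                       weather_by_loc: dict, weather_path) -> EnvironmentSeries:
    loc = site_row.location_id
    w = weather_by_loc[loc]
    dates = pd.date_range(sowing, periods=WINDOW_DAYS)
    series = w.reindex(dates)
    if series.isna().any():
        gaps = [d.date().isoformat() for d in dates[series.isna()]][:10]
        raise SchemaError(
            f"{weather_path}: weather gap for {loc} inside the "
            f"{WINDOW_DAYS}-day window from {sowing}: missing {gaps}"
            + (" ..." if series.isna().sum() > 10 else ""))
    doys = np.array([d.timetuple().tm_yday for d in dates])
    photos = day_length_series(float(site_row.latitude), doys)
    return EnvironmentSeries(env_id=env_id, latitude=float(site_row.latitude),
                             longitude=float(site_row.longitude),
                             sowing_date=sowing,
                             temperatures=series.to_numpy(dtype=float),
                             photoperiods=photos)


def load_bundle(pheno_path, weather_path, sites_path, markers_path,
                map_path=None) -> StudyBundle:
    """Load and cross-validate the five study tables.

    Checks referential integrity (every env resolves to a site with
    gap-free weather; every genotype has a marker row), rejects
    duplicate (genotype, env) observations, and parses dates strictly.
    """
    pheno = pd.read_csv(pheno_path)
    _require_columns(pheno, ["genotype_id", "env_id", "sowing_date", "dth"], pheno_path)
    pheno["genotype_id"] = pheno.genotype_id.astype(str)
    try:
        pheno["sowing_date"] = pd.to_datetime(pheno.sowing_date,
                                              format="%Y-%m-%d").dt.date
    except ValueError as err:
        raise SchemaError(f"{pheno_path}: unparseable sowing_date ({err})") from None
    if not np.issubdtype(pheno.dth.dtype, np.number) or (pheno.dth < 1).any():
        raise SchemaError(f"{pheno_path}: dth must be a positive day count")
    dup = pheno.duplicated(["genotype_id", "env_id"])
    if dup.any():
        rows = (pheno.index[dup] + 2).tolist()  # header + 1-based
        raise SchemaError(f"{pheno_path}: duplicate (genotype_id, env_id) at "
                          f"rows {rows}")

    sites = pd.read_csv(sites_path)
    _require_columns(sites, ["location_id", "latitude", "longitude"], sites_path)
    site_by_id = {r.location_id: r for r in sites.itertuples(index=False)}

    weather = pd.read_csv(weather_path)
    _require_columns(weather, ["location_id", "date", "tavg_c"], weather_path)
    if weather.tavg_c.isna().any() or ~np.isfinite(weather.tavg_c).all():
        raise SchemaError(f"{weather_path}: non-finite temperatures")
    weather["date"] = pd.to_datetime(weather.date, format="%Y-%m-%d")
    weather_by_loc = {loc: sub.set_index("date").tavg_c
                      for loc, sub in weather.groupby("location_id")}

    markers = read_markers(markers_path)
    linkage_map = read_linkage_map(map_path) if map_path else None

    warnings: list = []
    no_marker = sorted(set(pheno.genotype_id) - set(markers.genotype_ids))
    if no_marker:
        raise ReferenceError(
            f"{pheno_path}: genotypes with no marker row: {no_marker}")

    environments, env_locations = {}, {}
    env_rows = pheno.drop_duplicates("env_id")
    for r in env_rows.itertuples():
        loc = r.env_id.split(":", 1)[0]
        if loc not in site_by_id:
            raise ReferenceError(
                f"{pheno_path} row {r.Index + 2}: env_id {r.env_id!r} does not "
                f"resolve to a site (unknown location {loc!r})")
        if loc not in weather_by_loc:
            raise ReferenceError(
                f"{weather_path}: no weather rows for location {loc!r} "
                f"referenced by env {r.env_id!r}")
        environments[r.env_id] = _build_environment(
            r.env_id, r.sowing_date, site_by_id[loc], weather_by_loc,
            weather_path)
        env_locations[r.env_id] = loc
    mixed = pheno.groupby("env_id").sowing_date.nunique()
    if (mixed > 1).any():
        raise SchemaError(f"{pheno_path}: env ids with conflicting sowing "
                          f"dates: {mixed[mixed > 1].index.tolist()}")
    return StudyBundle(pheno=pheno, sites=sites, markers=markers,
                       linkage_map=linkage_map, environments=environments,
                       env_locations=env_locations, warnings=warnings)


# ---------------------------------------------------------------------------
# Writers


def write_study(study, outdir) -> dict:
    """Write a synthetic study as the five interchange CSVs; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.csv"
             for k in ("pheno", "weather", "sites", "markers", "map")}

    study.sites.to_csv(paths["sites"], index=False)

    wrows = []
    seen = set()
    for env in study.environments.values():
        loc = study.env_locations[env.env_id]
        for i, t in enumerate(env.temperatures):
            date = env.sowing_date + dt.timedelta(days=i)
            key = (loc, date)
            if key not in seen:
                seen.add(key)
                wrows.append((loc, date.isoformat(), t))
    pd.DataFrame(wrows, columns=["location_id", "date", "tavg_c"]) \
        .sort_values(["location_id", "date"]).to_csv(paths["weather"], index=False)

    pheno = study.observations.copy()
    pheno["sowing_date"] = pheno.env_id.map(
        {e: env.sowing_date.isoformat() for e, env in study.environments.items()})
    pheno[["genotype_id", "env_id", "sowing_date", "dth"]] \
        .to_csv(paths["pheno"], index=False)

    mdf = study.markers.to_frame().rename_axis("genotype_id").reset_index()
    mdf.to_csv(paths["markers"], index=False)
    study.linkage_map.to_csv(paths["map"], index=False)
    return paths


def write_manifest(path, inputs: dict, config: dict, seed: int | None) -> None:
    """Reproducibility manifest written beside every CLI output."""
    import phenobridge

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "config_sha256": digest,
        "seed": seed,
        "versions": {
            "phenobridge": phenobridge.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
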