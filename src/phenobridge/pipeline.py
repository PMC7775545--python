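"""Integrated genotype-to-phenotype prediction and cross-validated comparison.

The two-step route: (1a) calibrate the DVR parameters (alpha, beta, G)
per genotype by DREAM; (1b) regress the calibrated parameters on marker
dummies; (2) predict a genotype's parameters from its markers and run
the crop model in the target environment.  Compared against the bare
crop model and against direct machine-learning regression of DTH on
environment + marker features, under three cross-validation schemes:

fivefold
    random partition of observations, stratified by genotype (tested
    genotypes in tested locations: the interpolation scenario).
logo
    leave one genotype out: the test genotype's rows never enter
    training (new genotype, tested locations).
loglo
    leave one genotype and one location out: training excludes all rows
    of the test genotype *and* of the test location (new genotype in a
    new location: the extrapolation scenario).

Method-scheme combinations follow the study design: the bare crop model
is evaluated only under fivefold (it needs the target genotype's own
data), the integrated methods only under LOGO/LOGLO, direct machine
learning under all three.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dream import DreamConfig, PriorSpec, fit_genotype
from .ml import (
    MarkerMatrix,
    ParamBridge,
    build_direct_features,
    encode_markers,
    predict_direct_dth,
    train_direct_dth,
    train_param_regressor,
)
from .phenology import CardinalConstants, DVRParams, EnvironmentSeries, predict_dth

__all__ = [
    "Fold",
    "EvalMetrics",
    "CvResult",
    "ComparisonConfig",
    "salted_seed",
    "estimate_all_genotype_params",
    "predict_dth_integrated",
    "make_folds",
    "evaluate",
    "run_comparison",
]

DIRECT_METHODS = ("direct_elm", "direct_rf", "direct_xgb")
INTEGRATED_METHODS = ("integrated_elm", "integrated_rf", "integrated_xgb")
ALL_METHODS = ("dvr",) + DIRECT_METHODS + INTEGRATED_METHODS

#: Valid method -> scheme combinations (study design).
ALLOWED_SCHEMES = {
    "dvr": ("fivefold",),
    **{m: ("fivefold", "logo", "loglo") for m in DIRECT_METHODS},
    **{m: ("logo", "loglo") for m in INTEGRATED_METHODS},
}


def salted_seed(master_seed: int, *salt) -> int:
    """Deterministic sub-seed below 2**31 derived from a master seed."""
    tag = ":".join(str(s) for s in salt)
    return (int(master_seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class Fold:
    name: str
    train_index: np.ndarray
    test_index: np.ndarray


@dataclass
class EvalMetrics:
    rmse: float
    cor: float
    md: float
    n: int


@dataclass
class CvResult:
    scheme: str
    method: str
    predictions: pd.DataFrame  # fold, genotype_id, env_id, observed, predicted
    rmse: float
    cor: float
    md: float
    n_censored: int = 0


@dataclass
class ComparisonConfig:
    dream: DreamConfig = field(default_factory=DreamConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    cardinals: CardinalConstants = field(default_factory=CardinalConstants)
    hyper: dict | None = None
    k_folds: int = 5
    max_days: int = 200
    seed: int = 0


# ---------------------------------------------------------------------------
# Step 1a: per-genotype calibration


def estimate_all_genotype_params(obs: pd.DataFrame, environments: dict,
                                 prior: PriorSpec | None = None,
                                 config: DreamConfig | None = None,
                                 cardinals: CardinalConstants | None = None,
                                 master_seed: int = 0,
                                 rhat_threshold: float = 1.2) -> pd.DataFrame:
    """DREAM posterior-mean parameters for every genotype in ``obs``.

    Each genotype gets an independent run with a genotype-salted seed.
    Genotypes whose Gelman-Rubin statistic exceeds ``rhat_threshold`` on
    any parameter are flagged (column ``flagged``), not dropped.
    """
    prior = prior or PriorSpec()
    config = config or DreamConfig()
    rows = {}
    for gid, sub in obs.groupby("genotype_id", sort=True):
        missing = [e for e in sub.env_id if e not in environments]
        if missing:
            raise KeyError(f"genotype {gid}: unknown environments {missing}")
        envs = [environments[e] for e in sub.env_id]
        cfg = replace(config, seed=salted_seed(master_seed, "dream", gid))
        post = fit_genotype(sub.dth.to_numpy(), envs, prior, cfg, cardinals)
        rows[gid] = {
            "alpha": post.mean[0], "beta": post.mean[1], "g_days": post.mean[2],
            "alpha_median": post.median[0], "beta_median": post.median[1],
            "g_days_median": post.median[2],
            "alpha_mode": post.mode[0], "beta_mode": post.mode[1],
            "g_days_mode": post.mode[2],
            "rhat_alpha": post.rhat[0], "rhat_beta": post.rhat[1],
            "rhat_g": post.rhat[2],
            "acceptance_rate": post.acceptance_rate,
            "flagged": bool(np.nanmax(post.rhat) > rhat_threshold),
        }
    if not rows:
        raise ValueError("no observations to estimate from")
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("genotype_id")


# ---------------------------------------------------------------------------
# Step 2: integrated prediction


def predict_dth_integrated(markers: MarkerMatrix, env: EnvironmentSeries,
                           bridge: ParamBridge,
                           cardinals: CardinalConstants | None = None,
                           max_days: int = 200) -> np.ndarray:
    """Marker -> parameters -> crop model DTH for every genotype row.

    Returns one value per genotype; censored simulations (no heading
    within ``max_days``) are NaN.
    """
    P = bridge.predict_params(markers)
    out = np.empty(len(P))
    for i, (gid, p) in enumerate(P.iterrows()):
        dth = predict_dth(env, DVRParams(p.alpha, p.beta, p.g_days),
                          cardinals, max_days)
        out[i] = np.nan if dth is None else dth
    return out


# ---------------------------------------------------------------------------
# Cross-validation machinery


def make_folds(obs: pd.DataFrame, scheme: str, k: int = 5, seed: int = 0,
               env_locations: dict | None = None) -> list[Fold]:
    """Fold assignments for one CV scheme.

    fivefold: random k-way partition of observations stratified by
    genotype (each genotype's rows are dealt round-robin across folds).
    logo: one fold per genotype; training excludes that genotype.
    loglo: one fold per observed (genotype, location) pair; training
    excludes every row of that genotype and every row at that location
    (``env_locations`` maps env_id -> location_id).
    """
    if obs.empty:
        raise ValueError("no observations to split")
    idx = obs.index.to_numpy()
    if scheme == "fivefold":
        rng = np.random.default_rng(seed)
        assign = pd.Series(-1, index=obs.index)
        for _, sub in obs.groupby("genotype_id", sort=True):
            rows = sub.index.to_numpy()
            rng.shuffle(rows)
            start = int(rng.integers(k))
            for pos, r in enumerate(rows):
                assign[r] = (start + pos) % k
        return [Fold(name=f"fold{f + 1}",
                     train_index=idx[(assign != f).to_numpy()],
                     test_index=idx[(assign == f).to_numpy()])
                for f in range(k)]
    if scheme == "logo":
        folds = []
        for gid, sub in obs.groupby("genotype_id", sort=True):
            test = sub.index.to_numpy()
            train = obs.index[obs.genotype_id != gid].to_numpy()
            folds.append(Fold(name=f"logo:{gid}", train_index=train,
                              test_index=test))
        return folds
    if scheme == "loglo":
        if env_locations is None:
            raise ValueError("loglo folds require an env_id -> location map")
        loc = obs.env_id.map(env_locations)
        if loc.isna().any():
            bad = sorted(obs.env_id[loc.isna()].unique().tolist())
            raise ValueError(f"environments missing from the location map: {bad}")
        folds = []
        for (gid, lid), sub in obs.groupby([obs.genotype_id, loc], sort=True):
            test = sub.index.to_numpy()
            keep = (obs.genotype_id != gid) & (loc != lid)
            folds.append(Fold(name=f"loglo:{gid}:{lid}",
                              train_index=obs.index[keep].to_numpy(),
                              test_index=test))
        return folds
    raise ValueError(f"unknown cross-validation scheme {scheme!r}")


def evaluate(predicted, observed) -> EvalMetrics:
    """RMSE, Pearson correlation and mean absolute difference.

    Correlation is NaN when either vector has zero variance or fewer
    than two pairs are available.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 1:
        raise ValueError("predicted and observed must be equally long, non-empty")
    d = p - o
    rmse = float(np.sqrt(np.mean(d**2)))
    md = float(np.mean(np.abs(d)))
    if p.size >= 2 and p.std() > 0 and o.std() > 0:
        cor = float(np.corrcoef(p, o)[0, 1])
    else:
        cor = float("nan")
    return EvalMetrics(rmse=rmse, cor=cor, md=md, n=p.size)


# ---------------------------------------------------------------------------
# Method comparison


def _marker_subset(markers: MarkerMatrix, genotype_ids) -> MarkerMatrix:
    rows = [markers.genotype_ids.index(g) for g in genotype_ids]
    return MarkerMatrix(list(genotype_ids), list(markers.marker_ids),
                        markers.codes[rows])


def _direct_design(obs: pd.DataFrame, environments: dict, dummies: pd.DataFrame
                   ) -> np.ndarray:
    rows = [build_direct_features(environments[r.env_id],
                                  dummies.loc[r.genotype_id].to_numpy())
            for r in obs.itertuples(index=False)]
    return np.vstack(rows)


def _predict_dvr_fivefold(obs, environments, folds, cfg: ComparisonConfig):
    """Bare crop model under fivefold: per-fold, per-genotype calibration
    on training rows only, then simulation of the test rows."""
    pred = pd.Series(np.nan, index=obs.index)
    fold_of = pd.Series("", index=obs.index)
    for fold in folds:
        train = obs.loc[fold.train_index]
        params = estimate_all_genotype_params(
            train, environments, cfg.prior, cfg.dream, cfg.cardinals,
            master_seed=salted_seed(cfg.seed, "dvr", fold.name))
        for r in obs.loc[fold.test_index].itertuples():
            fold_of[r.Index] = fold.name
            if r.genotype_id not in params.index:
                continue  # genotype absent from training: left NaN
            p = params.loc[r.genotype_id]
            dth = predict_dth(environments[r.env_id],
                              DVRParams(p.alpha, p.beta, p.g_days),
                              cfg.cardinals, cfg.max_days)
            pred[r.Index] = np.nan if dth is None else dth
    return pred, fold_of


def _predict_direct(obs, environments, markers, folds, method, cfg):
    design, enc = encode_markers(markers)
    dummies = pd.DataFrame(design, index=markers.genotype_ids)
    X = _direct_design(obs, environments, dummies)
    y = obs.dth.to_numpy(dtype=float)
    pos = {ix: i for i, ix in enumerate(obs.index)}
    pred = pd.Series(np.nan, index=obs.index)
    fold_of = pd.Series("", index=obs.index)
    base = method.split("_", 1)[1]
    for fold in folds:
        tr = [pos[i] for i in fold.train_index]
        te = [pos[i] for i in fold.test_index]
        model = train_direct_dth(X[tr], y[tr], enc, method=base,
                                 seed=salted_seed(cfg.seed, method, fold.name),
                                 hyper=cfg.hyper)
        pred.iloc[te] = predict_direct_dth(model, X[te])
        fold_of.iloc[te] = fold.name
    return pred, fold_of


def _predict_integrated(obs, environments, markers, folds, method, scheme,
                        cfg: ComparisonConfig, env_locations):
    """Two-step route under LOGO/LOGLO.

    Parameters of training genotypes are estimated from training rows
    only: for LOGO these are simply each genotype's own rows (removing
    the test genotype does not change them); for LOGLO they are
    re-estimated with the test location's rows removed, cached per
    left-out location.
    """
    base = method.split("_", 1)[1]
    pred = pd.Series(np.nan, index=obs.index)
    fold_of = pd.Series("", index=obs.index)
    params_cache: dict = {}

    def params_for(location_excluded):
        if location_excluded not in params_cache:
            if location_excluded is None:
                train = obs
            else:
                loc = obs.env_id.map(env_locations)
                train = obs[loc != location_excluded]
            params_cache[location_excluded] = estimate_all_genotype_params(
                train, environments, cfg.prior, cfg.dream, cfg.cardinals,
                master_seed=salted_seed(cfg.seed, "step1a",
                                        location_excluded or "all"))
        return params_cache[location_excluded]

    for fold in folds:
        test = obs.loc[fold.test_index]
        gid = test.genotype_id.iloc[0]
        loc_excluded = (fold.name.rsplit(":", 1)[1] if scheme == "loglo" else None)
        params = params_for(loc_excluded)
        train_gids = [g for g in sorted(obs.loc[fold.train_index]
                                        .genotype_id.unique())
                      if g in params.index]
        bridge = train_param_regressor(
            _marker_subset(markers, train_gids),
            params.loc[train_gids, ["alpha", "beta", "g_days"]],
            method=base, seed=salted_seed(cfg.seed, method, fold.name),
            hyper=cfg.hyper)
        test_markers = _marker_subset(markers, [gid])
        for env_id, sub in test.groupby("env_id"):
            val = predict_dth_integrated(test_markers, environments[env_id],
                                         bridge, cfg.cardinals, cfg.max_days)[0]
            pred[sub.index] = val
            fold_of[sub.index] = fold.name
    return pred, fold_of


def run_comparison(obs: pd.DataFrame, environments: dict, markers: MarkerMatrix,
                   methods, schemes, cfg: ComparisonConfig | None = None,
                   env_locations: dict | None = None) -> list[CvResult]:
    """Cross-validated RMSE comparison of the requested methods.

    Raises on a method-scheme combination the study design forbids
    (e.g. the bare crop model under LOGO: the crop model requires the
    data of the target genotype to estimate its parameters).
    """
    cfg = cfg or ComparisonConfig()
    results = []
    for scheme in schemes:
        for method in methods:
            if method not in ALL_METHODS:
                raise ValueError(f"unknown method {method!r}")
            if scheme not in ALLOWED_SCHEMES[method]:
                raise ValueError(
                    f"method {method!r} is not evaluated under {scheme!r}: "
                    "the crop model requires the data of the target genotype"
                    if method == "dvr" else
                    f"method {method!r} is not evaluated under {scheme!r} "
                    "in the study design")
    for scheme in schemes:
        folds = make_folds(obs, scheme, k=cfg.k_folds,
                           seed=salted_seed(cfg.seed, "folds", scheme),
                           env_locations=env_locations)
        for method in methods:
            if method == "dvr":
                pred, fold_of = _predict_dvr_fivefold(obs, environments, folds, cfg)
            elif method in DIRECT_METHODS:
                pred, fold_of = _predict_direct(obs, environments, markers,
                                                folds, method, cfg)
            else:
                pred, fold_of = _predict_integrated(obs, environments, markers,
                                                    folds, method, scheme, cfg,
                                                    env_locations)
            table = pd.DataFrame({
                "fold": fold_of, "genotype_id": obs.genotype_id,
                "env_id": obs.env_id, "observed": obs.dth,
                "predicted": pred,
            })
            ok = table.predicted.notna()
            m = evaluate(table.predicted[ok], table.observed[ok])
            results.append(CvResult(scheme=scheme, method=method,
                                    predictions=table, rmse=m.rmse, cor=m.cor,
                                    md=m.md, n_censored=int((~ok).sum())))
    return results
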