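"""Machine-learning bridge between marker genotypes and heading phenology.

Two uses share this module:

* the two-step ("integrated") route, where regressors map marker dummies
  to the calibrated DVR parameters (alpha, beta, G) of each genotype,
  which are then fed back into the crop model; and
* the direct route, where a single regressor maps environment features
  (200 daily temperatures from sowing plus the photoperiod at day
  offsets 0/100/200) and marker dummies straight to days to heading.

Back-ends: an extreme learning machine (ELM) written from its
definition -- random fixed hidden layer, least-squares readout -- plus
random forest and gradient boosting delegated to scikit-learn with the
study's hyperparameters (RF: 500 trees, mtry = p/3; boosting: depth 6,
learning rate 0.1, 200 rounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .phenology import EnvironmentSeries

__all__ = [
    "MarkerMatrix",
    "MarkerEncoder",
    "encode_markers",
    "ElmModel",
    "elm_train",
    "elm_predict",
    "ParamBridge",
    "train_param_regressor",
    "build_direct_features",
    "DirectModel",
    "train_direct_dth",
    "predict_direct_dth",
]

#: Clip ranges for bridged parameter predictions (calibration box).
PARAM_RANGES = {"alpha": (0.0, 20.0), "beta": (0.0, 25.0), "g_days": (30.0, 120.0)}

#: Length of the daily-temperature feature window (day offsets 0..199).
TEMP_WINDOW = 200
#: Day offsets at which the photoperiod is sampled (0 = sowing day).
PHOTOPERIOD_OFFSETS = (0, 100, 200)


@dataclass
class MarkerMatrix:
    """Biallelic marker codes per genotype: 0/2 homozygous, 1 heterozygous.

    Missing values are NaN and are imputed to the marker's most frequent
    level at encoding time.
    """

    genotype_ids: list
    marker_ids: list
    codes: np.ndarray  # genotype x marker, float (NaN = missing)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match id lists")
        seen = self.codes[~np.isnan(self.codes)]
        if not np.isin(seen, [0.0, 1.0, 2.0]).all():
            raise ValueError("marker codes must be in {0, 1, 2} or missing")

    def row(self, genotype_id) -> np.ndarray:
        return self.codes[self.genotype_ids.index(genotype_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.genotype_ids,
                            columns=self.marker_ids)


@dataclass
class MarkerEncoder:
    """Full one-hot dummy coding of marker levels, reusable on new genotypes.

    Levels are those observed at fit time; a level unseen in training
    (e.g. a heterozygote among inbred training lines) maps to all-zero
    dummies for that marker.
    """

    marker_ids: list = field(default_factory=list)
    levels: dict = field(default_factory=dict)
    column_names: list = field(default_factory=list)

    def fit(self, m: MarkerMatrix) -> "MarkerEncoder":
        self.marker_ids = list(m.marker_ids)
        self.levels = {}
        self.column_names = []
        for j, mid in enumerate(m.marker_ids):
            col = m.codes[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                raise ValueError(f"marker {mid!r} has no observed genotypes")
            levs = sorted(set(obs.tolist()))
            self.levels[mid] = levs
            self.column_names += [f"{mid}:{int(v)}" for v in levs]
        return self

    def transform(self, m: MarkerMatrix) -> np.ndarray:
        if list(m.marker_ids) != self.marker_ids:
            raise ValueError("marker set differs from the one used to fit")
        n = len(m.genotype_ids)
        out = np.zeros((n, len(self.column_names)))
        pos = 0
        for j, mid in enumerate(self.marker_ids):
            col = m.codes[:, j].copy()
            if np.isnan(col).any():
                obs = col[~np.isnan(col)]
                if obs.size == 0:
                    raise ValueError(f"marker {mid!r} has no observed genotypes")
                vals, counts = np.unique(obs, return_counts=True)
                col[np.isnan(col)] = vals[np.argmax(counts)]
            for v in self.levels[mid]:
                out[:, pos] = (col == v).astype(float)
                pos += 1
        return out

    def fit_transform(self, m: MarkerMatrix) -> np.ndarray:
        return self.fit(m).transform(m)


def encode_markers(m: MarkerMatrix):
    """One-hot marker design matrix and the fitted encoder.

    Each marker expands to one indicator column per observed level;
    missing codes are imputed to the marker's modal level first.
    """
    enc = MarkerEncoder()
    return enc.fit_transform(m), enc


# ---------------------------------------------------------------------------
# Extreme learning machine


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class ElmModel:
    input_weights: np.ndarray   # n_features x n_hidden
    hidden_bias: np.ndarray     # n_hidden
    output_weights: np.ndarray  # n_hidden + 1 (readout intercept first)
    center: np.ndarray
    scale: np.ndarray
    seed: int

    def hidden(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.center) / self.scale
        return _sigmoid(Xs @ self.input_weights + self.hidden_bias)


def elm_train(X: np.ndarray, y: np.ndarray, n_hidden: int = 100,
              seed: int = 0) -> ElmModel:
    """Fit an ELM: random uniform[-1,1] hidden layer, least-squares readout.

    Features are centred and scaled first (random projections are
    scale-sensitive); the readout solves the minimum-norm least-squares
    problem, so with n_hidden >= n_samples the training data are
    interpolated.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be at least 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ValueError("X must be 2-D with one target per row (>= 2 rows)")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    model = ElmModel(W, b, np.zeros(n_hidden + 1), center, scale, seed)
    H = model.hidden(X)
    design = np.column_stack([np.ones(H.shape[0]), H])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    model.output_weights = beta
    return model


def elm_predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_weights.shape[0]:
        raise ValueError(
            f"expected {model.input_weights.shape[0]} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    H = model.hidden(X)
    return np.column_stack([np.ones(H.shape[0]), H]) @ model.output_weights


# ---------------------------------------------------------------------------
# Uniform regressor abstraction


class _ElmRegressor:
    """sklearn-style wrapper so all back-ends share fit/predict."""

    def __init__(self, n_hidden: int = 100, seed: int = 0):
        self.n_hidden = n_hidden
        self.seed = seed
        self.model_: ElmModel | None = None

    def fit(self, X, y):
        self.model_ = elm_train(X, y, n_hidden=self.n_hidden, seed=self.seed)
        return self

    def predict(self, X):
        return elm_predict(self.model_, X)


def _make_regressor(method: str, seed: int, n_features: int, hyper: dict | None):
    hyper = dict(hyper or {})
    if method == "elm":
        return _ElmRegressor(n_hidden=hyper.pop("n_hidden", 100), seed=seed)
    if method == "rf":
        return RandomForestRegressor(
            n_estimators=hyper.pop("n_estimators", 500),
            max_features=hyper.pop("max_features", max(n_features // 3, 1)),
            random_state=seed,
        )
    if method == "xgb":
        # gradient tree boosting with the study's settings
        return GradientBoostingRegressor(
            max_depth=hyper.pop("max_depth", 6),
            learning_rate=hyper.pop("learning_rate", 0.1),
            n_estimators=hyper.pop("n_estimators", 200),
            random_state=seed,
        )
    raise ValueError(f"unknown regression method {method!r}")


@dataclass
class ParamBridge:
    """Markers -> DVR parameters, one independent regressor per parameter.

    Predictions are clipped to the calibration box so the crop model is
    never handed a parameter outside its admissible range.
    """

    method: str
    encoder: MarkerEncoder
    models: dict = field(default_factory=dict)

    def predict_params(self, markers: MarkerMatrix) -> pd.DataFrame:
        X = self.encoder.transform(markers)
        out = {}
        for name, model in self.models.items():
            lo, hi = PARAM_RANGES[name]
            out[name] = np.clip(np.asarray(model.predict(X), dtype=float), lo, hi)
        return pd.DataFrame(out, index=markers.genotype_ids)


def train_param_regressor(markers: MarkerMatrix, params: pd.DataFrame,
                          method: str = "xgb", seed: int = 0,
                          hyper: dict | None = None) -> ParamBridge:
    """Fit the marker-to-parameter bridge on calibrated genotypes.

    ``params`` must have columns alpha, beta, g_days indexed by the
    genotypes of ``markers`` (order-aligned after reindexing).
    """
    P = params.reindex(markers.genotype_ids)
    if P.isna().any().any():
        missing = P.index[P.isna().any(axis=1)].tolist()
        raise ValueError(f"missing parameter rows for genotypes {missing}")
    if len(P) < 5:
        raise ValueError("at least 5 genotypes are required to train the bridge")
    X, enc = encode_markers(markers)
    bridge = ParamBridge(method=method, encoder=enc)
    for j, name in enumerate(("alpha", "beta", "g_days")):
        model = _make_regressor(method, seed + j, X.shape[1], hyper)
        model.fit(X, P[name].to_numpy())
        bridge.models[name] = model
    return bridge


# ---------------------------------------------------------------------------
# Direct environment + marker features


def build_direct_features(env: EnvironmentSeries, marker_dummies: np.ndarray
                          ) -> np.ndarray:
    """Feature vector for the direct DTH regression.

    Concatenates, in this order: 200 daily mean temperatures from the
    sowing day, the photoperiod at day offsets 0/100/200 (three
    representative days -- the photoperiod curve is smooth in latitude
    and date, so using all of it would be collinear), and the genotype's
    marker dummies.
    """
    if len(env) < PHOTOPERIOD_OFFSETS[-1] + 1:
        raise ValueError(
            f"environment {env.env_id} has {len(env)} days; "
            f">= {PHOTOPERIOD_OFFSETS[-1] + 1} are required"
        )
    temps = env.temperatures[:TEMP_WINDOW]
    photo = env.photoperiods[list(PHOTOPERIOD_OFFSETS)]
    return np.concatenate([temps, photo, np.asarray(marker_dummies, dtype=float)])


@dataclass
class DirectModel:
    method: str
    encoder: MarkerEncoder
    model: object

    def predict(self, rows: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(rows), dtype=float)


def train_direct_dth(features: np.ndarray, dth: np.ndarray, encoder: MarkerEncoder,
                     method: str = "xgb", seed: int = 0,
                     hyper: dict | None = None) -> DirectModel:
    """Single-stage DTH regressor on environment + marker features."""
    features = np.asarray(features, dtype=float)
    model = _make_regressor(method, seed, features.shape[1], hyper)
    model.fit(features, np.asarray(dth, dtype=float))
    return DirectModel(method=method, encoder=encoder, model=model)


def predict_direct_dth(model: DirectModel, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features, dtype=float))
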