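"""F2 progeny simulation over a linkage map and distribution comparison.

Progeny marker genotypes of an inbred x inbred cross are simulated by
meiosis of the F1: along each chromosome a gamete starts on either
parental haplotype with probability 1/2 and switches between adjacent
markers with the Haldane recombination fraction

    r = (1 - exp(-2 d / 100)) / 2

for a map distance of d centiMorgans (no crossover interference).
An F2 individual is the union of two independent F1 gametes.

The predicted days-to-heading distribution of a simulated population is
obtained by pushing every progeny through the marker -> parameter bridge
and the DVR model; predicted and observed populations are compared at
the 10/50/90th percentiles across populations (RMSE, Pearson
correlation, mean absolute difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ml import MarkerMatrix
from .phenology import CardinalConstants, EnvironmentSeries

__all__ = [
    "CrossSpec",
    "PercentileComparison",
    "haldane",
    "simulate_gamete",
    "simulate_f2",
    "predict_f2_distribution",
    "compare_percentiles",
]


@dataclass(frozen=True)
class CrossSpec:
    parent1_id: str
    parent2_id: str
    n_progeny: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be at least 1")


@dataclass
class PercentileComparison:
    percentiles: tuple
    observed: pd.DataFrame   # population x percentile
    predicted: pd.DataFrame
    rmse: pd.Series          # per percentile
    cor: pd.Series
    md: pd.Series


def haldane(d_cm) -> np.ndarray | float:
    """Haldane map function: cM distance -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _map_groups(linkage_map: pd.DataFrame, marker_ids: list):
    """Per-chromosome marker index lists (map order) and switch probabilities."""
    lm = linkage_map.set_index("marker_id")
    missing = [m for m in marker_ids if m not in lm.index]
    if missing:
        raise ValueError(f"markers absent from the linkage map: {missing}")
    groups = []
    for _, sub in lm.loc[marker_ids].groupby("chromosome", sort=True):
        sub = sub.sort_values("position_cm")
        idx = [marker_ids.index(m) for m in sub.index]
        r = haldane(np.diff(sub["position_cm"].to_numpy()))
        groups.append((idx, np.atleast_1d(r)))
    return groups


def simulate_gamete(hap1: np.ndarray, hap2: np.ndarray, groups, rng) -> np.ndarray:
    """One haploid gamete from a fully phased diploid.

    ``hap1``/``hap2`` are allele vectors (0/1) over all markers; ``groups``
    is the output of the per-chromosome map preparation.  Within each
    chromosome the tracked haplotype starts from a fair coin and switches
    between adjacent markers with the Haldane fraction; chromosomes
    assort independently.
    """
    haps = np.stack([hap1, hap2])
    out = np.empty(hap1.shape[0])
    for idx, r in groups:
        cur = int(rng.random() < 0.5)
        for k, j in enumerate(idx):
            if k > 0 and rng.random() < r[k - 1]:
                cur = 1 - cur
            out[j] = haps[cur, j]
    return out


def simulate_f2(cross: CrossSpec, parents: MarkerMatrix,
                linkage_map: pd.DataFrame) -> MarkerMatrix:
    """Simulate an F2 population from two inbred parents.

    Both parents must be homozygous (codes 0/2) at every mapped marker;
    the F1 is then trivially phased and each F2 individual is the sum of
    two independent F1 gametes (codes 0/1/2 = alt-allele dose).
    """
    p1 = parents.row(cross.parent1_id)
    p2 = parents.row(cross.parent2_id)
    for name, codes in ((cross.parent1_id, p1), (cross.parent2_id, p2)):
        if np.any(codes == 1.0) or np.any(np.isnan(codes)):
            raise ValueError(
                f"parent {name!r} is heterozygous or missing at some marker; "
                "only fully inbred parents can be crossed")
    groups = _map_groups(linkage_map, list(parents.marker_ids))
    rng = np.random.default_rng(cross.seed)
    hap1 = p1 / 2.0  # allele carried on both homologues of parent 1
    hap2 = p2 / 2.0
    codes = np.empty((cross.n_progeny, len(parents.marker_ids)))
    for i in range(cross.n_progeny):
        g1 = simulate_gamete(hap1, hap2, groups, rng)
        g2 = simulate_gamete(hap1, hap2, groups, rng)
        codes[i] = g1 + g2
    ids = [f"{cross.parent1_id}x{cross.parent2_id}_F2_{i + 1:04d}"
           for i in range(cross.n_progeny)]
    return MarkerMatrix(ids, list(parents.marker_ids), codes)


def predict_f2_distribution(progeny: MarkerMatrix, env: EnvironmentSeries,
                            bridge, cardinals: CardinalConstants | None = None,
                            max_days: int = 200):
    """Integrated DTH prediction for every progeny in one environment.

    Returns ``(dth_values, n_censored)``; censored progeny are excluded.
    """
    from .pipeline import predict_dth_integrated

    preds = predict_dth_integrated(progeny, env, bridge, cardinals, max_days)
    ok = ~np.isnan(preds)
    return preds[ok], int((~ok).sum())


def compare_percentiles(observed: dict, predicted: dict,
                        percentiles=(10, 50, 90)) -> PercentileComparison:
    """Compare per-population empirical quantiles of observed vs predicted DTH.

    ``observed`` and ``predicted`` map population id -> list of DTH values
    (sample sizes may differ; quantiles use linear interpolation between
    order statistics, numpy's default).  Populations missing from either
    side or empty are skipped with a warning.
    """
    import warnings

    common = []
    for pop in observed:
        if pop not in predicted:
            continue
        if len(observed[pop]) == 0 or len(predicted[pop]) == 0:
            warnings.warn(f"population {pop!r} is empty; skipped")
            continue
        common.append(pop)
    if not common:
        raise ValueError("no non-empty population present on both sides")
    pct = tuple(percentiles)
    obs = pd.DataFrame({q: [np.percentile(observed[p], q) for p in common]
                        for q in pct}, index=common)
    pred = pd.DataFrame({q: [np.percentile(predicted[p], q) for p in common]
                         for q in pct}, index=common)
    diff = pred - obs
    rmse = np.sqrt((diff ** 2).mean())
    md = diff.abs().mean()
    cor = pd.Series({q: (np.corrcoef(obs[q], pred[q])[0, 1]
                         if len(common) >= 2 and obs[q].std() > 0
                         and pred[q].std() > 0 else np.nan)
                     for q in pct})
    return PercentileComparison(percentiles=pct, observed=obs, predicted=pred,
                                rmse=rmse, cor=cor, md=md)
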