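"""Genetic offset surfaces and scenario comparison.

Genetic offset is the Euclidean distance between a unit's current and future
positions in cumulative-importance-transformed climate space: a proxy for
the allele-frequency change a population must realize to stay locally
adapted. Multi-period offsets are always computed against the same current
baseline (accumulated mismatch, not slice-to-slice steps). Scenario columns
are compared with a Friedman rank test followed by Conover post-hoc pairwise
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OffsetSurface", "genetic_offset", "offset_series",
           "friedman_conover", "FriedmanConoverResult"]


@dataclass
class OffsetSurface:
    """Per-unit offsets for one or more time slices.

    ``offsets`` is units x slices (one column per period/scenario label);
    ``extrapolated`` flags units whose climate fell outside the model's
    training range in any predictor of that slice.
    """

    offsets: pd.DataFrame
    extrapolated: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.extrapolated is None:
            self.extrapolated = pd.DataFrame(
                False, index=self.offsets.index, columns=self.offsets.columns)
        vals = self.offsets.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("offsets must be finite")
        if (vals < 0).any():
            raise ValueError("offsets must be non-negative")

    @property
    def slices(self) -> list:
        return list(self.offsets.columns)

    def to_csv(self, path) -> None:
        self.offsets.to_csv(path, index_label="unit")


def _future_predictors(results, env_future: pd.DataFrame) -> list:
    climate = [p for p in results.predictors if p not in results.spatial]
    missing = [p for p in climate if p not in env_future.columns]
    if missing:
        raise ValueError(f"future climate table missing predictors {missing}")
    return climate


def genetic_offset(results, env_now: pd.DataFrame,
                   env_future: pd.DataFrame) -> OffsetSurface:
    """Single-slice offset between current and future climate.

    ``offset_i = sqrt(sum_p (f_p(future_ip) - f_p(now_ip))^2)`` over the
    model's climate predictors; spatial covariates (PCNM axes) are
    time-invariant and contribute zero. Rows must be aligned by unit id.
    """
    if not env_now.index.equals(env_future.index):
        raise ValueError("env_now and env_future must share the same unit ids "
                         "in the same order")
    climate = _future_predictors(results, env_future)
    t_now, ex_now = results.transform(env_now, predictors=climate)
    t_fut, ex_fut = results.transform(env_future, predictors=climate)
    delta = t_fut.to_numpy() - t_now.to_numpy()
    off = np.sqrt((delta**2).sum(axis=1))
    label = getattr(env_future, "label", None) or "future"
    offsets = pd.DataFrame({label: off}, index=env_now.index)
    extrap = pd.DataFrame(
        {label: (ex_now.to_numpy() | ex_fut.to_numpy()).any(axis=1)},
        index=env_now.index)
    return OffsetSurface(offsets=offsets, extrapolated=extrap)


def offset_series(results, env_now: pd.DataFrame, env_by_slice) -> OffsetSurface:
    """Offsets of every slice against the SAME current baseline.

    ``env_by_slice`` is an ordered mapping label -> climate table (or a
    sequence of ClimateGrid-like objects with ``.values`` and ``.label``).
    """
    if hasattr(env_by_slice, "items"):
        items = list(env_by_slice.items())
    else:
        items = [(g.label, g.values) for g in env_by_slice]
    cols, flags = {}, {}
    for label, env_future in items:
        missing = [p for p in results.climate_predictors
                   if p not in env_future.columns]
        if missing:
            raise ValueError(
                f"slice {label!r} is missing predictor(s) {missing}")
        if not env_future.index.equals(env_now.index):
            env_future = env_future.loc[env_now.index]
        surf = genetic_offset(results, env_now, env_future)
        cols[label] = surf.offsets.iloc[:, 0]
        flags[label] = surf.extrapolated.iloc[:, 0]
    return OffsetSurface(offsets=pd.DataFrame(cols, index=env_now.index),
                         extrapolated=pd.DataFrame(flags, index=env_now.index))


@dataclass
class FriedmanConoverResult:
    statistic: float
    pvalue: float
    ranks: pd.DataFrame  # within-unit average ranks
    conover: pd.DataFrame = None  # pairwise BH-adjusted p-values
    conover_raw: pd.DataFrame = None
    note: str = ""


def friedman_conover(offsets: pd.DataFrame,
                     alpha: float = 0.05) -> FriedmanConoverResult:
    """Friedman test across scenario columns with Conover post-hoc pairs.

    Within-unit ranks use average ranks for ties; the Friedman chi-square
    uses the tie-corrected sum-of-squares form. Post-hoc pairwise
    comparisons follow Conover's t-statistic on rank sums with the pooled
    tie-corrected variance; pairwise p-values are Benjamini–Hochberg
    adjusted. If every unit ranks all scenarios identically (all tied), the
    statistic is 0 with p = 1 and the post-hoc step is skipped.
    """
    if offsets.shape[1] < 2 or offsets.shape[0] < 2:
        raise ValueError("need at least 2 scenarios and 2 units")
    data = offsets.to_numpy(dtype=float)
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rank_df = pd.DataFrame(ranks, index=offsets.index, columns=offsets.columns)
    rj = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    if a1 <= c1:  # every row fully tied
        return FriedmanConoverResult(
            statistic=0.0, pvalue=1.0, ranks=rank_df,
            note="all ranks tied; post-hoc skipped")
    t1 = (k - 1) * float(((rj - n * (k + 1) / 2.0) ** 2).sum()) / (a1 - c1)
    pvalue = float(stats.chi2.sf(t1, k - 1))

    # Conover pairwise comparisons on rank sums
    df = (n - 1) * (k - 1)
    pooled = 2.0 * (n * a1 - float((rj**2).sum())) / df
    names = list(offsets.columns)
    raw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if pooled > 0:
                tstat = abs(rj[i] - rj[j]) / np.sqrt(pooled)
                p = 2.0 * float(stats.t.sf(tstat, df))
            else:
                p = 1.0
            pairs.append((i, j))
            pvals.append(min(p, 1.0))
    adj = stats.false_discovery_control(pvals, method="bh") if pvals else []
    adj_df = raw.copy()
    for (i, j), p_raw, p_adj in zip(pairs, pvals, adj):
        raw.iloc[i, j] = raw.iloc[j, i] = p_raw
        adj_df.iloc[i, j] = adj_df.iloc[j, i] = p_adj
    return FriedmanConoverResult(statistic=t1, pvalue=pvalue, ranks=rank_df,
                                 conover=adj_df, conover_raw=raw)
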