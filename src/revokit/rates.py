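"""Required Evolutionary Rate (REvoRate) and offset x rate regimes.

Genetic offset says how far a population's genetic composition is from the
future optimum; REvoRate says how fast it must move. Discretely it is the
offset increment between consecutive periods divided by the gap between
their midpoint years (per-year genetic change); instantaneously it is the
chain rule dG/dt = (dG/dE)·(dE/dt) along a climate trajectory.

Default period midpoints follow the common climate-normal conventions: a
1970–2000 baseline (midpoint 1985) and four bidecadal projection periods
2021–2040, 2041–2060, 2061–2080, 2081–2100 (midpoints 2030.5 … 2090.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RateSeries", "discrete_revorate", "instantaneous_revorate",
           "classify_regime", "classify_series", "DEFAULT_BASELINE_MIDPOINT",
           "DEFAULT_PERIOD_MIDPOINTS", "REGIME_LABELS"]

DEFAULT_BASELINE_MIDPOINT = 1985.0
DEFAULT_PERIOD_MIDPOINTS = (2030.5, 2050.5, 2070.5, 2090.5)

REGIME_LABELS = ("adaptive_stress", "chronic_lag", "transient_stress",
                 "near_equilibrium")


@dataclass
class RateSeries:
    """Per-unit offsets at period midpoints and per-transition rates."""

    offsets: pd.DataFrame  # units x periods, G_k
    rates: pd.DataFrame  # units x transitions, r_k (per year)
    midpoints: np.ndarray  # period midpoint years, strictly increasing
    baseline_midpoint: float
    regimes: pd.DataFrame = None  # per-unit per-transition labels

    def to_csv(self, path) -> None:
        out = self.rates.copy()
        out.columns = [f"rate_{c}" for c in out.columns]
        pd.concat([self.offsets.add_prefix("offset_"), out], axis=1).to_csv(
            path, index_label="unit")


def discrete_revorate(offsets: pd.DataFrame, midpoints,
                      baseline_midpoint: float = DEFAULT_BASELINE_MIDPOINT,
                      absolute: bool = False,
                      include_baseline_transition: bool = True) -> RateSeries:
    """Period-to-period required evolutionary rates.

    ``offsets`` holds per-unit genetic offsets G_k for each period (all
    against the same current baseline, G_0 = 0). The rate of transition k is
    ``r_k = (G_k - G_{k-1}) / (t_k - t_{k-1})`` with t_0 the baseline
    midpoint. Rates are signed (a negative increment means the optimum moved
    back toward the current composition) unless ``absolute``. With
    ``include_baseline_transition=False``, the first transition (baseline to
    period 1) is omitted.
    """
    mids = np.asarray(midpoints, dtype=float)
    if len(mids) != offsets.shape[1]:
        raise ValueError("need one midpoint per period column")
    if np.any(np.diff(mids) <= 0):
        raise ValueError("midpoints must be strictly increasing")
    if mids[0] <= baseline_midpoint:
        raise ValueError("all midpoints must exceed the baseline midpoint")
    g = offsets.to_numpy(dtype=float)
    if (g < 0).any():
        raise ValueError("offsets must be non-negative")
    prev = np.concatenate([[baseline_midpoint], mids[:-1]])
    dt = mids - prev
    g_prev = np.concatenate([np.zeros((len(g), 1)), g[:, :-1]], axis=1)
    r = (g - g_prev) / dt
    if absolute:
        r = np.abs(r)
    rates = pd.DataFrame(r, index=offsets.index, columns=offsets.columns)
    if not include_baseline_transition:
        rates = rates.iloc[:, 1:]
    return RateSeries(offsets=offsets.copy(), rates=rates, midpoints=mids,
                      baseline_midpoint=float(baseline_midpoint))


def instantaneous_revorate(offset_fn, env_traj, t: float,
                           h: float = 1e-4) -> float:
    """Chain-rule REvoRate dG/dt = sum_p dG/dE_p * dE_p/dt at time ``t``.

    ``offset_fn`` maps a predictor vector to an offset; ``env_traj`` maps a
    year to the predictor vector. Partials use symmetric central differences
    with step ``h`` (O(h²) accurate for smooth inputs).
    """
    if h <= 0:
        raise ValueError("h must be positive")
    e0 = np.asarray(env_traj(t), dtype=float).ravel()
    e_plus = np.asarray(env_traj(t + h), dtype=float).ravel()
    e_minus = np.asarray(env_traj(t - h), dtype=float).ravel()
    de_dt = (e_plus - e_minus) / (2.0 * h)
    rate = 0.0
    for p in range(len(e0)):
        step = np.zeros_like(e0)
        step[p] = h
        dg_de = (offset_fn(e0 + step) - offset_fn(e0 - step)) / (2.0 * h)
        rate += dg_de * de_dt[p]
    return float(rate)


def classify_regime(offset: float, rate: float, offset_threshold: float,
                    rate_threshold: float) -> str:
    """One of the four offset x rate regimes.

    "High" means strictly above the threshold; the rate is compared by
    magnitude. high/high → adaptive stress (worst case), high/low → chronic
    lag (large accumulated mismatch, slow climate velocity), low/high →
    transient stress (fast change, small current mismatch), low/low → near
    equilibrium.
    """
    if offset_threshold <= 0 or rate_threshold <= 0:
        raise ValueError("thresholds must be positive")
    high_offset = offset > offset_threshold
    high_rate = abs(rate) > rate_threshold
    if high_offset and high_rate:
        return "adaptive_stress"
    if high_offset:
        return "chronic_lag"
    if high_rate:
        return "transient_stress"
    return "near_equilibrium"


def classify_series(series: RateSeries, offset_threshold: float = None,
                    rate_threshold: float = None) -> pd.DataFrame:
    """Regime label per unit per transition.

    Thresholds default to the dataset medians of offset and |rate| (the
    regimes are qualitative high/low contrasts).
    """
    if offset_threshold is None:
        offset_threshold = float(np.median(series.offsets.to_numpy()))
    if rate_threshold is None:
        rate_threshold = float(np.median(np.abs(series.rates.to_numpy())))
    offset_threshold = max(offset_threshold, np.finfo(float).tiny)
    rate_threshold = max(rate_threshold, np.finfo(float).tiny)
    labels = {}
    off_aligned = series.offsets[series.rates.columns]
    for col in series.rates.columns:
        labels[col] = [
            classify_regime(o, r, offset_threshold, rate_threshold)
            for o, r in zip(off_aligned[col], series.rates[col])
        ]
    out = pd.DataFrame(labels, index=series.rates.index)
    series.regimes = out
    return out
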