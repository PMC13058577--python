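"""Gradient-forest-style allele-frequency turnover model.

The model regresses each locus's population allele frequencies on the
environmental predictors with a bagged regression-tree ensemble. Split
impurity decreases, weighted by each locus's out-of-bag R², are binned along
every predictor and accumulated into a monotone *cumulative importance*
function: the turnover of genetic composition expected when moving along
that gradient. Evaluating those functions maps climate into "genetic
composition" space; Euclidean distances there define genetic offset.

The surface follows the statsmodels convention: :class:`TurnoverForest` is
built from data and ``fit()`` returns a :class:`TurnoverResults` carrying
estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._forest import forest_kernel
from .poolfreq import FrequencyMatrix

__all__ = ["TurnoverForest", "TurnoverResults", "CumulativeCurve",
           "identity_results"]

def _locus_seed(seed: int, locus) -> int:
    """Per-locus stream keyed on the locus id (order- and scheduling-invariant)."""
    return (int(seed) * 2654435761 + zlib.crc32(str(locus).encode())) % (2**31)


@dataclass
class CumulativeCurve:
    """Non-decreasing cumulative-importance function of one predictor.

    ``kind="step"`` (fitted models): right-continuous step function with
    mass located at ``x`` knots; 0 at/below the training minimum, equal to
    the predictor's overall importance at/above the maximum.
    ``kind="linear"``: piecewise-linear interpolation through the knots
    (used for analytically specified models such as the identity map).
    """

    x: np.ndarray
    y: np.ndarray
    x_min: float
    x_max: float
    kind: str = "step"

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "linear":
            out = np.interp(v, self.x, self.y, left=0.0,
                            right=self.y[-1] if len(self.y) else 0.0)
        else:
            idx = np.searchsorted(self.x, v, side="right") - 1
            out = np.where(idx < 0, 0.0, self.y[np.clip(idx, 0, len(self.y) - 1)])
            out = np.where(v >= self.x_max, self.y[-1] if len(self.y) else 0.0,
                           out)
        return out if out.ndim else float(out)

    @property
    def total(self) -> float:
        return float(self.y[-1]) if len(self.y) else 0.0


class TurnoverForest:
    """Allelic-turnover model specification.

    Parameters
    ----------
    freqs : FrequencyMatrix or DataFrame
        Populations x loci allele frequencies (complete, polymorphic loci).
    predictors : DataFrame
        Populations x predictors (climate plus optional spatial columns),
        aligned with ``freqs`` by index.
    n_trees : int
        Trees per locus ensemble.
    mtry : int, optional
        Candidate predictors per split; default ``max(1, P // 3)``.
    min_node : int
        Minimum samples per leaf.
    n_bins : int
        Equal-width bins per predictor for split-importance aggregation.
    spatial : sequence of str, optional
        Predictor columns to treat as time-invariant spatial covariates
        (e.g. PCNM axes); they enter the fit but are held fixed in offset
        projections.
    """

    def __init__(self, freqs, predictors: pd.DataFrame, n_trees: int = 200,
                 mtry: int | None = None, min_node: int = 2,
                 n_bins: int = 200, spatial=()):
        if isinstance(freqs, FrequencyMatrix):
            freqs = freqs.freqs
        if not freqs.index.equals(predictors.index):
            predictors = predictors.reindex(freqs.index)
        if predictors.isna().any().any():
            bad = predictors.columns[predictors.isna().any()][0]
            raise ValueError(f"predictor {bad!r} has missing values")
        if freqs.isna().any().any():
            raise ValueError("frequency matrix has missing values; run the "
                             "filter chain first")
        if len(freqs) < 8:
            raise ValueError("need at least 8 populations")
        variances = freqs.var(axis=0, ddof=0)
        if (variances == 0).any():
            bad = variances.index[variances == 0][0]
            raise ValueError(f"locus {bad!r} is monomorphic")
        for col in predictors.columns:
            if predictors[col].nunique() < 2:
                warnings.warn(f"predictor {col!r} has fewer than 2 distinct "
                              "values and will carry zero importance")
        self.freqs = freqs
        self.predictors = predictors
        self.n_trees = int(n_trees)
        self.mtry = int(mtry) if mtry else max(1, predictors.shape[1] // 3)
        self.min_node = int(min_node)
        self.n_bins = int(n_bins)
        self.spatial = [s for s in spatial if s in predictors.columns]

    @classmethod
    def from_dataframes(cls, freqs: pd.DataFrame, predictors: pd.DataFrame,
                        **kwargs) -> "TurnoverForest":
        return cls(freqs, predictors, **kwargs)

    def fit(self, seed: int = 0) -> "TurnoverResults":
        """Fit one ensemble per locus and aggregate importances.

        Deterministic given ``seed``: each locus draws from its own stream
        keyed on its id, so results do not depend on locus order or on
        how loci are scheduled.
        """
        X = np.ascontiguousarray(self.predictors.to_numpy(dtype=float))
        pred_names = list(self.predictors.columns)
        n_pred = len(pred_names)
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        edges = [np.linspace(lo[p], lo[p] + span[p], self.n_bins + 1)
                 for p in range(n_pred)]

        r2 = {}
        locus_mass = {}  # locus -> (n_pred, n_bins) mean gain per tree
        for locus in self.freqs.columns:
            y = np.ascontiguousarray(self.freqs[locus].to_numpy(dtype=float))
            oob_sum, oob_cnt, feat, thr, gain, _ = forest_kernel(
                X, y, self.n_trees, self.mtry, self.min_node,
                _locus_seed(seed, locus))
            seen = oob_cnt > 0
            var = float(np.var(y))
            if seen.any() and var > 0:
                pred = oob_sum[seen] / oob_cnt[seen]
                mse = float(np.mean((y[seen] - pred) ** 2))
                r2[locus] = 1.0 - mse / var
            else:
                r2[locus] = np.nan
            mass = np.zeros((n_pred, self.n_bins))
            for p in range(n_pred):
                sel = feat == p
                if sel.any():
                    h, _ = np.histogram(thr[sel], bins=edges[p],
                                        weights=gain[sel])
                    mass[p] = h / self.n_trees
            locus_mass[locus] = mass

        r2_series = pd.Series(r2, name="oob_r2")
        contributing = r2_series[r2_series > 0].index
        total = np.zeros((n_pred, self.n_bins))
        for locus in contributing:
            total += r2_series[locus] * locus_mass[locus]
        n_contrib = max(len(contributing), 1)
        binned = total / n_contrib
        importance = pd.Series(binned.sum(axis=1), index=pred_names,
                               name="importance")

        curves = {}
        for p, name in enumerate(pred_names):
            centers = 0.5 * (edges[p][:-1] + edges[p][1:])
            curves[name] = CumulativeCurve(
                x=centers, y=np.cumsum(binned[p]),
                x_min=float(lo[p]), x_max=float(hi[p]), kind="step")

        config = {"n_trees": self.n_trees, "mtry": self.mtry,
                  "min_node": self.min_node, "n_bins": self.n_bins,
                  "seed": int(seed)}
        return TurnoverResults(
            curves=curves, importance=importance, r2=r2_series,
            n_contributing=len(contributing), spatial=list(self.spatial),
            config=config, model=self)


class TurnoverResults:
    """Fitted turnover model: curves, importances and locus diagnostics."""

    def __init__(self, curves: dict, importance: pd.Series, r2: pd.Series,
                 n_contributing: int, spatial=(), config=None, model=None):
        self.curves = curves
        self.importance = importance
        self.r2 = r2
        self.n_contributing = n_contributing
        self.spatial = list(spatial)
        self.config = config or {}
        self.model = model

    @property
    def predictors(self) -> list[str]:
        return list(self.curves.keys())

    @property
    def climate_predictors(self) -> list[str]:
        return [p for p in self.predictors if p not in self.spatial]

    def cumulative_importance(self, predictor: str) -> CumulativeCurve:
        if predictor not in self.curves:
            raise KeyError(f"unknown predictor {predictor!r}")
        return self.curves[predictor]

    def transform(self, env: pd.DataFrame, predictors=None):
        """Map environment rows into cumulative-importance space.

        Returns ``(transformed DataFrame, extrapolation mask)``; values
        outside the training range are clamped to the boundary curve values
        and flagged in the mask.
        """
        use = list(predictors) if predictors is not None else self.predictors
        missing = [p for p in use if p not in env.columns]
        if missing:
            raise ValueError(f"environment table missing predictors {missing}")
        out = {}
        extrap = {}
        for p in use:
            curve = self.curves[p]
            v = env[p].to_numpy(dtype=float)
            out[p] = curve(v)
            extrap[p] = (v < curve.x_min) | (v > curve.x_max)
        return (pd.DataFrame(out, index=env.index),
                pd.DataFrame(extrap, index=env.index))

    # offsets and rates hang off the results object ---------------------
    def genetic_offset(self, env_now: pd.DataFrame, env_future: pd.DataFrame):
        from .offset import genetic_offset
        return genetic_offset(self, env_now, env_future)

    def offset_series(self, env_now: pd.DataFrame, env_by_slice):
        from .offset import offset_series
        return offset_series(self, env_now, env_by_slice)

    def candidate_loci(self, r2_min: float = 0.1) -> set:
        """Loci whose out-of-bag R² is at least ``r2_min``."""
        return set(self.r2.index[self.r2 >= r2_min])

    def summary(self) -> str:
        lines = ["Allelic turnover model (bagged regression-tree ensembles)",
                 "=" * 58]
        cfg = self.config
        if cfg:
            lines.append(
                f"trees/locus: {cfg.get('n_trees')}   mtry: {cfg.get('mtry')}"
                f"   min leaf: {cfg.get('min_node')}   bins: {cfg.get('n_bins')}"
            )
        r2 = self.r2.dropna()
        lines.append(f"loci fitted: {len(self.r2)}   "
                     f"contributing (R² > 0): {self.n_contributing}   "
                     f"mean OOB R²: {r2.mean():.4f}")
        lines.append("")
        lines.append(f"{'predictor':<22}{'importance':>12}{'kind':>10}")
        lines.append("-" * 44)
        for name, imp in self.importance.sort_values(ascending=False).items():
            kind = "spatial" if name in self.spatial else "climate"
            lines.append(f"{name:<22}{imp:>12.6f}{kind:>10}")
        return "\n".join(lines)

    def plot_cumulative_importance(self, predictors=None, ax=None):
        """Step plot of each predictor's cumulative-importance curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for p in predictors or self.predictors:
            curve = self.curves[p]
            ax.step(curve.x, curve.y, where="post", label=p)
        ax.set_xlabel("predictor value")
        ax.set_ylabel("cumulative importance")
        ax.legend(fontsize="small")
        return ax

    def to_json(self, path) -> None:
        doc = {
            "format": "revokit-turnover-v1",
            "spatial": self.spatial,
            "config": self.config,
            "n_contributing": self.n_contributing,
            "r2": {k: (None if pd.isna(v) else float(v))
                   for k, v in self.r2.items()},
            "curves": {
                name: {"x": c.x.tolist(), "y": c.y.tolist(),
                       "x_min": c.x_min, "x_max": c.x_max, "kind": c.kind}
                for name, c in self.curves.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "TurnoverResults":
        with open(path) as fh:
            doc = json.load(fh)
        curves = {
            name: CumulativeCurve(x=np.asarray(d["x"]), y=np.asarray(d["y"]),
                                  x_min=d["x_min"], x_max=d["x_max"],
                                  kind=d["kind"])
            for name, d in doc["curves"].items()
        }
        importance = pd.Series({n: c.total for n, c in curves.items()},
                               name="importance")
        r2 = pd.Series({k: (np.nan if v is None else v)
                        for k, v in doc["r2"].items()}, name="oob_r2",
                       dtype=float)
        return cls(curves=curves, importance=importance, r2=r2,
                   n_contributing=doc["n_contributing"],
                   spatial=doc["spatial"], config=doc["config"])


def identity_results(predictor_names, lo: float = 0.0,
                     hi: float = 1.0) -> TurnoverResults:
    """Analytic results whose cumulative curves are the identity on [lo, hi].

    Useful for validating offset geometry: transformed space equals input
    space, so offsets are plain Euclidean distances between climates.
    """
    curves = {
        p: CumulativeCurve(x=np.array([lo, hi]), y=np.array([lo, hi]),
                           x_min=lo, x_max=hi, kind="linear")
        for p in predictor_names
    }
    importance = pd.Series({p: hi for p in predictor_names},
                           name="importance")
    r2 = pd.Series(dtype=float, name="oob_r2")
    return TurnoverResults(curves=curves, importance=importance, r2=r2,
                           n_contributing=0, config={"analytic": True})
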