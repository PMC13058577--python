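"""Synthetic landscapes, climate trajectories and pool-seq allele counts.

The generator emulates the data a landscape-genomics study of a forest tree
works with: a smooth climate surface over a small region, a handful of
populations sampled on it, pool sequencing of ~25 diploid individuals per
population at ~25x coverage, and multi-decade warming/drying trajectories.
A minority of loci carry logistic allele-frequency clines along one climate
gradient each; the rest are neutral with drift-like noise. The full truth
(which loci are adaptive, their response curves, the imposed climate trends)
is returned so every downstream stage can be validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClimateGrid
from .poolfreq import PoolCounts

__all__ = [
    "SyntheticTruth",
    "make_climate_grid",
    "project_climate",
    "sample_populations",
    "simulate_pool_counts",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``response_center`` and ``response_slope`` parameterize the logistic
    cline of each adaptive locus j on its driving predictor e:
    ``p_j(e) = 1 / (1 + exp(-slope_j * (e - center_j)))``.
    """

    adaptive_locus_ids: set
    response_center: dict = field(default_factory=dict)
    response_slope: dict = field(default_factory=dict)
    driving_predictor: dict = field(default_factory=dict)
    trend: dict = field(default_factory=dict)  # predictor -> per-period shifts

    def expected_frequency(self, locus_id, env_value: float) -> float:
        s = self.response_slope[locus_id]
        c = self.response_center[locus_id]
        return 1.0 / (1.0 + np.exp(-s * (env_value - c)))

    def to_json(self, path) -> None:
        doc = {
            "adaptive_locus_ids": sorted(self.adaptive_locus_ids),
            "response_center": self.response_center,
            "response_slope": self.response_slope,
            "driving_predictor": self.driving_predictor,
            "trend": {k: list(v) for k, v in self.trend.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def make_climate_grid(nx: int, ny: int, predictor_names, smoothness: float,
                      seed: int, ranges: dict | None = None) -> ClimateGrid:
    """Smooth random field per predictor on an ``nx`` x ``ny`` grid.

    Each field is white Gaussian noise blurred with an isotropic Gaussian
    kernel of length-scale ``smoothness`` (in cell units); larger values give
    flatter landscapes. ``ranges`` optionally min–max rescales a predictor's
    field to ``(low, high)`` — e.g. a unit-range gradient for calibrated
    cline strengths. Deterministic given ``seed``.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be positive")
    names = list(predictor_names)
    if not names:
        raise ValueError("predictor_names must be non-empty")
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate predictor names: {dupes}")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in names:
        raw = rng.standard_normal((ny, nx))
        field = ndimage.gaussian_filter(raw, sigma=smoothness,
                                        mode="reflect").ravel()
        if ranges and name in ranges:
            low, high = ranges[name]
            span = field.max() - field.min()
            if span > 0:
                field = low + (high - low) * (field - field.min()) / span
            else:
                field = np.full_like(field, (low + high) / 2.0)
        cols[name] = field
    values = pd.DataFrame(cols, index=pd.RangeIndex(nx * ny, name="cell"))
    return ClimateGrid(values=values, nx=nx, ny=ny)


def project_climate(grid: ClimateGrid, period_labels, trend, noise_sd: float,
                    seed: int) -> list[ClimateGrid]:
    """Project a baseline grid through consecutive periods.

    ``trend`` maps predictor name -> sequence of per-period additive shifts
    (one entry per label in ``period_labels``). Slice k equals the baseline
    plus the cumulative trend through period k plus independent Gaussian
    noise of s.d. ``noise_sd`` per cell.
    """
    labels = list(period_labels)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for p in grid.predictors:
        if p not in trend:
            raise ValueError(f"trend table missing predictor {p!r}")
        if len(trend[p]) != len(labels):
            raise ValueError(
                f"trend for {p!r} has {len(trend[p])} entries, "
                f"expected {len(labels)} (one per period)"
            )
    rng = np.random.default_rng(seed)
    slices = []
    cumulative = {p: 0.0 for p in grid.predictors}
    for k, label in enumerate(labels):
        cols = {}
        for p in grid.predictors:
            cumulative[p] += trend[p][k]
            noise = rng.normal(0.0, noise_sd, grid.n_cells) if noise_sd > 0 else 0.0
            cols[p] = grid.values[p].to_numpy() + cumulative[p] + noise
        values = pd.DataFrame(cols, index=grid.values.index)
        slices.append(ClimateGrid(values=values, nx=grid.nx, ny=grid.ny,
                                  affine=grid.affine, label=str(label)))
    return slices


def sample_populations(grid: ClimateGrid, n_pops: int, seed: int) -> pd.DataFrame:
    """Sample ``n_pops`` distinct cells as population locations.

    Returns a table indexed by population id (``pop00``, ``pop01``, ...) with
    the cell id, user-unit coordinates, and the predictor values copied
    exactly from the grid.
    """
    if n_pops < 1:
        raise ValueError("n_pops must be positive")
    if n_pops > grid.n_cells:
        raise ValueError(f"n_pops={n_pops} exceeds the {grid.n_cells} grid cells")
    rng = np.random.default_rng(seed)
    cells = np.sort(rng.choice(grid.values.index.to_numpy(), size=n_pops,
                               replace=False))
    width = max(2, len(str(n_pops - 1)))
    ids = [f"pop{i:0{width}d}" for i in range(n_pops)]
    coords = grid.coords().loc[cells]
    table = pd.concat([coords, grid.values.loc[cells]], axis=1)
    table.insert(0, "cell", cells)
    table.index = pd.Index(ids, name="population")
    return table


def simulate_pool_counts(pops: pd.DataFrame, n_loci: int, frac_adaptive: float,
                         slope_range, pool_size_diploid: int,
                         mean_coverage: float, seed: int,
                         drift_sd: float = 0.05, driver: str | None = None):
    """Simulate pool-seq reference-allele read counts with known truth.

    Adaptive loci follow a logistic cline on one driving predictor; neutral
    loci draw population frequencies around a uniform(0.05, 0.95) ancestral
    frequency with truncated-normal drift noise of s.d. ``drift_sd``. Coverage
    is Poisson with the given mean (floored at 0) and reference reads are
    binomial(coverage, p), emulating equimolar pooling of
    ``pool_size_diploid`` trees per population. ``driver`` forces every
    adaptive locus onto that predictor; by default drivers are drawn
    uniformly over the predictors.

    Returns ``(PoolCounts, SyntheticTruth)``.
    """
    if not 0.0 <= frac_adaptive <= 1.0:
        raise ValueError("frac_adaptive must lie in [0, 1]")
    lo, hi = float(slope_range[0]), float(slope_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("slope_range must be finite")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if pool_size_diploid < 1:
        raise ValueError("pool_size_diploid must be positive")

    predictor_cols = [c for c in pops.columns if c not in ("cell", "x", "y")]
    if not predictor_cols:
        raise ValueError("population table carries no predictor columns")
    rng = np.random.default_rng(seed)
    n_pops = len(pops)
    n_adaptive = int(round(frac_adaptive * n_loci))

    width = max(4, len(str(n_loci)))
    locus_ids = [f"L{i:0{width}d}" for i in range(n_loci)]
    adaptive_ids = list(rng.choice(locus_ids, size=n_adaptive, replace=False))

    truth = SyntheticTruth(adaptive_locus_ids=set(adaptive_ids))
    freqs = np.empty((n_pops, n_loci))
    adaptive_set = set(adaptive_ids)
    for j, lid in enumerate(locus_ids):
        if lid in adaptive_set:
            if driver is not None:
                if driver not in predictor_cols:
                    raise ValueError(f"driver {driver!r} not a predictor")
                drv = driver
            else:
                drv = predictor_cols[rng.integers(len(predictor_cols))]
            env = pops[drv].to_numpy()
            # center inside the observed gradient so the cline is visible
            c = rng.uniform(np.quantile(env, 0.2), np.quantile(env, 0.8))
            s = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            p = 1.0 / (1.0 + np.exp(-s * (env - c)))
            truth.response_center[lid] = float(c)
            truth.response_slope[lid] = float(s)
            truth.driving_predictor[lid] = drv
        else:
            ancestral = rng.uniform(0.05, 0.95)
            p = ancestral + drift_sd * rng.standard_normal(n_pops)
            p = np.clip(p, 0.0, 1.0)
        freqs[:, j] = p

    coverage = rng.poisson(mean_coverage, size=(n_pops, n_loci))
    ref = rng.binomial(coverage, freqs)

    haploid = 2 * pool_size_diploid
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_loci + 1),
            "ref": "A",
            "alt": "C",
        },
        index=pd.Index(locus_ids, name="locus"),
    )
    pop_index = pops.index.copy()
    counts = PoolCounts(
        loci=loci,
        ref_counts=pd.DataFrame(ref.T, index=loci.index, columns=pop_index),
        coverage=pd.DataFrame(coverage.T, index=loci.index, columns=pop_index),
        haploid_pool_size=pd.Series(haploid, index=pop_index),
    )
    return counts, truth
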