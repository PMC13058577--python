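"""Climate-predictor reduction and spatial covariates.

Bioclim-style predictors are strongly collinear. This module implements the
reduction workflow used upstream of genotype–environment models: complete-
linkage grouping on the 1 − R² dissimilarity, a sum-of-squares collinearity
index scoring each candidate grouping, PC1 "synthetic" predictors per group,
iterative VIF pruning, a simple greedy |r| pruning, and PCNM spatial
eigenvectors (principal coordinates of a truncated neighbour matrix).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil, inf

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GroupingResult",
    "SyntheticPredictorTable",
    "PcnmBasis",
    "correlation_groups",
    "collinearity_index",
    "synthetic_predictors",
    "vif_prune",
    "pearson_prune",
    "pcnm_vectors",
]


@dataclass
class GroupingResult:
    grouping: list  # list of sorted name lists, a partition of the predictors
    index_value: float  # sum-of-squares collinearity index (may be +inf)
    ss_pc1_per_group: dict  # multi-variable group (tuple) -> SS of its PC1
    ss_total: float
    cut_threshold: float


@dataclass
class SyntheticPredictorTable:
    scores: pd.DataFrame  # populations x synthetic/singleton predictors
    loadings: dict  # column name -> pd.Series of member loadings (unit norm)
    explained_variance: dict  # column name -> PC1 variance fraction


@dataclass
class PcnmBasis:
    eigenvectors: pd.DataFrame  # populations x axes, orthonormal columns
    eigenvalues: np.ndarray  # descending, positive axes only by default
    scores: pd.DataFrame  # eigenvectors scaled by sqrt(eigenvalue)
    truncation_threshold: float

    @property
    def n_positive(self) -> int:
        return len(self.eigenvalues)

    def select_half(self) -> pd.DataFrame:
        """First ⌈m/2⌉ of the m positive-eigenvalue axes (by eigenvalue)."""
        keep = ceil(self.n_positive / 2)
        return self.scores.iloc[:, :keep]


def _standardize(env: pd.DataFrame) -> pd.DataFrame:
    sd = env.std(axis=0, ddof=1)
    zero = sd[sd == 0].index
    if len(zero):
        raise ValueError(f"zero-variance predictor(s): {list(zero)}")
    return (env - env.mean(axis=0)) / sd


def _check_partition(grouping, columns) -> list:
    groups = [sorted(g) for g in grouping]
    flat = [name for g in groups for name in g]
    if sorted(flat) != sorted(columns):
        raise ValueError("grouping is not a partition of the predictor columns")
    return groups


def correlation_groups(env: pd.DataFrame, thresholds) -> list:
    """Partitions from cutting the complete-linkage tree on 1 − R².

    One partition (list of sorted name lists) per cut height in
    ``thresholds``. R² is the squared Pearson correlation.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if env.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    z = _standardize(env)
    names = list(env.columns)
    r = np.corrcoef(z.to_numpy(), rowvar=False)
    diss = 1.0 - r**2
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, None)  # enforce exact symmetry
    tree = linkage(squareform(diss, checks=False), method="complete")
    partitions = []
    for t in thresholds:
        labels = fcluster(tree, t=t, criterion="distance")
        groups: dict[int, list] = {}
        for name, lab in zip(names, labels):
            groups.setdefault(lab, []).append(name)
        partitions.append(sorted((sorted(g) for g in groups.values())))
    return partitions


def collinearity_index(env: pd.DataFrame, grouping,
                       include_singletons: bool = False,
                       cut_threshold: float = float("nan")) -> GroupingResult:
    """Sum-of-squares collinearity index of a predictor grouping.

    All predictors are standardized (mean 0, unit variance, so each carries
    SS = N − 1). For each multi-variable group, SS_PC1 = (N − 1) x the
    largest eigenvalue of the group's correlation matrix. The index is
    Σ SS_PC1 / (SS_total − Σ SS_PC1); a zero denominator yields +inf.
    Singleton groups are excluded from the numerator by default (they form
    no synthetic component); ``include_singletons`` adds their own SS.
    """
    groups = _check_partition(grouping, list(env.columns))
    z = _standardize(env)
    n = len(z)
    ss_total = float(env.shape[1] * (n - 1))
    ss_pc1: dict = {}
    for g in groups:
        if len(g) == 1:
            if include_singletons:
                ss_pc1[tuple(g)] = float(n - 1)
            continue
        corr = np.corrcoef(z[g].to_numpy(), rowvar=False)
        lam1 = float(np.linalg.eigvalsh(corr)[-1])
        ss_pc1[tuple(g)] = (n - 1) * lam1
    numerator = sum(ss_pc1.values())
    denominator = ss_total - numerator
    index = numerator / denominator if denominator > 0 else inf
    return GroupingResult(grouping=groups, index_value=index,
                          ss_pc1_per_group=ss_pc1, ss_total=ss_total,
                          cut_threshold=cut_threshold)


def synthetic_predictors(env: pd.DataFrame, grouping) -> SyntheticPredictorTable:
    """PC1 scores per multi-variable group; singletons pass through standardized.

    The PC1 loading vector has unit norm with the loading of the
    alphabetically first member fixed >= 0 (PCA sign is arbitrary).
    Synthetic columns are named by joining member names with '+'.
    """
    groups = _check_partition(grouping, list(env.columns))
    z = _standardize(env)
    n = len(z)
    cols, loadings, explained = {}, {}, {}
    for g in groups:
        if len(g) == 1:
            name = g[0]
            cols[name] = z[name].to_numpy()
            continue
        name = "+".join(g)
        corr = np.corrcoef(z[g].to_numpy(), rowvar=False)
        vals, vecs = np.linalg.eigh(corr)
        lam1, v1 = vals[-1], vecs[:, -1]
        if v1[0] < 0:  # g is sorted, so index 0 is the alphabetically first
            v1 = -v1
        cols[name] = z[g].to_numpy() @ v1
        loadings[name] = pd.Series(v1, index=g)
        explained[name] = float(lam1 / len(g))
    scores = pd.DataFrame(cols, index=env.index)
    return SyntheticPredictorTable(scores=scores, loadings=loadings,
                                   explained_variance=explained)


def _vif_one(x: np.ndarray, others: np.ndarray) -> float:
    """VIF of one predictor regressed (with intercept) on the others."""
    n = len(x)
    design = np.column_stack([np.ones(n), others])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    ss_res = float(resid @ resid)
    xc = x - x.mean()
    ss_tot = float(xc @ xc)
    if ss_tot == 0:
        return inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return inf
    return 1.0 / (1.0 - r2)


def vif_prune(predictors: pd.DataFrame, threshold: float = 5.0):
    """Iteratively drop the predictor with the largest VIF above ``threshold``.

    Ties at the maximum are broken by removing the alphabetically last tied
    name. Returns ``(retained names, per-round VIF table)``.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if predictors.shape[0] <= predictors.shape[1]:
        raise ValueError("need more observations than predictors")
    retained = list(predictors.columns)
    rounds = []
    while len(retained) >= 2:
        vifs = {}
        mat = predictors[retained].to_numpy(dtype=float)
        for j, name in enumerate(retained):
            others = np.delete(mat, j, axis=1)
            vifs[name] = _vif_one(mat[:, j], others)
        rounds.append(dict(vifs))
        worst = max(vifs.values())
        if worst <= threshold:
            break
        tied = sorted(n for n, v in vifs.items() if v == worst)
        retained.remove(tied[-1])
    table = pd.DataFrame(rounds)
    table.index.name = "round"
    return retained, table


def pearson_prune(env: pd.DataFrame, r_max: float = 0.8) -> list:
    """Greedy removal of one member of each too-correlated pair.

    While some pair has |r| > ``r_max``, take the worst pair and drop the
    member with the larger mean absolute correlation to all other retained
    predictors (ties: drop the alphabetically last). No retained pair
    exceeds ``r_max`` on exit.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    retained = list(env.columns)
    while len(retained) >= 2:
        r = np.corrcoef(env[retained].to_numpy(dtype=float), rowvar=False)
        absr = np.abs(r)
        np.fill_diagonal(absr, 0.0)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= r_max:
            break
        mean_i = absr[i].sum() / (len(retained) - 1)
        mean_j = absr[j].sum() / (len(retained) - 1)
        if mean_i > mean_j:
            drop = retained[i]
        elif mean_j > mean_i:
            drop = retained[j]
        else:
            drop = max(retained[i], retained[j])
        retained.remove(drop)
    return retained


def pcnm_vectors(coords: pd.DataFrame, tol_factor: float = 1e-8) -> PcnmBasis:
    """PCNM spatial eigenvectors from point coordinates.

    Pairwise Euclidean distances are truncated at t = the longest edge of
    the minimum spanning tree; distances > t are replaced by 4t. The
    resulting matrix is Gower-centered (−D²/2, double-centered) and
    eigen-decomposed; axes with eigenvalue > ``tol_factor`` x the largest
    eigenvalue are retained and scaled by sqrt(eigenvalue).
    """
    xy = coords.to_numpy(dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 points")
    d = pdist(xy)
    if np.any(d == 0):
        raise ValueError("duplicate coordinates are not allowed")
    dm = squareform(d)
    mst = minimum_spanning_tree(dm).toarray()
    t = float(mst.max())
    dmod = np.where(dm > t, 4.0 * t, dm)
    np.fill_diagonal(dmod, 0.0)
    a = -0.5 * dmod**2
    n = len(xy)
    h = np.eye(n) - np.full((n, n), 1.0 / n)
    b = h @ a @ h
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = tol_factor * max(vals.max(), 0.0)
    keep = vals > tol
    vals_pos, vecs_pos = vals[keep], vecs[:, keep]
    axes = [f"PCNM{i + 1}" for i in range(len(vals_pos))]
    eigenvectors = pd.DataFrame(vecs_pos, index=coords.index, columns=axes)
    scores = eigenvectors * np.sqrt(vals_pos)
    return PcnmBasis(eigenvectors=eigenvectors, eigenvalues=vals_pos,
                     scores=scores, truncation_threshold=t)


def all_eigenvalues(coords: pd.DataFrame) -> np.ndarray:
    """Full (descending) eigenvalue spectrum of the centered PCNM matrix."""
    xy = coords.to_numpy(dtype=float)
    d = pdist(xy)
    if np.any(d == 0):
        raise ValueError("duplicate coordinates are not allowed")
    dm = squareform(d)
    t = float(minimum_spanning_tree(dm).toarray().max())
    dmod = np.where(dm > t, 4.0 * t, dm)
    np.fill_diagonal(dmod, 0.0)
    n = len(xy)
    h = np.eye(n) - np.full((n, n), 1.0 / n)
    b = h @ (-0.5 * dmod**2) @ h
    return np.sort(np.linalg.eigvalsh((b + b.T) / 2))[::-1]


def max_abs_correlation(env: pd.DataFrame) -> float:
    """Largest pairwise |r| among the columns (diagnostic helper)."""
    r = np.corrcoef(env.to_numpy(dtype=float), rowvar=False)
    return max(abs(r[i, j]) for i, j in combinations(range(env.shape[1]), 2))
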