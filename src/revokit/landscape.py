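"""RGB landscape maps and climate-predicted genetic clusters.

The turnover-transformed climate grid is reduced with a PCA and the first
three components are mapped to red/green/blue channels, so cells with
similar predicted genetic composition share similar colours. K-means on the
RGB triples, with the number of clusters chosen by mean silhouette width,
partitions the landscape into climate-predicted genetic groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = ["RgbSurface", "rgb_projection", "cluster_landscape",
           "ClusterResult"]


@dataclass
class RgbSurface:
    """Per-cell RGB channels in [0, 255] plus the PCA that produced them."""

    rgb: pd.DataFrame  # columns R, G, B
    loadings: pd.DataFrame  # predictors x up-to-3 components (orthonormal)
    explained_variance: np.ndarray  # fractions, non-increasing

    def __post_init__(self) -> None:
        vals = self.rgb.to_numpy()
        if vals.min() < 0 or vals.max() > 255:
            raise ValueError("RGB channels must lie in [0, 255]")


def rgb_projection(transformed: pd.DataFrame) -> RgbSurface:
    """PCA of the transformed grid mapped to RGB channels.

    Components 1–3 (zero-padded if fewer) are min–max scaled per channel to
    [0, 255]. Sign convention: within each component, the predictor with the
    largest |loading| gets a non-negative loading.
    """
    if len(transformed) < 3:
        raise ValueError("need at least 3 cells")
    x = transformed.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    if not np.any(centered):
        raise ValueError("all cells are identical; nothing to map")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n_comp = min(3, len(s))
    var = s**2
    explained = var / var.sum()
    channels = np.zeros((len(x), 3))
    load_cols = {}
    for c in range(n_comp):
        v = vt[c]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        load_cols[f"PC{c + 1}"] = v
        scores = centered @ v
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            channels[:, c] = np.clip(255.0 * (scores - lo) / (hi - lo),
                                     0.0, 255.0)
    rgb = pd.DataFrame(channels, index=transformed.index,
                       columns=["R", "G", "B"])
    loadings = pd.DataFrame(load_cols, index=transformed.columns)
    return RgbSurface(rgb=rgb, loadings=loadings,
                      explained_variance=explained[:n_comp])


@dataclass
class ClusterResult:
    labels: pd.Series  # contiguous ints from 0
    chosen_k: int
    silhouette_by_k: dict  # k -> mean silhouette width
    criterion: str = "highest"


def cluster_landscape(rgb: RgbSurface, k_range=(2, 3, 4, 5, 6), seed: int = 0,
                      n_restarts: int = 10,
                      criterion: str = "highest") -> ClusterResult:
    """K-means over RGB colours with silhouette-guided choice of k.

    ``criterion="highest"`` (default) picks the k maximizing the mean
    silhouette width — the standard reading; ``"lowest"`` picks the
    minimizer for users who want the literal alternative.
    """
    x = rgb.rgb.to_numpy(dtype=float)
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 2:
        raise ValueError("k must be at least 2")
    n_distinct = len(np.unique(x, axis=0))
    if max(ks) > n_distinct:
        raise ValueError(
            f"k={max(ks)} exceeds the {n_distinct} distinct points")
    if len(x) < max(ks) + 1:
        raise ValueError("need at least max(k_range)+1 cells")
    sil = {}
    fits = {}
    for k in ks:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                    random_state=seed)
        labels = km.fit_predict(x)
        fits[k] = labels
        sil[k] = float(silhouette_score(x, labels))
    if criterion == "highest":
        chosen = max(ks, key=lambda k: sil[k])
    elif criterion == "lowest":
        chosen = min(ks, key=lambda k: sil[k])
    else:
        raise ValueError("criterion must be 'highest' or 'lowest'")
    raw = fits[chosen]
    # relabel to contiguous ints in order of first appearance
    remap = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
    labels = pd.Series([remap[v] for v in raw], index=rgb.rgb.index,
                       name="cluster")
    return ClusterResult(labels=labels, chosen_k=chosen, silhouette_by_k=sil,
                         criterion=criterion)
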