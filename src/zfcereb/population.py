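"""Population-level maps and clustering.

Functional clusters come from PCA on per-ROI regressor-correlation (or
coefficient) vectors followed by k-means in PC space (k = 10 clusters on the
first 10 PCs by default, which already capture ~90% of the variance in the
regime this emulates). Two distance-ratio indices quantify spatial structure:
the anatomical clustering index (within-fish compactness of a cluster) and
the stereotypy index (cross-fish positional consistency); both equal 1 under
chance.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, cdist
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["correlation_map", "preference_map", "z_projection",
           "FunctionalClusterer", "pca_kmeans",
           "anatomical_clustering_index", "stereotypy_index"]


def z_projection(volume_map: np.ndarray) -> np.ndarray:
    """Mean over depth (axis 0) of a voxelwise map, for display export."""
    return np.asarray(volume_map, dtype=float).mean(axis=0)


def correlation_map(signals: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Pearson r of each voxel/ROI signal (rows) with one regressor.

    Zero-variance voxels get r = 0 (undefined, flagged by exactly-zero).
    """
    S = np.asarray(signals, dtype=float)
    r = np.asarray(regressor, dtype=float).ravel()
    if S.shape[-1] != r.size:
        raise ValueError("signals and regressor length mismatch")
    Sz = S - S.mean(axis=-1, keepdims=True)
    rz = r - r.mean()
    s_sd = np.sqrt((Sz ** 2).sum(axis=-1))
    r_sd = np.sqrt((rz ** 2).sum())
    denom = s_sd * r_sd
    out = np.zeros(S.shape[:-1])
    ok = denom > 0
    out[ok] = (Sz @ rz)[ok] / denom[ok]
    return out


def preference_map(sensory_map: np.ndarray, motor_map: np.ndarray,
                   min_distance: float = 0.2) -> np.ndarray:
    """Label each pixel sensory/motor/neutral by which map explains it better
    with at least ``min_distance`` margin (else neutral)."""
    s = np.asarray(sensory_map, dtype=float)
    m = np.asarray(motor_map, dtype=float)
    if s.shape != m.shape:
        raise ValueError("maps must have the same shape")
    out = np.full(s.shape, "neutral", dtype=object)
    out[s - m >= min_distance] = "sensory"
    out[m - s >= min_distance] = "motor"
    return out


class FunctionalClusterer(BaseEstimator):
    """PCA + k-means functional clustering of per-ROI feature vectors.

    Fitted attributes: ``labels_`` (1..k), ``variance_explained_`` per PC,
    ``pca_`` and ``kmeans_`` sub-models.
    """

    def __init__(self, n_pc: int = 10, k: int = 10, seed: int = 0,
                 n_init: int = 50):
        self.n_pc = n_pc
        self.k = k
        self.seed = seed
        self.n_init = n_init

    def fit(self, features: np.ndarray, y=None) -> "FunctionalClusterer":
        F = np.asarray(features, dtype=float)
        if F.shape[0] < self.k:
            raise ValueError("need at least k ROIs")
        if np.allclose(F, F[0]):
            raise ValueError("degenerate input: all feature vectors identical")
        n_pc = min(self.n_pc, F.shape[0], F.shape[1])
        self.pca_ = PCA(n_components=n_pc).fit(F)
        scores = self.pca_.transform(F)
        self.kmeans_ = KMeans(n_clusters=self.k, n_init=self.n_init,
                              random_state=self.seed).fit(scores)
        self.labels_ = self.kmeans_.labels_ + 1
        self.variance_explained_ = self.pca_.explained_variance_ratio_
        return self

    def fit_predict(self, features: np.ndarray, y=None) -> np.ndarray:
        return self.fit(features).labels_


def pca_kmeans(features, coords=None, fish_ids=None, n_pc: int = 10,
               k: int = 10, seed: int = 0) -> dict:
    """Cluster feature vectors and, when coordinates and fish ids are given,
    report both spatial indices per cluster."""
    fc = FunctionalClusterer(n_pc=n_pc, k=k, seed=seed).fit(features)
    report = {"labels": fc.labels_,
              "variance_explained": fc.variance_explained_}
    if coords is not None and fish_ids is not None:
        report["anatomical_clustering_index"] = anatomical_clustering_index(
            fc.labels_, coords, fish_ids)
        report["stereotypy_index"] = stereotypy_index(
            fc.labels_, coords, fish_ids)
    return report


def _mean_pdist(x: np.ndarray) -> float:
    return float(pdist(x).mean()) if len(x) >= 2 else np.nan


def anatomical_clustering_index(labels, coords, fish_ids) -> dict:
    """Within-fish spatial compactness of each cluster.

    Per fish: mean distance from a cluster ROI to any other ROI of that fish
    (the expectation of a randomly chosen ROI) divided by the mean
    within-cluster distance; averaged over fish. 1 = chance; singleton
    clusters within a fish are skipped.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    fish_ids = np.asarray(fish_ids)
    out: dict = {}
    for lab in np.unique(labels):
        per_fish = []
        for f in np.unique(fish_ids):
            in_fish = fish_ids == f
            in_cl = in_fish & (labels == lab)
            n_cl, n_f = int(in_cl.sum()), int(in_fish.sum())
            if n_cl < 2 or n_f < 3:
                continue
            within = _mean_pdist(coords[in_cl])
            # expectation over a randomly chosen other ROI of the same fish:
            # mean distance from each cluster ROI to every other fish ROI
            D = cdist(coords[in_cl], coords[in_fish])
            rand_all = D.sum() / (n_cl * (n_f - 1))  # self-distances are 0
            if within > 0:
                per_fish.append(rand_all / within)
        if per_fish:
            out[int(lab)] = float(np.mean(per_fish))
    return out


def stereotypy_index(labels, coords, fish_ids) -> dict:
    """Cross-fish positional consistency of each cluster.

    Per fish: mean distance from the cluster's ROIs to other-cluster ROIs of
    other fish, divided by the mean distance to same-cluster ROIs of other
    fish; averaged over fish. 1 = chance; clusters confined to one fish are
    skipped.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    fish_ids = np.asarray(fish_ids)
    out: dict = {}
    for lab in np.unique(labels):
        per_fish = []
        for f in np.unique(fish_ids):
            mine = (fish_ids == f) & (labels == lab)
            other_same = (fish_ids != f) & (labels == lab)
            other_diff = (fish_ids != f) & (labels != lab)
            if not (mine.any() and other_same.any() and other_diff.any()):
                continue
            same = float(cdist(coords[mine], coords[other_same]).mean())
            diff = float(cdist(coords[mine], coords[other_diff]).mean())
            if same > 0:
                per_fish.append(diff / same)
        if per_fish:
            out[int(lab)] = float(np.mean(per_fish))
    return out
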