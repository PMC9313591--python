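"""Morphospace construction: PCA of coefficient vectors, clade hulls, clustering.

PCA is run on the covariance of centred, unscaled coefficient vectors — after
Procrustes alignment all coefficients share units, so no correlation scaling is
applied.  Cluster-number selection follows the majority-rule mechanism: a
battery of internal validity indices each votes for its best K over a K range,
and the modal vote wins (ties broken toward the smaller K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .efa import EFACoefficients, efa_inverse
from .exceptions import InputError, MappingError
from .outlines import Outline

__all__ = [
    "MorphospaceModel",
    "ClusterReport",
    "coefficients_to_matrix",
    "fit_pca",
    "project",
    "reconstruct_axis_shape",
    "clade_hull_occupancy",
    "kmeans_fit",
    "select_k_majority",
    "DEFAULT_INDICES",
]


def coefficients_to_matrix(coeffs_list):
    """Stack flattened coefficient vectors into (n_taxa, 4N) with row labels."""
    coeffs_list = list(coeffs_list)
    if not coeffs_list:
        raise InputError("empty coefficient list")
    Ns = {c.N for c in coeffs_list}
    if len(Ns) != 1:
        raise InputError(f"inconsistent harmonic counts: {sorted(Ns)}")
    X = np.vstack([c.flattened() for c in coeffs_list])
    labels = [c.taxon_id or c.specimen_id for c in coeffs_list]
    return X, labels


@dataclass
class MorphospaceModel:
    """Fitted PC space of shape coefficients.

    Scores for the training taxa are stored as a DataFrame; ``project`` maps
    new coefficient vectors into the same space and ``reconstruct_axis_shape``
    inverts points along one axis back to outlines.
    """

    mean: np.ndarray
    loadings: np.ndarray  # (p, r), orthonormal columns
    eigenvalues: np.ndarray  # (r,), non-increasing
    scores: pd.DataFrame  # (n_taxa, r)
    n_harmonics: int
    view: str = "front"
    mean_perimeter: float = 1.0

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def project(self, coeffs) -> np.ndarray:
        return project(self, coeffs)

    def reconstruct_axis_shape(self, axis: int, multiple: float, n_points: int = 300) -> Outline:
        return reconstruct_axis_shape(self, axis, multiple, n_points=n_points)


def fit_pca(coeffs_or_matrix, labels=None, view: str = "front") -> MorphospaceModel:
    """PCA (covariance, unscaled) of per-taxon coefficient vectors.

    Sign convention: each loading's largest-magnitude entry is positive, which
    makes the decomposition deterministic across BLAS implementations.
    """
    if isinstance(coeffs_or_matrix, np.ndarray):
        X = np.asarray(coeffs_or_matrix, dtype=float)
        if labels is None:
            labels = [f"row{i}" for i in range(len(X))]
        n_harm = X.shape[1] // 4
        mean_T = 1.0
    else:
        coeffs_list = list(coeffs_or_matrix)
        X, labels = coefficients_to_matrix(coeffs_list)
        n_harm = coeffs_list[0].N
        view = coeffs_list[0].view
        mean_T = float(np.mean([c.T for c in coeffs_list]))
    n = X.shape[0]
    if n < 3:
        raise InputError(f"PCA needs at least 3 taxa, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(n - 1, X.shape[1])
    u, s, vt = u[:, :r], s[:r], vt[:r]
    eig = s**2 / (n - 1)
    loadings = vt.T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(r)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xc @ loadings
    score_df = pd.DataFrame(
        scores,
        index=pd.Index(labels, name="taxon_id"),
        columns=[f"PC{i + 1}" for i in range(r)],
    )
    return MorphospaceModel(
        mean=mean,
        loadings=loadings,
        eigenvalues=eig,
        scores=score_df,
        n_harmonics=n_harm,
        view=view,
        mean_perimeter=mean_T,
    )


def project(model: MorphospaceModel, coeffs) -> np.ndarray:
    """Scores = loadings^T (x - mean); the mean maps to the zero vector."""
    if isinstance(coeffs, EFACoefficients):
        vec = coeffs.flattened()
    else:
        vec = np.asarray(coeffs, dtype=float).ravel()
    if vec.size != model.mean.size:
        raise InputError(
            f"coefficient vector length {vec.size} != model dimension {model.mean.size}"
        )
    return (vec - model.mean) @ model.loadings


def reconstruct_axis_shape(
    model: MorphospaceModel, axis: int, multiple: float, n_points: int = 300
) -> Outline:
    """Outline of mean + multiple * sd_axis * loading_axis (multiple=0: mean)."""
    r = model.loadings.shape[1]
    if not 0 <= axis < r:
        raise InputError(f"axis {axis} out of range (model has {r} components)")
    sd = float(np.sqrt(model.eigenvalues[axis]))
    vec = model.mean + multiple * sd * model.loadings[:, axis]
    coeffs = EFACoefficients.from_flat(
        vec, T=model.mean_perimeter, view=model.view,
        specimen_id=f"PC{axis + 1}{multiple:+g}SD",
    )
    return efa_inverse(coeffs, n_points=n_points)


def clade_hull_occupancy(scores: pd.DataFrame, clades: dict, axes=(0, 1)) -> dict:
    """Convex hull (vertices + shoelace area) per clade on two score axes.

    Clades with fewer than 3 taxa, or degenerate (collinear) score clouds, are
    flagged with area 0 and an empty polygon.
    """
    cols = [scores.columns[axes[0]], scores.columns[axes[1]]]
    missing = [t for t in scores.index if t not in clades]
    if missing:
        raise MappingError(f"taxa without clade labels: {missing[:5]}")
    out = {}
    for clade in sorted(set(clades[t] for t in scores.index)):
        taxa = [t for t in scores.index if clades[t] == clade]
        pts = scores.loc[taxa, cols].to_numpy()
        if len(pts) < 3:
            out[clade] = {"polygon": np.empty((0, 2)), "area": 0.0, "degenerate": True,
                          "taxa": taxa}
            continue
        try:
            hull = ConvexHull(pts)
        except QhullError:
            out[clade] = {"polygon": np.empty((0, 2)), "area": 0.0, "degenerate": True,
                          "taxa": taxa}
            continue
        out[clade] = {
            "polygon": pts[hull.vertices],
            "area": float(hull.volume),  # 2D: volume is the area
            "degenerate": False,
            "taxa": taxa,
        }
    return out


# ----------------------------------------------------------------- clustering


def kmeans_fit(X, K: int, restarts: int = 10, seed: int = 0):
    """Best-of-``restarts`` Lloyd k-means with k-means++ seeding.

    Returns ``(labels, centroids, wcss)``; deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not 2 <= K <= n - 1:
        raise InputError(f"K must satisfy 2 <= K <= n-1 = {n - 1}, got {K}")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_, float(km.inertia_)


@dataclass
class ClusterReport:
    """Majority-rule cluster-number selection result."""

    k_min: int
    k_max: int
    votes: dict  # index name -> best K
    chosen_k: int
    labels: np.ndarray  # 1-based cluster labels per point
    centroids: np.ndarray
    vote_margin: float  # winner's vote share
    taxa: list = field(default_factory=list)

    def vote_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.votes.items()), columns=["index", "best_k"]
        )


def _wcss(X, labels, centroids) -> float:
    return float(np.sum((X - centroids[labels]) ** 2))


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    ks = np.unique(labels)
    intra = 0.0
    for k in ks:
        idx = np.flatnonzero(labels == k)
        if len(idx) > 1:
            intra = max(intra, D[np.ix_(idx, idx)].max())
    if intra == 0:
        return np.inf
    inter = np.inf
    for i, a in enumerate(ks):
        for b in ks[i + 1 :]:
            ia, ib = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
            inter = min(inter, D[np.ix_(ia, ib)].min())
    return inter / intra


def _c_index(D: np.ndarray, dvec: np.ndarray, labels: np.ndarray) -> float:
    S, n_w = 0.0, 0
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            S += sub[np.triu_indices_from(sub, 1)].sum()
            n_w += len(idx) * (len(idx) - 1) // 2
    if n_w == 0:
        return 0.0
    ordered = np.sort(dvec)
    smin = ordered[:n_w].sum()
    smax = ordered[-n_w:].sum()
    if smax == smin:
        return 0.0
    return (S - smin) / (smax - smin)


DEFAULT_INDICES = (
    "calinski_harabasz",
    "silhouette",
    "davies_bouldin",
    "dunn",
    "c_index",
    "gap",
    "hartigan",
    "krzanowski_lai",
    "ball_hall",
    "xu",
)


def select_k_majority(
    X,
    K_min: int = 2,
    K_max: int = 20,
    indices=DEFAULT_INDICES,
    seed: int = 0,
    restarts: int = 10,
    gap_refs: int = 50,
    taxa=None,
) -> ClusterReport:
    """Choose the cluster count by majority vote of internal validity indices.

    For each K in [K_min, K_max] a seeded k-means is fitted; each index in the
    battery votes for its optimal K (standard optimum direction per index);
    the modal vote wins, ties broken toward smaller K.  The gap statistic uses
    ``gap_refs`` seeded uniform reference sets.  Bit-reproducible under a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise InputError("need at least 3 points to cluster")
    if K_min < 2:
        raise InputError("K_min must be >= 2")
    if K_max > n - 1:
        warnings.warn(f"K_max lowered from {K_max} to n-1 = {n - 1}")
        K_max = n - 1
    if K_min > K_max:
        raise InputError(f"K_min={K_min} > K_max={K_max}")

    Ks = list(range(K_min, K_max + 1))
    # W at K-1 and K+1 endpoints supports the difference-based indices
    fit_Ks = sorted(set(Ks) | {k + 1 for k in Ks if k + 1 <= n - 1} | {k - 1 for k in Ks if k - 1 >= 2})
    fits = {k: kmeans_fit(X, k, restarts=restarts, seed=seed) for k in fit_Ks}
    Xc = X - X.mean(axis=0)
    W = {1: float(np.sum(Xc**2))}
    W.update({k: fits[k][2] for k in fit_Ks})

    dvec = pdist(X)
    D = squareform(dvec)
    votes: dict[str, int] = {}

    def argbest(values, direction):
        arr = np.asarray(values, dtype=float)
        return Ks[int(np.argmax(arr) if direction == "max" else np.argmin(arr))]

    for name in indices:
        if name == "calinski_harabasz":
            votes[name] = argbest(
                [calinski_harabasz_score(X, fits[k][0]) for k in Ks], "max"
            )
        elif name == "silhouette":
            votes[name] = argbest([silhouette_score(D, fits[k][0], metric="precomputed") for k in Ks], "max")
        elif name == "davies_bouldin":
            votes[name] = argbest([davies_bouldin_score(X, fits[k][0]) for k in Ks], "min")
        elif name == "dunn":
            votes[name] = argbest([_dunn(D, fits[k][0]) for k in Ks], "max")
        elif name == "c_index":
            votes[name] = argbest([_c_index(D, dvec, fits[k][0]) for k in Ks], "min")
        elif name == "gap":
            votes[name] = _gap_vote(X, fits, Ks, W, gap_refs, seed, restarts)
        elif name == "hartigan":
            votes[name] = _hartigan_vote(W, Ks, n)
        elif name == "krzanowski_lai":
            votes[name] = _kl_vote(W, Ks, p)
        elif name == "ball_hall":
            diffs = [W[k - 1] / (k - 1) - W[k] / k if k - 1 in W else -np.inf for k in Ks]
            votes[name] = argbest(diffs, "max")
        elif name == "xu":
            vals = [p * np.log(np.sqrt(max(W[k], 1e-300) / (p * n**2))) + np.log(k) for k in Ks]
            votes[name] = argbest(vals, "min")
        else:
            raise InputError(f"unknown validity index {name!r}")

    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == top)  # tie -> smaller K
    labels, centroids, _ = fits[chosen]
    return ClusterReport(
        k_min=K_min,
        k_max=K_max,
        votes=votes,
        chosen_k=chosen,
        labels=labels + 1,
        centroids=centroids,
        vote_margin=top / len(votes),
        taxa=list(taxa) if taxa is not None else [],
    )


def _gap_vote(X, fits, Ks, W, n_refs, seed, restarts):
    """Tibshirani gap statistic with uniform bounding-box references."""
    rng = np.random.default_rng(seed + 1)
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w_ref = np.zeros((n_refs, len(Ks)))
    for b in range(n_refs):
        ref = lo + rng.random((n, p)) * (hi - lo)
        for j, k in enumerate(Ks):
            km = KMeans(n_clusters=k, n_init=2, random_state=seed, algorithm="lloyd")
            km.fit(ref)
            log_w_ref[b, j] = np.log(max(km.inertia_, 1e-300))
    log_w = np.array([np.log(max(W[k], 1e-300)) for k in Ks])
    gap = log_w_ref.mean(axis=0) - log_w
    s = log_w_ref.std(axis=0) * np.sqrt(1 + 1.0 / n_refs)
    for j in range(len(Ks) - 1):
        if gap[j] >= gap[j + 1] - s[j + 1]:
            return Ks[j]
    return Ks[int(np.argmax(gap))]


def _hartigan_vote(W, Ks, n):
    """Smallest K with Hartigan statistic <= 10 (else the largest K)."""
    for k in Ks:
        if k + 1 not in W:
            break
        h = (W[k] / max(W[k + 1], 1e-300) - 1.0) * (n - k - 1)
        if h <= 10.0:
            return k
    return Ks[-1]


def _kl_vote(W, Ks, p):
    """Krzanowski-Lai: argmax |DIFF_K / DIFF_{K+1}|."""
    def diff(k):
        return (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]

    vals = []
    for k in Ks:
        if k - 1 not in W or k + 1 not in W:
            vals.append(-np.inf)
            continue
        d1, d2 = diff(k), diff(k + 1)
        vals.append(abs(d1) / max(abs(d2), 1e-300))
    return Ks[int(np.argmax(vals))]
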