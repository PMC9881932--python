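"""Comparison methods: PCA and contrastive PCA (finite alpha and alpha = inf).

cPCA finds v maximizing v' X X' v - alpha * v' Y Y' v subject to ||v|| = 1:
the dominant case axis penalized for the control variance it explains.
alpha = 0 reduces to ordinary PCA of the cases; alpha = inf forces v into
the null space of the (centered) control matrix, i.e. v must be orthogonal
to all n0 control samples — an m - rank(Y) dimensional constraint that
degrades as n0 approaches m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import SpectralClustering

from .datamodel import DataMatrix, ValidationError
from .io import align_features, standardize


def _center(M: DataMatrix) -> np.ndarray:
    return M.values - M.values.mean(axis=1, keepdims=True)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    return V * flip


@dataclass
class PcaFit:
    loadings: np.ndarray   # m x d principal axes
    scores: np.ndarray     # n x d sample coordinates
    variances: np.ndarray  # d explained variances, non-increasing


@dataclass
class CpcaFit:
    alpha: float                       # may be np.inf
    components: np.ndarray             # m x d, orthonormal
    scores: np.ndarray                 # n1 x d
    eigenvalues: np.ndarray
    suggested_alphas: list[float] = field(default_factory=list)


def fit_pca(X: DataMatrix, d: int) -> PcaFit:
    """Top-d principal components of the (feature-centered) case matrix."""
    if not (1 <= d <= min(X.n_features, X.n_samples)):
        raise ValidationError(f"d={d} out of range for shape {X.shape}")
    Xc = _center(X)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U = _fix_signs(U[:, :d])
    scores = Xc.T @ U
    variances = s[:d] ** 2 / (X.n_samples - 1)
    return PcaFit(loadings=U, scores=scores, variances=variances)


def fit_cpca(X: DataMatrix, Y: DataMatrix, alpha: float, d: int) -> CpcaFit:
    """Contrastive PCA at a finite alpha >= 0.

    Eigendecomposes the contrast operator X X' - alpha * Y Y' (each matrix
    feature-centered) and returns the top-d eigenvectors and case scores.
    """
    if not np.isfinite(alpha) or alpha < 0:
        raise ValidationError("alpha must be finite and nonnegative; use fit_cpca_inf")
    X, Y = align_features(X, Y)
    Xc, Yc = _center(X), _center(Y)
    m = Xc.shape[0]
    C = Xc @ Xc.T - alpha * (Yc @ Yc.T)
    d = min(d, m)
    w, V = scipy.linalg.eigh(C, subset_by_index=[m - d, m - 1])
    order = np.argsort(w)[::-1]
    w, V = w[order], _fix_signs(V[:, order])
    return CpcaFit(alpha=alpha, components=V, scores=Xc.T @ V, eigenvalues=w)


def fit_cpca_inf(X: DataMatrix, Y: DataMatrix, d: int) -> CpcaFit:
    """cPCA in the alpha -> inf limit: PCA of X restricted to null(Y').

    Projects the centered case matrix onto the orthogonal complement of the
    centered control column space, then takes principal components; every
    component v satisfies Y' v = 0.  Requires m > n0, otherwise the null
    space is trivial (rank-nullity) and only v = 0 solves the program.
    """
    X, Y = align_features(X, Y)
    m, n0 = X.n_features, Y.n_samples
    if m <= n0:
        raise ValidationError(
            f"alpha=inf needs m > n0: with m={m} features and n0={n0} controls "
            "the control column space leaves no room for a nonzero component "
            "(rank-nullity)"
        )
    Xc, Yc = _center(X), _center(Y)
    if np.linalg.norm(Yc) == 0:
        Q = np.empty((m, 0))
    else:
        Q = scipy.linalg.orth(Yc)
    Xp = Xc - Q @ (Q.T @ Xc)
    d = min(d, min(Xp.shape))
    U, s, _ = np.linalg.svd(Xp, full_matrices=False)
    V = _fix_signs(U[:, :d])
    return CpcaFit(
        alpha=np.inf,
        components=V,
        scores=Xc.T @ V,
        eigenvalues=s[:d] ** 2 / (X.n_samples - 1),
    )


def _principal_angle_affinity(subspaces: list[np.ndarray]) -> np.ndarray:
    """Pairwise product-of-cosines of principal angles between subspaces."""
    g = len(subspaces)
    A = np.eye(g)
    for i in range(g):
        for j in range(i + 1, g):
            sv = np.linalg.svd(subspaces[i].T @ subspaces[j], compute_uv=False)
            A[i, j] = A[j, i] = float(np.prod(np.clip(sv, 0, 1)))
    return A


def suggest_alphas(
    X: DataMatrix,
    Y: DataMatrix,
    n_alphas: int = 10,
    grid: np.ndarray | None = None,
    d: int = 2,
    seed: int = 0,
) -> list[float]:
    """Recommend contrast strengths spanning maximally distinct subspaces.

    Fits cPCA across a log-spaced grid of alphas, measures pairwise
    subspace affinity as the product of principal-angle cosines between the
    top-d component subspaces, spectral-clusters the affinity matrix, and
    returns the medoid alpha of each cluster (sorted ascending).  This is a
    reimplementation of the published cPCA selection heuristic; treat the
    returned values as representatives, not as canonical.
    """
    if grid is None:
        grid = np.logspace(-1, 3, 40)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("alpha grid must be nonempty")
    subspaces = [fit_cpca(X, Y, a, d).components for a in grid]
    A = _principal_angle_affinity(subspaces)
    k = min(n_alphas, grid.size)
    if k == grid.size:
        idx = list(range(grid.size))
    else:
        labels = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=seed,
            assign_labels="discretize",
        ).fit_predict(A)
        idx = []
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            medoid = members[np.argmax(A[np.ix_(members, members)].sum(axis=1))]
            idx.append(int(medoid))
    # Collapse representatives whose subspaces are numerically identical —
    # distinct alphas inducing the same subspace carry no extra information.
    kept: list[int] = []
    for i in sorted(idx, key=lambda i: grid[i]):
        if all(A[i, j] < 1 - 1e-9 for j in kept):
            kept.append(i)
    return sorted(float(grid[i]) for i in kept)
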