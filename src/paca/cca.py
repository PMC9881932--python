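"""Sample-space canonical correlation analysis of a case/control matrix pair.

Standard CCA seeks linear combinations of *features* that correlate across
two datasets.  Here the roles are transposed: given case matrix X (m x n1)
and control matrix Y (m x n0) over the same m features, we seek linear
combinations of the *samples* — vectors a in R^n1, b in R^n0 — such that the
feature-space images Xa and Yb are maximally correlated:

    max_{a,b}  a' X'Y b   s.t.  ||Xa|| = ||Yb|| = 1.

The images u_r = X a_r of the successive canonical pairs span the
representation in X of the variation shared between cases and controls
(population structure, cell composition, batch, ...).  Projecting X off the
top-k of these directions removes the expected effect of the shared
structure, leaving case-specific variation for downstream PCA.

The optimal a is the top eigenvector of S_XX^{-1} S_XY S_YY^{-1} S_YX with
S_XX = X'X etc.; we solve the equivalent symmetric whitened problem
(S_XX+eI)^{-1/2} S_XY (S_YY+eI)^{-1} S_YX (S_XX+eI)^{-1/2} via SVD, which
yields all min(n0, n1) pairs at once with real spectrum, and matches the
iterative formulation in which each u_r is constrained orthogonal to its
predecessors.  A small ridge e keeps near-singular sample Gram matrices
invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datamodel import DataMatrix, ValidationError


@dataclass
class CanonicalSystem:
    """All canonical pairs of a case/control pair, samples-space convention.

    Attributes
    ----------
    a_vectors, b_vectors
        Case-side (n1 x R) and control-side (n0 x R) canonical coefficients.
    correlations
        The R canonical correlations, non-increasing, in [0, 1].
    u_directions
        (m x R); column r is the normalized image X a_r — the representation
        in X of the r-th shared direction.
    y_directions
        (m x R); the analogous normalized images Y b_r.
    R
        Number of pairs computed (min(n0, n1) by default, cached so the
        shared-dimension search never recomputes the CCA).
    """

    a_vectors: np.ndarray
    b_vectors: np.ndarray
    correlations: np.ndarray
    u_directions: np.ndarray
    y_directions: np.ndarray
    R: int


def _check_aligned(X: DataMatrix, Y: DataMatrix) -> None:
    if X.n_features != Y.n_features or not np.array_equal(X.feature_ids, Y.feature_ids):
        raise ValidationError("X and Y must be feature-aligned (use align_features)")


def _inv_sqrt(S: np.ndarray, eps: float) -> np.ndarray:
    """Symmetric inverse square root of S + eps*I."""
    w, V = np.linalg.eigh(S)
    w = w + eps
    if np.min(w) <= 0:
        raise np.linalg.LinAlgError(
            "sample Gram matrix is numerically singular; pass a positive "
            "ridge_epsilon"
        )
    return (V / np.sqrt(w)) @ V.T


def sample_space_cca(
    X: DataMatrix,
    Y: DataMatrix,
    r_max: int | None = None,
    ridge_epsilon: float | None = None,
) -> CanonicalSystem:
    """Compute the top ``r_max`` sample-space canonical pairs of (X, Y).

    Requires m > max(n0, n1) (the large-p regime); for the opposite regime
    use :func:`paca.rpaca.fit_rpaca`.  ``ridge_epsilon=None`` defaults to
    ``1e-8 * trace(S)/n`` per side; pass ``0`` to forbid regularization.
    """
    _check_aligned(X, Y)
    Xv, Yv = X.values, Y.values
    m, n1 = Xv.shape
    n0 = Yv.shape[1]
    if m <= max(n0, n1):
        raise ValidationError(
            f"sample-space CCA needs more features than samples "
            f"(m={m}, n1={n1}, n0={n0}); use fit_rpaca for the m < n regime"
        )
    r_cap = min(n0, n1)
    if r_max is None:
        r_max = r_cap
    if r_max > r_cap:
        raise ValidationError(f"r_max={r_max} exceeds min(n0, n1)={r_cap}")

    S_xx = Xv.T @ Xv
    S_yy = Yv.T @ Yv
    S_xy = Xv.T @ Yv
    eps_x = 1e-8 * np.trace(S_xx) / n1 if ridge_epsilon is None else ridge_epsilon
    eps_y = 1e-8 * np.trace(S_yy) / n0 if ridge_epsilon is None else ridge_epsilon

    Wx = _inv_sqrt(S_xx, eps_x)
    Wy = _inv_sqrt(S_yy, eps_y)
    P, rho, Qt = np.linalg.svd(Wx @ S_xy @ Wy, full_matrices=False)

    a = Wx @ P[:, :r_max]
    b = Wy @ Qt.T[:, :r_max]
    u = Xv @ a
    v = Yv @ b
    # ||Xa_r|| = 1 holds exactly only at eps = 0; normalize the images.
    u_norm = np.linalg.norm(u, axis=0)
    v_norm = np.linalg.norm(v, axis=0)
    if np.any(u_norm == 0) or np.any(v_norm == 0):
        raise np.linalg.LinAlgError(
            "degenerate canonical image; pass a positive ridge_epsilon"
        )
    u = u / u_norm
    v = v / v_norm
    # Deterministic sign: largest-|entry| coordinate of u_r positive; flip
    # a, b, v with it so a'S_xy b keeps its sign.
    flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    return CanonicalSystem(
        a_vectors=a * flip,
        b_vectors=b * flip,
        correlations=np.clip(rho[:r_max], 0.0, 1.0),
        u_directions=u * flip,
        y_directions=v * flip,
        R=r_max,
    )


def shared_basis(cs: CanonicalSystem, k: int, side: str = "x") -> np.ndarray:
    """Orthonormal m x k basis of the top-k shared directions.

    Ordered (QR) orthonormalization of the first k canonical images so the
    leading direction is preserved; under a small ridge the raw images are
    only approximately orthogonal.  Column signs fix the largest-|entry|
    coordinate positive.  ``side="y"`` returns the control-side analogue.
    """
    if k > cs.R:
        raise ValidationError(f"k={k} exceeds number of canonical pairs R={cs.R}")
    dirs = cs.u_directions if side == "x" else cs.y_directions
    if k == 0:
        return np.empty((dirs.shape[0], 0))
    Q, Rm = np.linalg.qr(dirs[:, :k])
    Q = Q * np.sign(np.diag(Rm))  # keep each column aligned with its raw image
    flip = np.sign(Q[np.abs(Q).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return Q * flip


def residualize(M: DataMatrix, U: np.ndarray) -> DataMatrix:
    """Remove the expected effect of the shared directions: M - U U' M.

    ``U`` must have orthonormal columns spanning the estimated shared
    subspace; the result is the orthogonal projection of every sample onto
    its complement, so U' M_res = 0.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[0] != M.n_features:
        raise ValidationError(
            f"basis row dimension {U.shape} does not match m={M.n_features}"
        )
    if U.shape[1] == 0:
        return M.with_values(M.values.copy())
    gram = U.T @ U
    if not np.allclose(gram, np.eye(U.shape[1]), atol=1e-6):
        raise ValidationError("basis columns are not orthonormal")
    return M.with_values(M.values - U @ (U.T @ M.values))
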