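"""PACA fitting: shared-dimension selection and case-specific PCA.

The pipeline: center each matrix, compute all sample-space canonical pairs,
binary-search the *effective* shared dimension k — the minimal number of
shared axes whose removal reveals structure unique to cases — then project
the case matrix off the selected shared basis and take its principal
components as the putative subphenotypic gradient.

The search probes a candidate k by residualizing both matrices against
their top-k shared directions and asking whether the leading principal
component of the case residual carries significant variance in cases and/or
controls, judged against a null built by permuting the component's feature
loadings.  Four outcomes steer the search:

  (i)   significant in cases only            -> case-specific structure found;
                                                try smaller k (refine)
  (ii)  significant in both                  -> residual shared variation;
                                                try larger k — unless the
                                                case/control variance ratio
                                                exceeds gamma, which is
                                                treated like (i)
  (iii) significant in neither               -> over-corrected; try smaller k
  (iv)  significant in controls only         -> model assumption violated;
                                                terminate

The selected k is the smallest probed candidate classified (i) or
(ii)-with-ratio-pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.linalg

from .datamodel import AnalysisConfig, DataMatrix, ValidationError
from .cca import CanonicalSystem, residualize, sample_space_cca, shared_basis
from .io import align_features, standardize

logger = logging.getLogger("paca")

SCENARIOS = ("i", "ii", "iii", "iv", "ii-ratio-pass")


class PCVariancePair(NamedTuple):
    loading: np.ndarray
    var_x: float
    var_y: float
    degenerate: bool


def pc_variance_pair(x_res: DataMatrix, y_res: DataMatrix) -> PCVariancePair:
    """Top principal axis of the case residual and its variance in each group.

    ``loading`` is the unit m-vector maximizing sample variance in ``x_res``;
    ``var_x``/``var_y`` are the (ddof=1) variances of its projections across
    case and control samples.  A zero case residual yields ``var_x = 0`` with
    the ``degenerate`` flag set rather than an error.
    """
    if not np.array_equal(x_res.feature_ids, y_res.feature_ids):
        raise ValidationError("x_res and y_res must be feature-aligned")
    Xv = x_res.values
    if not Xv.any():
        loading = np.zeros(Xv.shape[0])
        loading[0] = 1.0
        vy = float(np.var(loading @ y_res.values, ddof=1))
        return PCVariancePair(loading, 0.0, vy, True)
    # Top left-singular vector via the smaller sample Gram matrix.
    m, n = Xv.shape
    if n <= m:
        G = Xv.T @ Xv
        w, V = scipy.linalg.eigh(G, subset_by_index=[n - 1, n - 1])
        img = Xv @ V[:, 0]
    else:
        G = Xv @ Xv.T
        w, V = scipy.linalg.eigh(G, subset_by_index=[m - 1, m - 1])
        img = V[:, 0]
    loading = img / np.linalg.norm(img)
    j = int(np.abs(loading).argmax())
    if loading[j] < 0:
        loading = -loading
    var_x = float(np.var(loading @ Xv, ddof=1))
    var_y = float(np.var(loading @ y_res.values, ddof=1))
    return PCVariancePair(loading, var_x, var_y, False)


def permutation_null_variance(
    loading: np.ndarray,
    M: DataMatrix,
    n_permutations: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null projection variances under uniform permutation of the loadings.

    Each draw permutes the m loading entries, projects the samples onto the
    permuted axis, and records the (ddof=1) variance — destroying the
    feature alignment between the axis and the data while preserving the
    loading's entry distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loading = np.asarray(loading, dtype=float)
    perms = rng.permuted(
        np.broadcast_to(loading, (n_permutations, loading.size)).copy(), axis=1
    )
    proj = perms @ M.values
    return proj.var(axis=1, ddof=1)


def classify_scenario(
    var_x: float,
    var_y: float,
    null_x: np.ndarray,
    null_y: np.ndarray,
    level: float,
    gamma: float,
) -> str:
    """Classify a probe into one of the four search scenarios.

    Significance is a one-sided empirical test: the observed variance must
    exceed the (1 - level) quantile of its permutation null.  When both
    groups are significant, a case/control ratio above ``gamma`` (with a
    zero control variance treated as an infinite ratio) upgrades the probe
    to ``"ii-ratio-pass"``, handled like scenario (i).
    """
    qx = float(np.quantile(null_x, 1.0 - level, method="higher"))
    qy = float(np.quantile(null_y, 1.0 - level, method="higher"))
    sig_x = var_x > qx
    sig_y = var_y > qy
    if sig_x and not sig_y:
        return "i"
    if not sig_x and not sig_y:
        return "iii"
    if not sig_x and sig_y:
        return "iv"
    ratio = np.inf if var_y == 0 else var_x / var_y
    return "ii-ratio-pass" if ratio > gamma else "ii"


@dataclass
class ProbeRecord:
    k_candidate: int
    scenario: str
    var_x: float
    var_y: float
    null_quantile_x: float
    null_quantile_y: float
    ratio: float


@dataclass
class KSelection:
    """Outcome of the binary search for the effective shared dimension."""

    k_selected: int
    trace: list[ProbeRecord] = field(default_factory=list)
    terminated_by: str = "converged"  # converged | scenario_iv | exhausted


def select_k(
    X: DataMatrix,
    Y: DataMatrix,
    cs: CanonicalSystem,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> KSelection:
    """Binary search for the minimal shared dimension to remove.

    ``cs`` must have been computed from this (X, Y) pair.  Scenarios (i),
    (iii) and ratio-passes move the search down, (ii) moves it up, and (iv)
    terminates it.  Returns k = 0 when no probe reveals case-specific
    structure.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    k_max = cs.R
    if k_max < 1:
        raise ValidationError("empty search space: no canonical pairs available")
    level = config.significance_level
    trace: list[ProbeRecord] = []

    def probe(k: int) -> str:
        Ux = shared_basis(cs, k, side="x")
        x_res = residualize(X, Ux)
        if config.y_residual_mode == "own":
            y_res = residualize(Y, shared_basis(cs, k, side="y"))
        else:
            y_res = residualize(Y, Ux)
        pv = pc_variance_pair(x_res, y_res)
        null_x = permutation_null_variance(pv.loading, x_res, config.n_permutations, rng)
        null_y = permutation_null_variance(pv.loading, y_res, config.n_permutations, rng)
        scenario = classify_scenario(pv.var_x, pv.var_y, null_x, null_y, level, config.gamma)
        trace.append(ProbeRecord(
            k_candidate=k,
            scenario=scenario,
            var_x=pv.var_x,
            var_y=pv.var_y,
            null_quantile_x=float(np.quantile(null_x, 1 - level, method="higher")),
            null_quantile_y=float(np.quantile(null_y, 1 - level, method="higher")),
            ratio=float(np.inf if pv.var_y == 0 else pv.var_x / pv.var_y),
        ))
        return scenario

    lo, hi = 1, k_max
    best: int | None = None
    saw_iv = False
    exhausted_at_top = False
    while lo <= hi:
        k = (lo + hi) // 2
        scenario = probe(k)
        if scenario in ("i", "ii-ratio-pass"):
            best = k if best is None else min(best, k)
            hi = k - 1
        elif scenario == "iii":
            hi = k - 1
        elif scenario == "ii":
            if k == k_max:
                exhausted_at_top = True
            lo = k + 1
        else:  # iv
            saw_iv = True
            break

    if saw_iv:
        logger.warning(
            "shared-dimension search hit control-only structure (scenario iv): "
            "the case-specific orthogonality assumption looks violated"
        )
        return KSelection(k_selected=best or 0, trace=trace, terminated_by="scenario_iv")
    # The search space starts at k = 1; when it bottoms out there, ask
    # whether removing nothing at all already exposes case-specific
    # structure (the k0 = 0 degenerate case) — k is the *minimal* dimension.
    if best == 1 and not saw_iv:
        if probe(0) in ("i", "ii-ratio-pass"):
            best = 0
    if best is None and exhausted_at_top:
        logger.warning(
            "residual shared variation persists at k = min(n0, n1); removing "
            "the full shared subspace (cPCA-infinity-like behaviour)"
        )
        return KSelection(k_selected=k_max, trace=trace, terminated_by="exhausted")
    return KSelection(k_selected=best or 0, trace=trace, terminated_by="converged")


@dataclass
class PacaFit:
    """Fitted PACA model for one case/control pair."""

    k_selection: KSelection
    shared_basis: np.ndarray          # m x k, orthonormal
    x_residual: DataMatrix            # case matrix with shared effects removed
    loadings: np.ndarray              # m x D principal axes of the residual
    scores: np.ndarray                # n1 x D case sample coordinates
    explained_variance: np.ndarray    # D, non-increasing
    canonical_correlations: np.ndarray
    config: AnalysisConfig

    @property
    def k_selected(self) -> int:
        return self.k_selection.k_selected


def fit_paca(
    X: DataMatrix,
    Y: DataMatrix,
    config: AnalysisConfig | None = None,
    n_components: int | None = None,
) -> PacaFit:
    """Fit PACA to a case matrix X against a control matrix Y.

    Steps: feature alignment and standardization (config default: feature
    centering per matrix), sample-space CCA, shared-dimension selection,
    residualization of X against the selected shared basis, and PCA of the
    residual.  Scores are the sample coordinates on the residual's top
    principal axes — the estimated case-specific gradient.
    """
    config = config or AnalysisConfig()
    X, Y = align_features(X, Y)
    if X.n_features <= max(X.n_samples, Y.n_samples):
        raise ValidationError(
            "PACA requires more features than samples in either group "
            f"(m={X.n_features}, n1={X.n_samples}, n0={Y.n_samples}); "
            "use fit_rpaca for this regime"
        )
    Xc = standardize(X, config.standardization)
    Yc = standardize(Y, config.standardization)
    Xc, Yc = align_features(Xc, Yc)  # zscore may drop constant features

    cs = sample_space_cca(Xc, Yc, ridge_epsilon=config.ridge_epsilon)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ks = select_k(Xc, Yc, cs, config, rng=rng)
    U = shared_basis(cs, ks.k_selected, side="x")
    x_res = residualize(Xc, U)

    D = n_components if n_components is not None else config.resolve_components(
        Xc.n_features, Xc.n_samples
    )
    D = min(D, min(x_res.shape))
    L, s, Vt = np.linalg.svd(x_res.values, full_matrices=False)
    L, s, Vt = L[:, :D], s[:D], Vt[:D, :]
    flip = np.sign(L[np.abs(L).argmax(axis=0), np.arange(D)])
    flip[flip == 0] = 1.0
    L = L * flip
    scores = (Vt.T * s) * flip
    explained = s**2 / (x_res.n_samples - 1)
    return PacaFit(
        k_selection=ks,
        shared_basis=U,
        x_residual=x_res,
        loadings=L,
        scores=scores,
        explained_variance=explained,
        canonical_correlations=cs.correlations.copy(),
        config=config,
    )
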