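"""Randomized PACA for the many-samples regime (m < max(n0, n1)).

Sample-space CCA needs more features than samples; when a cohort is larger
than the feature panel, we instead estimate the shared-variation-adjusted
case-sample covariance from many random sample subsets.  Each batch draws
equal-size case and control subsets small enough that the subset pair is a
valid PACA problem, runs the usual residualization on it, and contributes
the implied covariance entries for the sampled case pairs; entries are
averaged over the batches in which both samples co-occur.  The aggregated
covariance is eigendecomposed for the case-specific sample scores.

The batch protocol here is a reconstruction from the method's one-sentence
description (random subsets estimating the full adjusted sample covariance);
k is selected independently per batch since every batch is a self-contained
problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import AnalysisConfig, DataMatrix, ValidationError
from .cca import residualize, sample_space_cca, shared_basis
from .core import KSelection, PacaFit, select_k
from .io import align_features, standardize


@dataclass
class RpacaConfig:
    subset_size: int
    n_batches: int = 50
    aggregation: str = "mean"
    inner: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValidationError("n_batches must be positive")
        if self.aggregation != "mean":
            raise ValidationError("only mean aggregation is supported")
        if self.subset_size < 2:
            raise ValidationError("subset_size must be at least 2")


def fit_rpaca(
    X: DataMatrix,
    Y: DataMatrix,
    rconfig: RpacaConfig,
    n_components: int | None = None,
) -> PacaFit:
    """Randomized PACA: subset-averaged adjusted covariance, then eigen-scores.

    Every pair of case samples must co-occur in at least one batch; if not,
    the coverage check fails with a hint to increase ``n_batches``.
    Deterministic under ``rconfig.inner.seed``.
    """
    X, Y = align_features(X, Y)
    config = rconfig.inner
    Xc = standardize(X, config.standardization)
    Yc = standardize(Y, config.standardization)
    Xc, Yc = align_features(Xc, Yc)
    m, n1 = Xc.shape
    n0 = Yc.n_samples
    s = rconfig.subset_size
    if s > m - 1:
        raise ValidationError(
            f"subset_size={s} must be below m={m} so each batch is a "
            "features-exceed-samples problem"
        )
    if s > min(n0, n1):
        raise ValidationError(f"subset_size={s} exceeds min(n0, n1)={min(n0, n1)}")

    ss = np.random.SeedSequence(config.seed)
    rng_subset, rng_inner = (np.random.default_rng(c) for c in ss.spawn(2))

    cov_sum = np.zeros((n1, n1))
    cov_count = np.zeros((n1, n1))
    k_per_batch: list[int] = []
    for _ in range(rconfig.n_batches):
        idx1 = np.sort(rng_subset.choice(n1, size=s, replace=False))
        idx0 = np.sort(rng_subset.choice(n0, size=s, replace=False))
        Xb = Xc.subset_samples(idx1)
        Yb = Yc.subset_samples(idx0)
        cs = sample_space_cca(Xb, Yb, ridge_epsilon=config.ridge_epsilon)
        ks = select_k(Xb, Yb, cs, config, rng=rng_inner)
        k_per_batch.append(ks.k_selected)
        U = shared_basis(cs, ks.k_selected, side="x")
        res = residualize(Xb, U).values
        block = res.T @ res
        ij = np.ix_(idx1, idx1)
        cov_sum[ij] += block
        cov_count[ij] += 1.0

    uncovered = cov_count == 0
    if uncovered.any():
        i, j = np.argwhere(uncovered)[0]
        raise ValidationError(
            f"case samples {Xc.sample_ids[i]!r} and {Xc.sample_ids[j]!r} were "
            f"never co-sampled across {rconfig.n_batches} batches; increase "
            "n_batches or subset_size"
        )
    cov = cov_sum / cov_count
    cov = (cov + cov.T) / 2.0

    D = n_components if n_components is not None else config.resolve_components(m, n1)
    D = min(D, n1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:D]
    w, V = np.clip(w[order], 0, None), V[:, order]
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(D)])
    flip[flip == 0] = 1.0
    scores = V * flip * np.sqrt(w)

    k_med = int(np.median(k_per_batch))
    ks_global = KSelection(k_selected=k_med, trace=[], terminated_by="converged")
    return PacaFit(
        k_selection=ks_global,
        shared_basis=np.empty((m, 0)),
        x_residual=Xc,
        loadings=np.empty((m, 0)),
        scores=scores,
        explained_variance=w / max(n1 - 1, 1),
        canonical_correlations=np.empty(0),
        config=config,
    )
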