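"""Calibration and power experiments on simulated case/control data.

Two questions drive the evaluation of a subtype-discovery method:

* *Calibration*: on data with no case-specific structure, how often does the
  method claim to have found some, at a nominal error level?  We answer with
  a label re-randomization permutation test: the observed statistic is the
  variance of the method's top case component; null replicates re-partition
  case/control labels uniformly among all samples and refit.
  Re-partitioning destroys any case-specific structure while preserving all
  shared structure — exactly the null hypothesis of interest.

* *Power*: on data with a planted two-subtype axis, how well does the top
  component track the subtype?  Measured as the absolute Pearson correlation
  between the component's sample scores and the binary subtype indicator,
  averaged over simulation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, DataMatrix, ValidationError
from .baselines import fit_cpca, fit_cpca_inf, fit_pca, suggest_alphas
from .core import fit_paca
from .simulate import SimParams, SimTruth, simulate

# A method, for evaluation purposes, maps (X, Y, seed, truth?) to the sample
# scores of its top case component.  truth is only consulted by the
# best-alpha cPCA mode, which exists to reproduce an over-optimistic
# comparison and is meaningless outside simulations.
MethodFn = Callable[..., np.ndarray]


def _paca_top(X, Y, seed=0, truth=None, config: AnalysisConfig | None = None):
    cfg = replace(config, seed=seed) if config else AnalysisConfig(seed=seed)
    return fit_paca(X, Y, cfg, n_components=1).scores[:, 0]


def _pca_top(X, Y, seed=0, truth=None):
    return fit_pca(X, 1).scores[:, 0]


def _cpca_inf_top(X, Y, seed=0, truth=None):
    return fit_cpca_inf(X, Y, 1).scores[:, 0]


def _cpca_best_top(X, Y, seed=0, truth=None):
    if truth is None:
        raise ValidationError("best-alpha cPCA requires ground-truth subtypes")
    alphas = suggest_alphas(X, Y, n_alphas=10, seed=seed)
    best, best_corr = None, -1.0
    for a in alphas:
        s = fit_cpca(X, Y, a, 1).scores[:, 0]
        c = abs_corr(s, truth.subtype_labels)
        if c > best_corr:
            best, best_corr = s, c
    return best


METHODS: dict[str, MethodFn] = {
    "paca": _paca_top,
    "pca": _pca_top,
    "cpca_inf": _cpca_inf_top,
    "cpca_best": _cpca_best_top,
}


def abs_corr(scores: np.ndarray, labels: np.ndarray) -> float:
    """|Pearson correlation| between component scores and a binary label."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if np.std(scores) == 0 or np.std(labels) == 0:
        return 0.0
    return float(abs(np.corrcoef(scores, labels)[0, 1]))


def structure_significance_test(
    method_fit_fn: MethodFn,
    X: DataMatrix,
    Y: DataMatrix,
    n_perm: int = 19,
    level: float = 0.05,
    seed: int = 0,
) -> tuple[bool, float]:
    """Permutation test of whether the method's top component is case-specific.

    Statistic: variance of the top case-component scores.  Null: case and
    control columns re-partitioned uniformly among the pooled samples,
    method refit.  p = (1 + #{null >= observed}) / (1 + n_perm); reject when
    p <= level.  The default n_perm = 19 is the smallest count at which a
    level-0.05 test is exact (rejection iff the observed statistic exceeds
    every null draw).
    """
    rng = np.random.default_rng(seed)
    n1, n0 = X.n_samples, Y.n_samples
    obs = float(np.var(method_fit_fn(X, Y, seed=seed), ddof=1))
    pooled = np.hstack([X.values, Y.values])
    ids = np.array([f"s{i:05d}" for i in range(n1 + n0)], dtype=object)
    null = np.empty(n_perm)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_perm) % (2**31)
    for p in range(n_perm):
        idx = rng.permutation(n1 + n0)
        Xp = DataMatrix(pooled[:, idx[:n1]], X.feature_ids.copy(), ids[idx[:n1]], "target")
        Yp = DataMatrix(pooled[:, idx[n1:]], X.feature_ids.copy(), ids[idx[n1:]], "background")
        null[p] = float(np.var(method_fit_fn(Xp, Yp, seed=int(child_seeds[p])), ddof=1))
    p_value = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return bool(p_value <= level), float(p_value)


@dataclass
class CalibrationResult:
    method: str
    n_replicates: int
    level: float
    rejections: int
    type1_rate: float
    mc_se: float
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))


def run_calibration(
    methods: Sequence[str | tuple[str, MethodFn]],
    sim_null_params: SimParams,
    n_replicates: int = 100,
    level: float = 0.05,
    seed: int = 0,
    n_perm: int = 19,
) -> list[CalibrationResult]:
    """Empirical type-I error of the structure test on simulated null data."""
    if sim_null_params.signal_strength != 0:
        raise ValidationError("calibration requires signal_strength = 0 (null data)")
    resolved = [(m, METHODS[m]) if isinstance(m, str) else m for m in methods]
    sim_ss, test_ss = np.random.SeedSequence(seed).spawn(2)
    sim_seeds = sim_ss.generate_state(n_replicates) % (2**31)
    test_seeds = test_ss.generate_state(n_replicates) % (2**31)
    results = []
    for name, fn in resolved:
        rejections = 0
        pvals = np.empty(n_replicates)
        for r in range(n_replicates):
            params = replace(sim_null_params, seed=int(sim_seeds[r]))
            X, Y, _ = simulate(params)
            reject, pvals[r] = structure_significance_test(
                fn, X, Y, n_perm=n_perm, level=level, seed=int(test_seeds[r])
            )
            rejections += int(reject)
        rate = rejections / n_replicates
        results.append(CalibrationResult(
            method=name,
            n_replicates=n_replicates,
            level=level,
            rejections=rejections,
            type1_rate=rate,
            mc_se=float(np.sqrt(level * (1 - level) / n_replicates)),
            p_values=pvals,
        ))
    return results


@dataclass
class PowerCell:
    params: SimParams
    method: str
    mean_abs_corr: float
    se: float | None
    n_reps: int
    corrs: np.ndarray = field(default_factory=lambda: np.empty(0))


def run_power(
    grid: Sequence[SimParams],
    methods: Sequence[str | tuple[str, MethodFn]],
    n_reps: int = 20,
    seed: int = 0,
) -> list[PowerCell]:
    """Mean |corr(top component, subtype)| per grid cell per method."""
    resolved = [(m, METHODS[m]) if isinstance(m, str) else m for m in methods]
    cells = []
    for ci, params in enumerate(grid):
        rep_seeds = np.random.SeedSequence((seed, ci)).generate_state(2 * n_reps) % (2**31)
        per_method = {name: np.empty(n_reps) for name, _ in resolved}
        for r in range(n_reps):
            X, Y, truth = simulate(replace(params, seed=int(rep_seeds[r])))
            for name, fn in resolved:
                scores = fn(X, Y, seed=int(rep_seeds[n_reps + r]), truth=truth)
                per_method[name][r] = abs_corr(scores, truth.subtype_labels)
        for name, _ in resolved:
            c = per_method[name]
            se = float(c.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else None
            cells.append(PowerCell(
                params=params, method=name, mean_abs_corr=float(c.mean()),
                se=se, n_reps=n_reps, corrs=c,
            ))
    return cells


def calibration_table(results: Sequence[CalibrationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(method=r.method, n_replicates=r.n_replicates, level=r.level,
             rejections=r.rejections, type1_rate=r.type1_rate, mc_se=r.mc_se)
        for r in results
    ])


def power_table(cells: Sequence[PowerCell]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(method=c.method, signal_strength=c.params.signal_strength,
             sparsity=c.params.sparsity, prop=c.params.prop,
             violation_rho=c.params.violation_rho,
             mean_abs_corr=c.mean_abs_corr,
             se=np.nan if c.se is None else c.se, n_reps=c.n_reps)
        for c in cells
    ])
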