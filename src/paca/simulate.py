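"""Generative model for case/control matrices with a planted subtype axis.

Cases and controls share a k0-dimensional low-rank structure plus isotropic
Gaussian noise; cases additionally carry a weak, optionally sparse axis that
separates two planted subtypes:

    X = W0 Z0_X + W1 Z1 + E_X,   E ~ N(0, sigma^2)
    Y = W0 Z0_Y + E_Y

W0 has orthonormalized columns scaled by a decaying spectrum (the shared
axes: population structure, batch, cell composition, ...).  W1 is supported
on a random feature subset of size ceil(sparsity * m), projected orthogonal
to span(W0) so the case-specific axis is structurally orthogonal to the
shared ones, and scaled so its column norm is ``signal_strength`` times the
median shared-axis norm — a dimensionless strength knob.  The first
case-specific score is the centered subtype indicator (Bernoulli(prop)
labels).  ``violation_rho`` breaks the orthogonality *of scores*: the first
(strongest) shared factor of the cases is mixed with the subtype indicator
to reach that target correlation, while the uniquely case-specific norm
shrinks by sqrt(1 - rho^2) — violation reallocates subtype expression into
the shared subspace rather than adding new signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import DataMatrix, ValidationError


def default_shared_spectrum(k0: int, sigma: float = 1.0) -> np.ndarray:
    """Geometric decay from 10*sigma to 1*sigma across the k0 shared axes.

    The weakest shared axes sit at the noise scale and straddle typical
    subtype signal strengths, so the effective dimension to remove is
    genuinely smaller than k0 — the regime the method is designed for.
    """
    if k0 == 0:
        return np.empty(0)
    if k0 == 1:
        return np.array([10.0 * sigma])
    return np.geomspace(10.0, 1.0, k0) * sigma


@dataclass
class SimParams:
    """Simulation parameters; defaults are the desk-scale preset."""

    m: int = 400
    n1: int = 200
    n0: int = 200
    k0: int = 80
    k1: int = 1
    sigma: float = 1.0
    signal_strength: float = 2.0
    sparsity: float = 0.1
    prop: float = 0.5
    violation_rho: float = 0.0
    shared_spectrum: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sparsity <= 1):
            raise ValidationError("sparsity must lie in (0, 1]")
        if not (0 < self.prop < 1):
            raise ValidationError("prop must lie in (0, 1)")
        if not (0 <= self.violation_rho < 1):
            raise ValidationError("violation_rho must lie in [0, 1)")
        if self.k1 < 1:
            raise ValidationError("k1 must be at least 1")
        if self.sparsity * self.m < 1:
            raise ValidationError("sparsity * m must support at least one feature")
        if self.shared_spectrum is not None:
            spectrum = np.asarray(self.shared_spectrum, dtype=float)
            if spectrum.shape != (self.k0,) or np.any(spectrum <= 0):
                raise ValidationError("shared_spectrum must be k0 positive reals")
            self.shared_spectrum = spectrum

    def resolved_spectrum(self) -> np.ndarray:
        if self.shared_spectrum is not None:
            return self.shared_spectrum
        return default_shared_spectrum(self.k0, self.sigma)


@dataclass
class SimTruth:
    """Ground truth attached to a simulated (X, Y) pair."""

    subtype_labels: np.ndarray  # n1 binary
    W0: np.ndarray              # m x k0, spectrum-scaled shared directions
    W1: np.ndarray              # m x k1 case-specific directions
    Z0_X: np.ndarray            # k0 x n1
    Z0_Y: np.ndarray            # k0 x n0
    Z1: np.ndarray              # k1 x n1
    k0_true: int
    params: SimParams


def _draw_labels(rng: np.random.Generator, n1: int, prop: float) -> np.ndarray:
    # A subtype split needs both classes present; redraw on the same stream
    # in the (rare at realistic n1) degenerate event.
    for _ in range(1000):
        labels = rng.binomial(1, prop, n1)
        if 0 < labels.sum() < n1:
            return labels
    raise RuntimeError("could not draw a two-class subtype labelling")


def simulate(params: SimParams) -> tuple[DataMatrix, DataMatrix, SimTruth]:
    """Draw (X, Y, truth) from the generative model, reproducibly under seed."""
    rng = np.random.default_rng(params.seed)
    m, n1, n0, k0, k1 = params.m, params.n1, params.n0, params.k0, params.k1
    spectrum = params.resolved_spectrum()

    if k0 > 0:
        Q, _ = np.linalg.qr(rng.standard_normal((m, k0)))
        W0 = Q * spectrum
    else:
        Q = np.empty((m, 0))
        W0 = Q

    labels = _draw_labels(rng, n1, params.prop)
    z_subtype = labels - labels.mean()  # centered subtype indicator
    Z1 = np.vstack([z_subtype[None, :], rng.standard_normal((k1 - 1, n1))])

    W1_raw = np.zeros((m, k1))
    support = rng.choice(m, size=int(np.ceil(params.sparsity * m)), replace=False)
    W1_raw[support, :] = rng.standard_normal((support.size, k1))
    if k0 > 0:
        W1_raw = W1_raw - Q @ (Q.T @ W1_raw)  # enforce W0 _|_ W1
    norms = np.linalg.norm(W1_raw, axis=0)
    scale_ref = np.median(spectrum) if k0 > 0 else (params.sigma or 1.0)
    target_norm = params.signal_strength * scale_ref
    # Orthogonality violation reallocates subtype expression: a fraction
    # rho^2 of it moves into the strongest shared factor (below), and the
    # uniquely case-specific axis shrinks accordingly — at rho -> 1 the
    # subtype lives entirely inside the shared subspace and no contrastive
    # method can recover it.
    target_norm *= np.sqrt(1.0 - params.violation_rho**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        W1 = np.where(norms > 0, W1_raw / norms, 0.0) * target_norm
    if params.signal_strength == 0:
        W1 = np.zeros((m, k1))

    Z0_X = rng.standard_normal((k0, n1))
    Z0_Y = rng.standard_normal((k0, n0))
    if params.violation_rho > 0 and k0 > 0:
        t = (labels - labels.mean()) / labels.std()
        rho = params.violation_rho
        Z0_X[0, :] = rho * t + np.sqrt(1 - rho**2) * Z0_X[0, :]

    X = W0 @ Z0_X + W1 @ Z1 + params.sigma * rng.standard_normal((m, n1))
    Y = W0 @ Z0_Y + params.sigma * rng.standard_normal((m, n0))

    features = np.array([f"f{i:05d}" for i in range(m)], dtype=object)
    Xdm = DataMatrix(X, features, np.array([f"case{i:05d}" for i in range(n1)], dtype=object), "target")
    Ydm = DataMatrix(Y, features.copy(), np.array([f"ctrl{i:05d}" for i in range(n0)], dtype=object), "background")
    truth = SimTruth(labels, W0, W1, Z0_X, Z0_Y, Z1, k0, params)
    return Xdm, Ydm, truth


# Power-experiment grid -------------------------------------------

SPARSITY_LEVELS = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0)
STRENGTH_LEVELS = {"weak": 1.5, "moderate": 2.5, "strong": 4.0}
PROP_LEVELS = (0.5, 0.75, 0.9)


def power_experiment_grid(scale: str = "desk") -> list[SimParams]:
    """The power-experiment grid: sparsity x strength x subtype imbalance.

    ``scale="full"`` uses n = 2000 (1000 per group), m = 2000, k0 = 400;
    ``scale="desk"`` is the 1/5-scale preset (n = 400, m = 400, k0 = 80)
    preserving the n/m and k0/n ratios.  Deterministic: repeated calls
    return identical parameter lists (seeds are assigned per cell downstream).
    """
    if scale == "full":
        base = dict(m=2000, n1=1000, n0=1000, k0=400)
    elif scale == "desk":
        base = dict(m=400, n1=200, n0=200, k0=80)
    else:
        raise ValidationError("scale must be 'desk' or 'full'")
    grid = []
    for strength in STRENGTH_LEVELS.values():
        for prop in PROP_LEVELS:
            for sparsity in SPARSITY_LEVELS:
                grid.append(SimParams(
                    signal_strength=strength, sparsity=sparsity, prop=prop, **base
                ))
    return grid
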