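"""Core domain types: labelled feature-by-sample matrices and analysis configuration.

The central container is :class:`DataMatrix`, an ``m x n`` real matrix of
``m`` molecular features (rows) measured on ``n`` samples (columns), tagged
with a *role*: ``"target"`` for cases, ``"background"`` for controls.  All
downstream operations (shared-variation estimation, residualization, the
baselines and the simulator) speak this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

ROLES = ("target", "background")


class ValidationError(ValueError):
    """Raised when an input matrix or configuration violates an invariant."""


@dataclass
class DataMatrix:
    """A named feature-by-sample numeric matrix.

    Parameters
    ----------
    values
        Real matrix of shape ``(m, n)``: features in rows, samples in columns.
    feature_ids
        ``m`` unique feature identifiers.
    sample_ids
        ``n`` unique sample identifiers.
    role
        ``"target"`` (cases) or ``"background"`` (controls).
    """

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    role: str = "target"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D feature-by-sample matrix")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValidationError(
                f"need at least 1 feature and 2 samples, got shape {(m, n)}"
            )
        if self.feature_ids.shape != (m,):
            raise ValidationError("feature_ids length must match number of rows")
        if self.sample_ids.shape != (n,):
            raise ValidationError("sample_ids length must match number of columns")
        if len(set(self.feature_ids)) != m:
            raise ValidationError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids must be unique")
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain missing or non-finite entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        """Return a copy carrying ``values`` and the same ids/role."""
        return replace(self, values=np.asarray(values, dtype=float))

    def subset_features(self, index: Sequence[int]) -> "DataMatrix":
        index = np.asarray(index)
        return DataMatrix(
            self.values[index, :],
            self.feature_ids[index],
            self.sample_ids.copy(),
            self.role,
        )

    def subset_samples(self, index: Sequence[int]) -> "DataMatrix":
        index = np.asarray(index)
        return DataMatrix(
            self.values[:, index],
            self.feature_ids.copy(),
            self.sample_ids[index],
            self.role,
        )


@dataclass
class AnalysisConfig:
    """Knobs shared by the fitting pipeline.

    ``gamma`` is the case/control variance-ratio threshold used when a
    candidate component is significant in both groups: a ratio above
    ``gamma`` is taken as evidence that the component is case-specific
    despite explaining some control variance.  Default 10.

    ``y_residual_mode`` chooses how controls are residualized inside the
    shared-dimension search: ``"own"`` projects Y onto the orthonormalized
    control-side images of the canonical directions (each matrix expresses
    the shared structure in its own coordinates), ``"cross"`` reuses the
    case-side basis.
    """

    gamma: float = 10.0
    n_permutations: int = 100
    significance_level: float = 0.05
    seed: int = 0
    max_components: int | str = "auto"
    standardization: str = "center"
    ridge_epsilon: float | None = None  # None -> 1e-8 * trace(S)/n, per side
    y_residual_mode: str = "own"

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValidationError("gamma must be positive")
        if not (0 < self.significance_level < 1):
            raise ValidationError("significance_level must lie in (0, 1)")
        if self.n_permutations < 10:
            raise ValidationError("n_permutations must be at least 10")
        if self.standardization not in ("none", "center", "zscore"):
            raise ValidationError("standardization must be none|center|zscore")
        if self.ridge_epsilon is not None and self.ridge_epsilon < 0:
            raise ValidationError("ridge_epsilon must be nonnegative")
        if self.y_residual_mode not in ("own", "cross"):
            raise ValidationError("y_residual_mode must be 'own' or 'cross'")
        if self.max_components != "auto" and int(self.max_components) < 1:
            raise ValidationError("max_components must be positive or 'auto'")

    def resolve_components(self, m: int, n1: int) -> int:
        cap = max(1, min(m, n1 - 1))
        if self.max_components == "auto":
            return min(10, cap)
        return min(int(self.max_components), cap)
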