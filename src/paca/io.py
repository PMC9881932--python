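"""Reading, writing, alignment and standardization of feature-by-sample tables.

Input format: delimited text (tab or comma, auto-detected), header row of
sample IDs, first column of feature IDs.  Missing values are rejected by
default; per-feature mean imputation is available behind a flag because the
generative model downstream has no missingness mechanism.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import DataMatrix, ValidationError

logger = logging.getLogger("paca")


def _detect_delimiter(path: Path) -> str:
    with open(path, "r") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_matrix(path, role: str, impute_missing: bool = False) -> DataMatrix:
    """Load a delimited feature-by-sample table as a :class:`DataMatrix`.

    Parameters
    ----------
    path
        TSV/CSV file; first column feature IDs, header sample IDs.
    role
        ``"target"`` or ``"background"``.
    impute_missing
        Replace missing cells by the feature (row) mean instead of erroring.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate feature ID {dup!r} in {path}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample ID {dup!r} in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"malformed numeric cell at feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}: {raw.iat[i, j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_missing:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at feature {raw.index[i]!r}, sample "
                f"{raw.columns[j]!r} in {path}; pass impute_missing=True to "
                "fill with feature means"
            )
        n_missing = int(np.isnan(values).sum())
        row_means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), row_means, values)
        logger.warning("imputed %d missing cells in %s with feature means",
                       n_missing, path)
    return DataMatrix(values, raw.index.to_numpy(object), raw.columns.to_numpy(object), role)


def write_matrix(dm: DataMatrix, path) -> None:
    """Write a :class:`DataMatrix` as TSV (or CSV for a ``.csv`` path)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.DataFrame(dm.values, index=dm.feature_ids, columns=dm.sample_ids)
    frame.to_csv(path, sep=sep, float_format="%.17g")


def align_features(X: DataMatrix, Y: DataMatrix) -> tuple[DataMatrix, DataMatrix]:
    """Restrict both matrices to their common features, in X's row order.

    A sample ID shared between the two matrices is an error: a sample cannot
    be both a case and a control.
    """
    overlap = set(X.sample_ids) & set(Y.sample_ids)
    if overlap:
        raise ValidationError(
            f"sample IDs appear in both matrices (e.g. {sorted(overlap)[0]!r}); "
            "cases and controls must be disjoint"
        )
    y_pos = {f: i for i, f in enumerate(Y.feature_ids)}
    keep_x, keep_y = [], []
    for i, f in enumerate(X.feature_ids):
        j = y_pos.get(f)
        if j is not None:
            keep_x.append(i)
            keep_y.append(j)
    if not keep_x:
        raise ValidationError("feature sets of X and Y are disjoint")
    return X.subset_features(keep_x), Y.subset_features(keep_y)


def standardize(M: DataMatrix, mode: str = "center") -> DataMatrix:
    """Feature-wise standardization across samples.

    ``center`` subtracts each feature's mean; ``zscore`` additionally scales
    to unit variance, dropping constant features with a logged warning
    (they carry no sample-level information and would divide by zero).
    """
    if mode == "none":
        return M.with_values(M.values.copy())
    means = M.values.mean(axis=1, keepdims=True)
    centered = M.values - means
    if mode == "center":
        return M.with_values(centered)
    if mode != "zscore":
        raise ValidationError(f"unknown standardization mode {mode!r}")
    sd = centered.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = M.feature_ids[~keep]
        logger.warning("dropping %d constant feature(s) under zscore: %s",
                       len(dropped), ", ".join(map(str, dropped[:5])))
    out = M.subset_features(np.flatnonzero(keep))
    return out.with_values(centered[keep] / sd[keep, None])
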