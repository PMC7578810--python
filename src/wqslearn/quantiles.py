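"""Rank-based decile scoring of exposure columns.

Each exposure column is mapped to integer scores 0-9 by average rank, which
makes every downstream index scale-free: any strictly monotone transform of
a column leaves its scores unchanged.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError

N_QUANTILES = 10


def decile_scores(x: np.ndarray, n_quantiles: int = N_QUANTILES) -> np.ndarray:
    """Score one column into ``n_quantiles`` ordered bins coded 0..n_quantiles-1.

    Average ranks are floored into equal-count bins, so tied values always
    share a single bin and, for distinct values, bins hold n/10 +/- 1
    observations.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("decile_scores expects a 1-D column")
    if np.any(~np.isfinite(x)):
        raise ValidationError("column contains non-finite values")
    if np.ptp(x) == 0:
        raise ValidationError("constant column cannot be deciled")
    n = x.size
    if n < n_quantiles:
        raise ValidationError(f"need at least {n_quantiles} observations, got {n}")
    if np.unique(x).size < n_quantiles:
        warnings.warn(
            "fewer distinct values than quantile bins; ties share a bin",
            UserWarning,
            stacklevel=2,
        )
    ranks = rankdata(x, method="average")
    q = np.floor((ranks - 0.5) * n_quantiles / n).astype(np.int64)
    return np.clip(q, 0, n_quantiles - 1)


def decile_transform(X: pd.DataFrame, n_quantiles: int = N_QUANTILES) -> pd.DataFrame:
    """Column-wise decile scoring of an exposure table.

    Returns an integer DataFrame with the same index and columns; entries lie
    in {0, ..., n_quantiles-1} and are monotone in the original values within
    each column.
    """
    if X.shape[1] == 0:
        raise ValidationError("exposure table has no columns")
    out = {}
    for col in X.columns:
        out[col] = decile_scores(X[col].to_numpy(), n_quantiles)
    return pd.DataFrame(out, index=X.index)
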