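"""Pearson-correlation primitives shared across the pipeline.

All correlations are computed over pairwise-complete observations (entries
where both series are non-missing).  A correlation is *degenerate* — and
reported as 0 — when fewer than 3 complete pairs exist or either series has
zero variance over the complete pairs; downstream, "no evidence of
correlation" must contribute no differential-correlation score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pairwise_correlation",
    "correlation_matrix",
    "fisher_z",
    "MIN_COMPLETE_PAIRS",
    "FISHER_EPS",
]

#: minimum number of complete (both non-missing) pairs for a defined correlation
MIN_COMPLETE_PAIRS = 3

#: clipping for the Fisher z-transform: atanh diverges at |r| = 1, so r is
#: clipped to 1 - FISHER_EPS, capping any single pair's contribution at
#: atanh(1 - 1e-6) ~ 7.2543
FISHER_EPS = 1e-6


def pairwise_correlation(x, y, return_degenerate: bool = False):
    """Pearson correlation of two series over pairwise-complete entries.

    Parameters
    ----------
    x, y : array-like of equal length
        Value series; NaN marks a missing entry.
    return_degenerate : bool
        When True, return ``(r, degenerate)`` where ``degenerate`` flags
        fewer than :data:`MIN_COMPLETE_PAIRS` complete pairs or zero
        variance in either series; ``r`` is 0 in that case.

    Returns
    -------
    float, or (float, bool)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"series length mismatch: {x.shape} vs {y.shape} (need equal 1-d)"
        )
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    degenerate = True
    r = 0.0
    if n >= MIN_COMPLETE_PAIRS:
        xs = x[mask]
        ys = y[mask]
        xd = xs - xs.mean()
        yd = ys - ys.mean()
        denom = np.sqrt((xd @ xd) * (yd @ yd))
        if denom > 0.0:
            r = float(np.clip((xd @ yd) / denom, -1.0, 1.0))
            degenerate = False
    if return_degenerate:
        return r, degenerate
    return r


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation between the rows of ``values``.

    Degenerate entries are 0; the diagonal is 1.  Uses a dense fast path
    (``np.corrcoef``) when no entry is missing, otherwise falls back to
    pandas' pairwise-complete kernel.  Both paths apply the same formula,
    so they agree to floating-point roundoff.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-d rows-are-variables array")
    n_rows, n_obs = values.shape
    if n_rows == 0:
        return np.zeros((0, 0))
    if not np.isnan(values).any():
        if n_obs < MIN_COMPLETE_PAIRS:
            corr = np.zeros((n_rows, n_rows))
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(values)
            corr = np.asarray(corr, dtype=float).reshape(n_rows, n_rows)
            corr[~np.isfinite(corr)] = 0.0
            corr = np.clip(corr, -1.0, 1.0)
    else:
        corr = (
            pd.DataFrame(values.T)
            .corr(min_periods=MIN_COMPLETE_PAIRS)
            .to_numpy()
        )
        corr[~np.isfinite(corr)] = 0.0
        corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(r):
    """Variance-stabilising Fisher z-transform, z = atanh(r).

    ``r`` is clipped to +-(1 - 1e-6) so that perfectly correlated pairs map
    to a large finite value (~7.2543) rather than infinity.  Accepts scalars
    or arrays; raises on |r| > 1.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlation outside [-1, 1]")
    z = np.arctanh(np.clip(arr, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))
    if np.isscalar(r) or arr.ndim == 0:
        return float(z)
    return z
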