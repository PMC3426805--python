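"""Correlation of methylation as a function of genomic distance.

Methylation is locally coordinated: probes interrogating loci a few
hundred base pairs apart tend to be strongly correlated, and the
correlation decays to a baseline beyond a couple of kilobases.  This
module quantifies that decay: enumerate probe pairs with their genomic
distance, compute each pair's beta-value correlation, and summarize the
correlation distribution per distance bin (boxplot-style quartiles and
whiskers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BetaMatrix, DistanceBinSummary, ValidationError
from .correlation import pairwise_correlation

__all__ = ["neighboring_pairs", "correlation_by_distance", "DEFAULT_BIN_EDGES"]

#: (0,200], (200,400], ..., (1800,2000]; distances beyond the last edge go
#: to an explicit overflow bin, never silently dropped
DEFAULT_BIN_EDGES = tuple(range(0, 2001, 200))


def neighboring_pairs(
    ann: pd.DataFrame,
    probes,
    max_distance: int,
    adjacent_only: bool = True,
) -> pd.DataFrame:
    """Enumerate same-chromosome probe pairs with genomic distance.

    Parameters
    ----------
    ann : probe annotation (indexed by probe_id, with chromosome/position).
    probes : probe ids to consider; all must be annotated.
    max_distance : int, base pairs; pairs farther apart are not emitted.
    adjacent_only : bool
        True (default): only consecutive probes in per-chromosome position
        order ("neighboring probes").  False: every pair within
        ``max_distance`` on the same chromosome (windowed mode).

    Returns
    -------
    DataFrame with columns probe_a, probe_b, distance.
    """
    probes = list(probes)
    missing = [p for p in probes if p not in ann.index]
    if missing:
        raise ValidationError(f"probes missing from annotation: {missing}")
    sub = ann.loc[probes, ["chromosome", "position"]]
    records = []
    for _, grp in sub.groupby("chromosome", sort=False):
        grp = grp.sort_values("position", kind="stable")
        ids = grp.index.to_numpy()
        pos = grp["position"].to_numpy()
        if adjacent_only:
            dist = np.abs(np.diff(pos))
            for i, d in enumerate(dist):
                if d <= max_distance:
                    records.append((ids[i], ids[i + 1], int(d)))
        else:
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    d = int(abs(pos[j] - pos[i]))
                    if d > max_distance:
                        break  # positions sorted; farther j only grows d
                    records.append((ids[i], ids[j], d))
    return pd.DataFrame(records, columns=["probe_a", "probe_b", "distance"])


def _box_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return q1, med, q3, lo, hi


def correlation_by_distance(
    m: BetaMatrix, pairs: pd.DataFrame, bin_edges=DEFAULT_BIN_EDGES
) -> DistanceBinSummary:
    """Summarize pairwise probe correlations per genomic-distance bin.

    Each pair's Pearson correlation (pairwise-complete) is assigned to the
    unique half-open bin (lower, upper]; distances beyond the last edge are
    counted in an overflow row.  Per bin: pair count, quartiles, and Tukey
    whisker bounds of the correlation distribution.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    values = m.data
    corrs = np.empty(len(pairs))
    for k, (pa, pb) in enumerate(zip(pairs["probe_a"], pairs["probe_b"])):
        corrs[k] = pairwise_correlation(
            values.loc[pa].to_numpy(), values.loc[pb].to_numpy()
        )
    dist = pairs["distance"].to_numpy() if len(pairs) else np.empty(0)

    rows = []
    for lo_edge, hi_edge in zip(edges[:-1], edges[1:]):
        in_bin = (dist > lo_edge) & (dist <= hi_edge)
        vals = corrs[in_bin]
        if len(vals):
            q1, med, q3, wlo, whi = _box_stats(vals)
        else:
            q1 = med = q3 = wlo = whi = np.nan
        rows.append((lo_edge, hi_edge, int(in_bin.sum()), q1, med, q3, wlo, whi))

    overflow = (dist > edges[-1]) | (dist <= edges[0])
    n_overflow = int(overflow.sum())
    vals = corrs[overflow]
    if len(vals):
        q1, med, q3, wlo, whi = _box_stats(vals)
    else:
        q1 = med = q3 = wlo = whi = np.nan
    rows.append((edges[-1], np.inf, n_overflow, q1, med, q3, wlo, whi))

    table = pd.DataFrame(
        rows,
        columns=[
            "bin_lower",
            "bin_upper",
            "n_pairs",
            "q1",
            "median",
            "q3",
            "whisker_low",
            "whisker_high",
        ],
    )
    return DistanceBinSummary(bin_edges=edges, table=table, n_overflow=n_overflow)
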