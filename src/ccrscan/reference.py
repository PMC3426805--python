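"""Straight-from-the-definition reference scorer (test oracle).

A deliberately naive reimplementation of the CCR scoring definition in
plain Python loops — split samples at beta >= 0.2, average member betas
into module profiles, Pearson-correlate every module pair within each
group over complete observations, Fisher-transform, and sum the absolute
z-differences.  It shares no code with the pipeline (only the two
numerical constants, the Fisher clip and the minimum pair count, which are
part of the definition) and exists solely so the optimized implementation
can be checked against it on small instances.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["score_candidates_reference"]

_CLIP = 1e-6
_MIN_PAIRS = 3


def _pearson(xs: list[float], ys: list[float]) -> float:
    """Two-pass Pearson correlation; degenerate cases are 0."""
    pairs = [
        (x, y) for x, y in zip(xs, ys) if not (math.isnan(x) or math.isnan(y))
    ]
    n = len(pairs)
    if n < _MIN_PAIRS:
        return 0.0
    mx = sum(p[0] for p in pairs) / n
    my = sum(p[1] for p in pairs) / n
    sxy = sum((x - mx) * (y - my) for x, y in pairs)
    sxx = sum((x - mx) ** 2 for x, _ in pairs)
    syy = sum((y - my) ** 2 for _, y in pairs)
    denom = math.sqrt(sxx * syy)
    if denom <= 0.0:
        return 0.0
    return max(-1.0, min(1.0, sxy / denom))


def _fisher(r: float) -> float:
    return math.atanh(max(-1.0 + _CLIP, min(1.0 - _CLIP, r)))


def _module_means(
    data: pd.DataFrame, labels: np.ndarray, sample_idx: list[int]
) -> list[list[float]]:
    values = data.to_numpy(dtype=float)
    n_modules = int(max(labels)) + 1
    profiles = []
    for k in range(n_modules):
        members = [i for i, lab in enumerate(labels) if lab == k]
        row = []
        for j in sample_idx:
            vals = [values[i, j] for i in members if not math.isnan(values[i, j])]
            row.append(sum(vals) / len(vals) if vals else math.nan)
        profiles.append(row)
    return profiles


def score_candidates_reference(
    data: pd.DataFrame,
    module_labels: np.ndarray,
    threshold: float = 0.2,
    min_minority_fraction: float = 0.15,
    min_group_size: int = 3,
    candidates=None,
) -> pd.DataFrame:
    """Score candidates directly from the definition.

    Parameters mirror the pipeline: ``data`` is probes x samples,
    ``module_labels`` assigns each probe (row) a module index.  Returns a
    table with columns candidate_probe, score_s, n_methylated,
    n_unmethylated, valid, rank.
    """
    values = data.to_numpy(dtype=float)
    probe_ids = list(data.index)
    if candidates is None:
        candidates = probe_ids
    rows = []
    for cand in candidates:
        i = probe_ids.index(cand)
        meth_idx = []
        unmeth_idx = []
        for j in range(values.shape[1]):
            v = values[i, j]
            if math.isnan(v):
                continue
            (meth_idx if v >= threshold else unmeth_idx).append(j)
        n_meth, n_unmeth = len(meth_idx), len(unmeth_idx)
        total = n_meth + n_unmeth
        frac = min(n_meth, n_unmeth) / total if total else 0.0
        valid = frac >= min_minority_fraction and min(n_meth, n_unmeth) >= min_group_size
        score = math.nan
        if valid:
            prof1 = _module_means(data, module_labels, unmeth_idx)
            prof2 = _module_means(data, module_labels, meth_idx)
            n_modules = len(prof1)
            score = 0.0
            for a in range(n_modules):
                for b in range(a + 1, n_modules):
                    r1 = _pearson(prof1[a], prof1[b])
                    r2 = _pearson(prof2[a], prof2[b])
                    score += abs(_fisher(r1) - _fisher(r2))
        rows.append((cand, score, n_meth, n_unmeth, valid))
    table = pd.DataFrame(
        rows,
        columns=[
            "candidate_probe",
            "score_s",
            "n_methylated",
            "n_unmethylated",
            "valid",
        ],
    )
    table["rank"] = np.nan
    valid_part = table[table["valid"]].sort_values(
        ["score_s", "candidate_probe"], ascending=[False, True], kind="stable"
    )
    table.loc[valid_part.index, "rank"] = np.arange(1.0, len(valid_part) + 1)
    return table
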