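"""CCR-association scoring of candidate probes.

For each candidate probe the samples are dichotomized by its methylation
status (beta >= 0.2 is "methylated"), module-module correlation matrices
are computed separately within the two groups, and the global change in
correlation structure is summarized as

    s = sum over module pairs i < j of |z1(i, j) - z2(i, j)|

where z = atanh(r) is the Fisher transform of the group-wise Pearson
correlation.  Candidates whose split is extremely unbalanced (smaller
group under 15% of assessed samples, or under 3 samples) are not scored —
correlations estimated from a handful of samples are unreliable.
Candidates are rank-ordered by s; high ranks mark probes whose on/off
status is associated with global changes in methylation correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import BetaMatrix, DichotomySplit, ModuleSet
from .correlation import correlation_matrix, fisher_z
from .modules import CoherenceClustering, module_meta_profiles

__all__ = [
    "CCRScorer",
    "dichotomize",
    "group_correlation_matrix",
    "ccr_score",
    "score_all_candidates",
    "split_train_test",
    "score_consistency",
    "fisher_z",
]

DEFAULT_BETA_THRESHOLD = 0.2
DEFAULT_MIN_MINORITY_FRACTION = 0.15
MIN_GROUP_SIZE = 3

SCORE_COLUMNS = [
    "candidate_probe",
    "score_s",
    "n_methylated",
    "n_unmethylated",
    "valid",
    "rank",
]


def _split_arrays(beta_row: np.ndarray, threshold: float):
    missing = np.isnan(beta_row)
    meth = (beta_row >= threshold) & ~missing
    unmeth = ~meth & ~missing
    return meth, unmeth, missing


def _minority_fraction(n_meth: int, n_unmeth: int) -> float:
    total = n_meth + n_unmeth
    if total == 0:
        return 0.0
    return min(n_meth, n_unmeth) / total


def dichotomize(
    m: BetaMatrix,
    candidate,
    threshold: float = DEFAULT_BETA_THRESHOLD,
    min_minority_fraction: float = DEFAULT_MIN_MINORITY_FRACTION,
    min_group_size: int = MIN_GROUP_SIZE,
) -> DichotomySplit:
    """Split samples into methylated / unmethylated by one candidate probe.

    A sample is methylated iff its beta at the candidate is >= ``threshold``
    (the comparator is >=, so beta exactly at the cutoff counts as
    methylated); samples with a missing beta are excluded.  The split is
    valid when the smaller group holds at least ``min_minority_fraction``
    of the assessed samples and both groups have at least
    ``min_group_size`` samples (a correlation needs 3 points).
    """
    row = m.probe(candidate).to_numpy(dtype=float)
    samples = np.asarray(m.sample_ids, dtype=object)
    meth, unmeth, missing = _split_arrays(row, threshold)
    n_meth, n_unmeth = int(meth.sum()), int(unmeth.sum())
    frac = _minority_fraction(n_meth, n_unmeth)
    valid = frac >= min_minority_fraction and min(n_meth, n_unmeth) >= min_group_size
    return DichotomySplit(
        candidate_probe=candidate,
        threshold=threshold,
        methylated_samples=list(samples[meth]),
        unmethylated_samples=list(samples[unmeth]),
        excluded_samples=list(samples[missing]),
        minority_fraction=frac,
        valid=bool(valid),
    )


def group_correlation_matrix(meta: pd.DataFrame, samples) -> np.ndarray:
    """Module-module correlation matrix restricted to a sample subset.

    ``meta`` is modules x samples.  Entries are pairwise-complete Pearson
    correlations; degenerate pairs are 0; the diagonal is 1.
    """
    samples = list(samples)
    if len(samples) < MIN_GROUP_SIZE:
        raise ValueError(
            f"need at least {MIN_GROUP_SIZE} samples for a correlation matrix, "
            f"got {len(samples)}"
        )
    return correlation_matrix(meta[samples].to_numpy(dtype=float))


def _score_from_matrices(r1: np.ndarray, r2: np.ndarray) -> float:
    iu = np.triu_indices_from(r1, k=1)
    return float(np.abs(fisher_z(r1[iu]) - fisher_z(r2[iu])).sum())


def ccr_score(split: DichotomySplit, meta: pd.DataFrame) -> float:
    """The scalar differential-correlation score s for one valid split.

    s = sum_{i<j} |z1(i,j) - z2(i,j)| with z1/z2 from the unmethylated and
    methylated groups respectively; the diagonal is excluded and each
    unordered pair counts once (summing the full matrix would exactly
    double s without changing any ranking).
    """
    if not split.valid:
        raise ValueError(
            f"candidate {split.candidate_probe!r} failed the imbalance guard "
            f"(minority fraction {split.minority_fraction:.3f}); not scored"
        )
    r1 = group_correlation_matrix(meta, split.unmethylated_samples)
    r2 = group_correlation_matrix(meta, split.methylated_samples)
    return _score_from_matrices(r1, r2)


class CCRScorer(TransformerMixin, BaseEstimator):
    """Score every probe for association with global correlation changes.

    A feature scorer/selector in the SelectKBest mould: ``fit`` computes
    the CCR score of each candidate probe of a samples x probes beta
    matrix; ``transform`` keeps the ``n_markers`` top-scoring probes.

    Parameters
    ----------
    modules : None, fitted CoherenceClustering, or array of module labels
        Module structure used for the surrogate correlation space.  When
        None, a :class:`CoherenceClustering` is fitted internally on the
        same data with ``coherence_threshold`` and ``random_state``.
    beta_threshold : float, default 0.2
        Dichotomization cutoff on the beta value.
    min_minority_fraction : float, default 0.15
        Imbalance guard: the smaller group must hold at least this
        fraction of the assessed samples, else the candidate is left
        unscored.
    min_group_size : int, default 3
    n_markers : int, default 200
        Number of top-ranked probes kept by ``transform``.
    candidates : sequence of probe ids or None
        Restrict scoring to these probes (default: every column).
    coherence_threshold, random_state :
        Passed to the internal clustering when ``modules`` is None.

    Attributes
    ----------
    score_table_ : pandas.DataFrame
        Columns candidate_probe, score_s, n_methylated, n_unmethylated,
        valid, rank.  Invalid candidates are present but unscored (NaN
        score, NaN rank); rank is dense (1 = best) over valid candidates,
        descending in score, ties broken by probe ID.
    meta_profiles_ : pandas.DataFrame, modules x samples.
    module_labels_ : ndarray of module index per probe.
    top_markers_ : list of the n_markers best probes.
    """

    def __init__(
        self,
        modules=None,
        beta_threshold: float = DEFAULT_BETA_THRESHOLD,
        min_minority_fraction: float = DEFAULT_MIN_MINORITY_FRACTION,
        min_group_size: int = MIN_GROUP_SIZE,
        n_markers: int = 200,
        candidates=None,
        coherence_threshold: float = 0.7,
        random_state: int | None = None,
    ):
        self.modules = modules
        self.beta_threshold = beta_threshold
        self.min_minority_fraction = min_minority_fraction
        self.min_group_size = min_group_size
        self.n_markers = n_markers
        self.candidates = candidates
        self.coherence_threshold = coherence_threshold
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _resolve_meta(self, values: np.ndarray, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (module labels per probe, modules x samples meta matrix)."""
        modules = self.modules
        if modules is None:
            modules = CoherenceClustering(
                coherence_threshold=self.coherence_threshold,
                random_state=self.random_state,
            ).fit(X)
        if isinstance(modules, CoherenceClustering):
            labels = np.asarray(modules.labels_)
        elif isinstance(modules, ModuleSet):
            labels = modules.module_assignments.to_numpy(dtype=int)
        else:
            labels = np.asarray(modules, dtype=int)
        if labels.shape[0] != values.shape[0]:
            raise ValueError("module labels do not match the number of probes")
        meta = module_meta_profiles(values, labels)
        return labels, meta

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            probe_ids = list(X.columns)
            sample_ids = list(X.index)
            values = X.to_numpy(dtype=float).T  # probes x samples
        else:
            values = np.asarray(X, dtype=float).T
            probe_ids = list(range(values.shape[0]))
            sample_ids = list(range(values.shape[1]))
        candidates = self.candidates
        if candidates is None:
            candidates = probe_ids
        candidates = list(candidates)
        if len(candidates) == 0:
            raise ValueError("empty candidate list")
        pos = {p: i for i, p in enumerate(probe_ids)}
        unknown = [c for c in candidates if c not in pos]
        if unknown:
            raise KeyError(f"unknown candidate probes: {unknown}")

        labels, meta = self._resolve_meta(values, X)

        rows = []
        for cand in candidates:
            beta = values[pos[cand]]
            meth, unmeth, _ = _split_arrays(beta, self.beta_threshold)
            n_meth, n_unmeth = int(meth.sum()), int(unmeth.sum())
            frac = _minority_fraction(n_meth, n_unmeth)
            valid = (
                frac >= self.min_minority_fraction
                and min(n_meth, n_unmeth) >= self.min_group_size
            )
            score = np.nan
            if valid:
                r1 = correlation_matrix(meta[:, unmeth])
                r2 = correlation_matrix(meta[:, meth])
                score = _score_from_matrices(r1, r2)
            rows.append((cand, score, n_meth, n_unmeth, bool(valid)))

        table = pd.DataFrame(
            rows,
            columns=["candidate_probe", "score_s", "n_methylated", "n_unmethylated", "valid"],
        )
        table["rank"] = np.nan
        valid_part = table[table["valid"]].sort_values(
            ["score_s", "candidate_probe"],
            ascending=[False, True],
            kind="stable",
        )
        table.loc[valid_part.index, "rank"] = np.arange(1, len(valid_part) + 1)

        self.probe_ids_ = probe_ids
        self.sample_ids_ = sample_ids
        self.module_labels_ = labels
        self.meta_profiles_ = pd.DataFrame(meta, columns=sample_ids)
        self.score_table_ = table[SCORE_COLUMNS]
        order = valid_part["candidate_probe"].tolist()
        self.top_markers_ = order[: self.n_markers]
        return self

    def transform(self, X):
        """Keep only the top ``n_markers`` scoring probes (columns)."""
        check_is_fitted(self, "score_table_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.top_markers_]
        idx = [self.probe_ids_.index(p) for p in self.top_markers_]
        return np.asarray(X)[:, idx]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "score_table_")
        mask = np.zeros(len(self.probe_ids_), dtype=bool)
        sel = [self.probe_ids_.index(p) for p in self.top_markers_]
        mask[sel] = True
        return np.asarray(sel) if indices else mask


def score_all_candidates(
    m: BetaMatrix,
    modules: ModuleSet,
    candidates,
    threshold: float = DEFAULT_BETA_THRESHOLD,
    min_minority_fraction: float = DEFAULT_MIN_MINORITY_FRACTION,
) -> pd.DataFrame:
    """Score candidate probes against a ModuleSet; returns the score table.

    Thin wrapper over :class:`CCRScorer` with externally supplied modules.
    """
    est = CCRScorer(
        modules=modules,
        beta_threshold=threshold,
        min_minority_fraction=min_minority_fraction,
        candidates=list(candidates),
    ).fit(m.data.T)
    return est.score_table_


def split_train_test(sample_ids, n_train: int, seed: int | None):
    """Seeded uniform random disjoint, exhaustive train/test split."""
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    perm = np.random.default_rng(seed).permutation(n)
    train = [sample_ids[i] for i in perm[:n_train]]
    test = [sample_ids[i] for i in perm[n_train:]]
    return train, test


def score_consistency(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> float:
    """Pearson correlation of scores over candidates valid in both tables."""
    a = scores_a[scores_a["valid"]].set_index("candidate_probe")["score_s"]
    b = scores_b[scores_b["valid"]].set_index("candidate_probe")["score_s"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 commonly valid candidates, got {len(common)}"
        )
    x = a.loc[common].to_numpy()
    y = b.loc[common].to_numpy()
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise ValueError("zero variance in one of the score vectors")
    return float((xd @ yd) / denom)
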