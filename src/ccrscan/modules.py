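"""Coherence-constrained randomized agglomerative clustering of probes.

Probes are grouped into modules of highly correlated probes so that
module-module correlations can stand in for probe-probe correlations in the
differential-correlation scan.  The algorithm is a randomized agglomeration
with a quality floor: a merge is committed only if the merged cluster's
*coherence* — the average Pearson correlation between each member and the
cluster mean — stays at or above a user threshold (default 0.7).  Each
cluster's mean beta profile is its *meta-probe*.

Algorithm (one iteration):
  all clusters are marked available; repeatedly pick an available cluster
  uniformly at random and find its nearest neighbour among all other
  clusters by average-linkage Pearson similarity.  If the neighbour is
  unavailable the picked cluster is retired for this iteration; otherwise
  the merge is tried and committed only when the union's coherence meets
  the threshold (the merged cluster is then retired; on rejection only the
  picked cluster is retired).  The iteration ends when nothing is
  available; the algorithm ends when an iteration commits no merge, which
  roughly halves the cluster count per iteration early on and guarantees
  every returned module's coherence >= threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import BetaMatrix, ModuleSet
from .correlation import MIN_COMPLETE_PAIRS, correlation_matrix, pairwise_correlation

__all__ = [
    "CoherenceClustering",
    "agglomerate",
    "cluster_coherence",
    "cluster_similarity",
    "module_meta_profiles",
]


def _as_profile_array(profiles) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        return profiles.to_numpy(dtype=float)
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def cluster_coherence(member_profiles) -> float:
    """Average Pearson correlation between each member and the cluster mean.

    Singleton clusters have coherence 1 by convention.  Degenerate
    member-to-mean correlations (fewer than 3 complete pairs, or zero
    variance) count as 0.
    """
    vals = _as_profile_array(member_profiles)
    m = vals.shape[0]
    if m == 0:
        raise ValueError("cluster_coherence requires at least one member")
    if m == 1:
        return 1.0
    mask = ~np.isnan(vals)
    counts = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mu = np.where(counts > 0, np.nansum(vals, axis=0) / counts, np.nan)
    # a member's non-missing entries always have a defined mean (the member
    # itself contributes), so each member's complete-pair mask is its own
    filled = np.where(mask, vals, 0.0)
    mu_f = np.where(mask, mu, 0.0)
    n_i = mask.sum(axis=1).astype(float)
    sum_v = filled.sum(axis=1)
    sum_m = mu_f.sum(axis=1)
    sxy = (filled * mu_f).sum(axis=1) - sum_v * sum_m / np.where(n_i > 0, n_i, 1)
    sxx = (filled * filled).sum(axis=1) - sum_v * sum_v / np.where(n_i > 0, n_i, 1)
    syy = (mu_f * mu_f).sum(axis=1) - sum_m * sum_m / np.where(n_i > 0, n_i, 1)
    denom = np.sqrt(np.maximum(sxx, 0.0) * np.maximum(syy, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0.0, sxy / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.where(n_i >= MIN_COMPLETE_PAIRS, np.clip(r, -1.0, 1.0), 0.0)
    return float(r.mean())


def cluster_similarity(a, b) -> float:
    """Average-linkage similarity: mean pairwise correlation over cross pairs."""
    va = _as_profile_array(a)
    vb = _as_profile_array(b)
    if va.shape[0] == 0 or vb.shape[0] == 0:
        raise ValueError("cluster_similarity requires non-empty clusters")
    total = 0.0
    for i in range(va.shape[0]):
        for j in range(vb.shape[0]):
            total += pairwise_correlation(va[i], vb[j])
    return total / (va.shape[0] * vb.shape[0])


def module_meta_profiles(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-module mean over non-missing member entries (modules x samples).

    An entry where every member is missing stays NaN: no data, no value.
    """
    n_modules = int(labels.max()) + 1 if labels.size else 0
    meta = np.full((n_modules, values.shape[1]), np.nan)
    for k in range(n_modules):
        block = values[labels == k]
        counts = (~np.isnan(block)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            meta[k] = np.where(counts > 0, np.nansum(block, axis=0) / counts, np.nan)
    return meta


class CoherenceClustering(TransformerMixin, BaseEstimator):
    """Randomized agglomerative feature clustering with a coherence floor.

    Analogous to :class:`sklearn.cluster.FeatureAgglomeration`: ``fit``
    clusters the *columns* (probes) of a samples x probes matrix and
    ``transform`` pools each module into its meta-probe (mean beta over the
    module's non-missing members).

    Parameters
    ----------
    coherence_threshold : float in (0, 1], default 0.7
        Quality floor: every returned module's average member-to-mean
        correlation is at least this value.
    random_state : int or None
        Seed for the single random generator driving the pick order.

    Attributes
    ----------
    labels_ : ndarray of int, shape (n_probes,)
        Module index per probe, contiguous from 0, numbered by the input
        position of each module's first member.
    coherences_ : ndarray, per-module coherence (singletons are 1).
    n_modules_ : int
    probe_ids_ : list
    """

    def __init__(self, coherence_threshold: float = 0.7, random_state: int | None = None):
        self.coherence_threshold = coherence_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        thr = self.coherence_threshold
        if not np.isfinite(thr) or not 0.0 < thr <= 1.0:
            raise ValueError("coherence_threshold must be a finite value in (0, 1]")
        if isinstance(X, pd.DataFrame):
            probe_ids = list(X.columns)
            values = X.to_numpy(dtype=float).T  # probes x samples
        else:
            values = np.asarray(X, dtype=float).T
            probe_ids = list(range(values.shape[0]))
        n = values.shape[0]
        if n < 1:
            raise ValueError("need at least one probe")
        rng = np.random.default_rng(self.random_state)

        S = correlation_matrix(values)
        cluster_counts: list[int] = []
        members: list[list[int] | None] = [[i] for i in range(n)]
        coherences = [1.0] * n
        sizes = np.ones(n)
        csum = S.copy()
        np.fill_diagonal(csum, 0.0)
        active = np.ones(n, dtype=bool)

        while True:
            available = np.flatnonzero(active).tolist()
            available_set = set(available)
            n_merges = 0
            while available:
                pick = available[int(rng.integers(len(available)))]
                act_idx = np.flatnonzero(active)
                others = act_idx[act_idx != pick]
                if others.size == 0:
                    available.remove(pick)
                    available_set.discard(pick)
                    continue
                sims = csum[pick, others] / (sizes[pick] * sizes[others])
                best = sims.max()
                # nearest neighbour; ties favour available clusters so that
                # fully tied landscapes still halve per iteration, then
                # lowest index for determinism
                tied = others[sims == best]
                tied_avail = [t for t in tied if t in available_set]
                nn = int(tied_avail[0] if tied_avail else tied[0])
                if nn not in available_set:
                    available.remove(pick)
                    available_set.discard(pick)
                    continue
                union = members[pick] + members[nn]
                coh = cluster_coherence(values[union])
                if coh >= thr:
                    keep, drop = (pick, nn) if pick < nn else (nn, pick)
                    members[keep] = union
                    members[drop] = None
                    coherences[keep] = coh
                    sizes[keep] += sizes[drop]
                    csum[keep, :] += csum[drop, :]
                    csum[:, keep] = csum[keep, :]
                    csum[keep, keep] = 0.0
                    active[drop] = False
                    available.remove(pick)
                    available.remove(nn)
                    available_set.discard(pick)
                    available_set.discard(nn)
                    n_merges += 1
                else:
                    available.remove(pick)
                    available_set.discard(pick)
            cluster_counts.append(int(active.sum()))
            if n_merges == 0:
                break

        slots = np.flatnonzero(active)
        # number modules by the input position of their first member
        slots = slots[np.argsort([min(members[s]) for s in slots])]
        labels = np.empty(n, dtype=int)
        final_coh = np.empty(len(slots))
        for k, s in enumerate(slots):
            labels[members[s]] = k
            final_coh[k] = coherences[s]

        self.probe_ids_ = probe_ids
        self.labels_ = labels
        self.coherences_ = final_coh
        self.n_modules_ = len(slots)
        #: cluster count at the end of each iteration (last entry is the
        #: final count, from the iteration that committed no merge)
        self.n_clusters_per_iteration_ = cluster_counts
        self._fit_values = values
        return self

    def transform(self, X):
        """Pool probes into module meta-profiles (samples x modules)."""
        check_is_fitted(self, "labels_")
        if isinstance(X, pd.DataFrame):
            values = X.loc[:, self.probe_ids_].to_numpy(dtype=float).T
            index = X.index
        else:
            values = np.asarray(X, dtype=float).T
            index = pd.RangeIndex(values.shape[1])
        meta = module_meta_profiles(values, self.labels_)
        return pd.DataFrame(
            meta.T, index=index, columns=pd.RangeIndex(self.n_modules_)
        )


def agglomerate(
    m: BetaMatrix, coherence_threshold: float = 0.7, seed: int | None = None
) -> ModuleSet:
    """Cluster a BetaMatrix's probes into coherent modules.

    Thin wrapper over :class:`CoherenceClustering`; returns a
    :class:`ModuleSet` with meta-profiles (modules x samples), per-module
    coherences, and the seed used.
    """
    est = CoherenceClustering(
        coherence_threshold=coherence_threshold, random_state=seed
    ).fit(m.data.T)
    meta = module_meta_profiles(est._fit_values, est.labels_)
    return ModuleSet(
        module_assignments=pd.Series(est.labels_, index=m.probe_ids),
        meta_profiles=pd.DataFrame(meta, columns=m.sample_ids),
        coherences=est.coherences_,
        threshold_used=coherence_threshold,
        seed_used=seed,
    )


def module_set_from_assignments(m: BetaMatrix, assignments: pd.Series) -> ModuleSet:
    """Build a ModuleSet from a given probe -> module-index mapping.

    Useful for scoring against externally defined (e.g. ground-truth)
    modules.  Coherences are computed from the members; no threshold is
    enforced (``threshold_used`` is 0).
    """
    assignments = assignments.loc[m.probe_ids]
    labels = assignments.to_numpy(dtype=int)
    if labels.min() != 0 or len(np.unique(labels)) != labels.max() + 1:
        raise ValueError("module indices must be contiguous from 0")
    values = m.data.to_numpy(dtype=float)
    meta = module_meta_profiles(values, labels)
    coh = np.array(
        [cluster_coherence(values[labels == k]) for k in range(int(labels.max()) + 1)]
    )
    return ModuleSet(
        module_assignments=assignments,
        meta_profiles=pd.DataFrame(meta, columns=m.sample_ids),
        coherences=coh,
        threshold_used=0.0,
        seed_used=None,
    )
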