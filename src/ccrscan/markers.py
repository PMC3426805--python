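"""Marker-panel selection and sample-level hierarchical clustering.

The headline use of the CCR score table: keep the top-ranked marker probes
(default 200), hierarchically cluster the samples on that panel
(dissimilarity 1 - Pearson, average linkage), and export the reordered
matrix plus an aligned sample-label track for heatmap display or external
survival analysis of the resulting groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .containers import BetaMatrix, ClusteringResult, MarkerPanel
from .correlation import correlation_matrix

__all__ = [
    "select_top_markers",
    "cluster_samples",
    "export_ordered_matrix",
    "SampleSubtypeClustering",
]


def select_top_markers(scores: pd.DataFrame, n: int = 200) -> MarkerPanel:
    """The n highest-scoring valid candidates, score-descending.

    Ties are broken by probe ID, so ``select_top_markers(scores, n)`` is
    always a prefix of ``select_top_markers(scores, n + 1)``.  Requesting
    more markers than there are valid candidates returns all of them with
    a truncation warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = scores[scores["valid"]]
    if valid.empty:
        raise ValueError("no valid scored candidates to select markers from")
    ordered = valid.sort_values(
        ["score_s", "candidate_probe"], ascending=[False, True], kind="stable"
    )["candidate_probe"].tolist()
    truncated = n > len(ordered)
    if truncated:
        warnings.warn(
            f"requested {n} markers but only {len(ordered)} valid candidates",
            stacklevel=2,
        )
    return MarkerPanel(
        probe_ids=ordered[:n],
        source_score_table=scores,
        n_requested=n,
        truncated=truncated,
    )


class SampleSubtypeClustering(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of samples on a marker panel.

    Dissimilarity between samples is 1 - Pearson correlation of their beta
    profiles across the panel probes (pairwise-complete; degenerate pairs
    count as correlation 0), with average linkage.  Deterministic: scipy's
    agglomeration breaks ties by index.

    Parameters
    ----------
    n_clusters : int or None
        When set, ``labels_`` holds the flat cut into this many groups
        (e.g. 2 for a two-subtype split).

    Attributes
    ----------
    linkage_ : ndarray, scipy linkage record (merge children and heights).
    sample_order_ : list, dendrogram leaf order.
    labels_ : ndarray or None, flat-cut group labels (0-based).
    """

    def __init__(self, n_clusters: int | None = None):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            sample_ids = list(X.index)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            sample_ids = list(range(values.shape[0]))
        n = values.shape[0]
        if n < 2:
            raise ValueError("need at least 2 samples to cluster")
        corr = correlation_matrix(values)  # samples as rows/variables
        diss = 1.0 - corr
        np.fill_diagonal(diss, 0.0)
        diss = np.maximum(diss, 0.0)
        condensed = diss[np.triu_indices(n, k=1)]
        self.linkage_ = linkage(condensed, method="average")
        leaves = dendrogram(self.linkage_, no_plot=True)["leaves"]
        self.sample_ids_ = sample_ids
        self.sample_order_ = [sample_ids[i] for i in leaves]
        if self.n_clusters is not None:
            self.labels_ = (
                fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust") - 1
            )
        else:
            self.labels_ = None
        return self


def cluster_samples(
    m: BetaMatrix, panel: MarkerPanel, k: int | None = None
) -> ClusteringResult:
    """Hierarchically cluster samples on the panel submatrix.

    Thin wrapper over :class:`SampleSubtypeClustering` (1 - Pearson,
    average linkage).  The probe order of the result is the probe
    dendrogram leaf order (same metric/linkage over probes).
    """
    missing = [p for p in panel.probe_ids if p not in m.data.index]
    if missing:
        raise KeyError(f"panel probes absent from matrix: {missing}")
    sub = m.data.loc[panel.probe_ids]  # probes x samples
    est = SampleSubtypeClustering(n_clusters=k).fit(sub.T)

    if len(panel.probe_ids) >= 2:
        pcorr = correlation_matrix(sub.to_numpy(dtype=float))
        pdiss = np.maximum(1.0 - pcorr, 0.0)
        np.fill_diagonal(pdiss, 0.0)
        plink = linkage(pdiss[np.triu_indices(len(panel.probe_ids), k=1)], "average")
        pleaves = dendrogram(plink, no_plot=True)["leaves"]
        probe_order = [panel.probe_ids[i] for i in pleaves]
    else:
        probe_order = list(panel.probe_ids)

    labels = None
    if est.labels_ is not None:
        labels = pd.Series(est.labels_, index=m.sample_ids)
    return ClusteringResult(
        sample_order=est.sample_order_,
        probe_order=probe_order,
        linkage_record=est.linkage_,
        sample_group_labels=labels,
    )


def export_ordered_matrix(
    m: BetaMatrix,
    result: ClusteringResult,
    metadata: pd.DataFrame | None = None,
    matrix_path=None,
    labels_path=None,
    annotation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reorder the matrix per the clustering and build an aligned label track.

    Probe rows follow genomic coordinate when an annotation is supplied
    (chromosome, then position), else the probe dendrogram order; sample
    columns follow the sample dendrogram order.  The label track has one
    row per sample, in display order, carrying any supplied metadata
    columns plus the flat-cut group label when present.  When paths are
    given the two tables are also written as TSV.
    """
    probe_order = [p for p in result.probe_order if p in m.data.index]
    if annotation is not None:
        ann = annotation.loc[probe_order]
        ann = ann.sort_values(["chromosome", "position"], kind="stable")
        probe_order = list(ann.index)
    ordered = m.data.loc[probe_order, result.sample_order]

    track = pd.DataFrame(index=pd.Index(result.sample_order, name="sample_id"))
    if result.sample_group_labels is not None:
        track["group"] = result.sample_group_labels.loc[result.sample_order].to_numpy()
    if metadata is not None:
        track = track.join(metadata, how="left")

    if matrix_path is not None:
        ordered.to_csv(matrix_path, sep="\t", index_label="probe_id", na_rep="NA")
    if labels_path is not None:
        track.to_csv(labels_path, sep="\t", na_rep="NA")
    return ordered, track
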