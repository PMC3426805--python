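"""Probe filtering: null-fraction, sex-chromosome, SD and top-k-variance rules.

Probes with many missing entries (more than ``max_null_fraction`` of the
sample size, default 1%) or low variability (sample SD below ``min_sd``,
default 0.1) carry little correlation signal and are removed before any CCR
analysis, as are X/Y probes whose methylation mostly reflects sex rather
than disease or tissue.  An optional top-k-variance truncation keeps only
the k most variable survivors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import BetaMatrix, FilterReport, ValidationError

__all__ = ["ProbeFilter", "filter_probes"]

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


class ProbeFilter(TransformerMixin, BaseEstimator):
    """Feature (probe) filter over a samples x probes beta matrix.

    Parameters
    ----------
    annotation : pandas.DataFrame or None
        Probe annotation indexed by probe_id with a ``chromosome`` column.
        Required when ``drop_sex_chromosomes`` is True.
    max_null_fraction : float, default 0.01
        A probe is dropped when its missing count exceeds
        ``max_null_fraction * n_samples``.
    min_sd : float, default 0.1
        Minimum sample standard deviation (ddof=1, over non-missing
        entries).  Probes with fewer than 2 non-missing values have
        undefined SD and are treated as SD 0.
    drop_sex_chromosomes : bool, default True
    top_k_variance : int or None, default None
        When set, keep only the k highest-SD probes among the survivors.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_probes,)
        Mask of kept probes, in input order.
    kept_probe_ids_ : list
    report_ : FilterReport
        Removal counts with each probe attributed to exactly one reason, in
        the precedence null-fraction, sex-chromosome, SD, top-k.  The kept
        set is independent of this precedence; the attributed counts are
        not.
    """

    def __init__(
        self,
        annotation: pd.DataFrame | None = None,
        max_null_fraction: float = 0.01,
        min_sd: float = 0.1,
        drop_sex_chromosomes: bool = True,
        top_k_variance: int | None = None,
    ):
        self.annotation = annotation
        self.max_null_fraction = max_null_fraction
        self.min_sd = min_sd
        self.drop_sex_chromosomes = drop_sex_chromosomes
        self.top_k_variance = top_k_variance

    def _probe_ids(self, X) -> list:
        if isinstance(X, pd.DataFrame):
            return list(X.columns)
        return list(range(np.asarray(X).shape[1]))

    def fit(self, X, y=None):
        if not 0.0 <= self.max_null_fraction <= 1.0:
            raise ValueError("max_null_fraction must be in [0, 1]")
        if self.min_sd < 0:
            raise ValueError("min_sd must be >= 0")
        probe_ids = self._probe_ids(X)
        values = np.asarray(
            X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float
        )
        if values.ndim != 2:
            raise ValueError("expected a 2-d samples x probes matrix")
        n_samples, n_probes = values.shape

        null_counts = np.isnan(values).sum(axis=0)
        n_obs = n_samples - null_counts
        with np.errstate(invalid="ignore"):
            sds = np.nanstd(values, axis=0, ddof=1)
        sds = np.where(n_obs >= 2, sds, 0.0)  # undefined SD -> treated as 0

        fail_null = null_counts > self.max_null_fraction * n_samples
        if self.drop_sex_chromosomes:
            if self.annotation is None:
                raise ValidationError(
                    "drop_sex_chromosomes=True requires an annotation table"
                )
            chrom = self.annotation["chromosome"]
            unannotated = [p for p in probe_ids if p not in chrom.index]
            if unannotated:
                raise ValidationError(
                    f"probes missing from annotation: {unannotated}"
                )
            fail_sex = np.asarray(
                [str(chrom.loc[p]) in SEX_CHROMOSOMES for p in probe_ids]
            )
        else:
            fail_sex = np.zeros(n_probes, dtype=bool)
        fail_sd = sds < self.min_sd

        keep = ~(fail_null | fail_sex | fail_sd)
        n_removed_topk = 0
        if self.top_k_variance is not None and keep.sum() > self.top_k_variance:
            survivors = np.flatnonzero(keep)
            order = survivors[np.argsort(-sds[survivors], kind="stable")]
            dropped = order[self.top_k_variance :]
            keep[dropped] = False
            n_removed_topk = len(dropped)
        if not keep.any():
            raise ValidationError("all probes removed by filtering")

        # attribute each removal to exactly one reason, in precedence order
        reason_null = fail_null
        reason_sex = fail_sex & ~reason_null
        reason_sd = fail_sd & ~reason_null & ~reason_sex

        self.support_ = keep
        self.kept_probe_ids_ = [p for p, k in zip(probe_ids, keep) if k]
        self.sds_ = sds
        self.null_counts_ = null_counts
        self.report_ = FilterReport(
            n_input=n_probes,
            n_removed_null=int(reason_null.sum()),
            n_removed_sex=int(reason_sex.sum()),
            n_removed_sd=int(reason_sd.sum()),
            n_removed_topk=n_removed_topk,
            n_kept=int(keep.sum()),
            kept_probe_ids=list(self.kept_probe_ids_),
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_


def filter_probes(
    m: BetaMatrix,
    ann: pd.DataFrame | None = None,
    max_null_fraction: float = 0.01,
    min_sd: float = 0.1,
    drop_sex_chromosomes: bool = True,
    top_k_variance: int | None = None,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the standard probe filters to a probes x samples BetaMatrix.

    Thin wrapper over :class:`ProbeFilter` (which follows the sklearn
    samples x features orientation).  Survivor row order preserves the
    input order.
    """
    est = ProbeFilter(
        annotation=ann,
        max_null_fraction=max_null_fraction,
        min_sd=min_sd,
        drop_sex_chromosomes=drop_sex_chromosomes,
        top_k_variance=top_k_variance,
    ).fit(m.data.T)
    return m.subset_probes(est.kept_probe_ids_), est.report_
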