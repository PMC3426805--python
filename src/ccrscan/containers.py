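"""Core in-memory containers for the CCR-scanning pipeline.

The universal input is a probes x samples matrix of methylation beta values
(the level-3 ratio M/(U+M), in [0, 1]) with explicit missing entries encoded
as NaN.  Everything downstream — probe filtering, module clustering, marker
scoring — consumes a :class:`BetaMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "FilterReport",
    "ModuleSet",
    "DichotomySplit",
    "MarkerPanel",
    "ClusteringResult",
    "DistanceBinSummary",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


ANNOTATION_COLUMNS = ("probe_id", "chromosome", "position", "gene_symbol")


class BetaMatrix:
    """Probes x samples matrix of methylation beta ratios.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are probes, columns are samples.  Missing entries are NaN.
        Every non-missing value must lie in [0, 1]; out-of-range values are
        rejected, never clamped, because a beta is a ratio of intensities and
        anything outside [0, 1] signals corrupt input.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("BetaMatrix expects a pandas DataFrame")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe IDs: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        values = data.to_numpy(dtype=float, copy=False)
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {values[r, c]!r} out of [0, 1] at probe "
                f"{data.index[r]!r}, sample {data.columns[c]!r}"
            )
        self._data = data.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying probes x samples DataFrame (NaN = missing)."""
        return self._data

    @property
    def probe_ids(self) -> list:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def n_probes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def probe(self, probe_id) -> pd.Series:
        if probe_id not in self._data.index:
            raise KeyError(f"unknown probe {probe_id!r}")
        return self._data.loc[probe_id]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self._data.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self._data[list(sample_ids)])

    def equals(self, other: "BetaMatrix") -> bool:
        """Exact equality of ids, values and the missing mask."""
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples)"


@dataclass
class FilterReport:
    """Bookkeeping for :func:`ccrscan.filtering.filter_probes`.

    Each removed probe is attributed to exactly one reason, applied in the
    documented precedence: null fraction, sex chromosome, low SD, then
    top-k variance truncation.
    """

    n_input: int
    n_removed_null: int
    n_removed_sex: int
    n_removed_sd: int
    n_removed_topk: int
    n_kept: int
    kept_probe_ids: list = field(default_factory=list)

    def __post_init__(self):
        removed = (
            self.n_removed_null
            + self.n_removed_sex
            + self.n_removed_sd
            + self.n_removed_topk
        )
        if self.n_kept != self.n_input - removed:
            raise ValidationError("FilterReport counts do not partition the input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_null": self.n_removed_null,
            "n_removed_sex": self.n_removed_sex,
            "n_removed_sd": self.n_removed_sd,
            "n_removed_topk": self.n_removed_topk,
            "n_kept": self.n_kept,
            "kept_probe_ids": list(self.kept_probe_ids),
        }


@dataclass
class ModuleSet:
    """Partition of probes into coherent modules plus meta-probe profiles.

    Attributes
    ----------
    module_assignments : pandas.Series
        probe_id -> module index (contiguous ints from 0).
    meta_profiles : pandas.DataFrame
        modules x samples mean beta per module (NaN where every member is
        missing).  The meta-probe is the correlation surrogate for its
        members.
    coherences : numpy.ndarray
        Per-module average member-to-mean Pearson correlation (singletons
        are 1 by convention).
    threshold_used : float
    seed_used : int or None
    """

    module_assignments: pd.Series
    meta_profiles: pd.DataFrame
    coherences: np.ndarray
    threshold_used: float
    seed_used: int | None = None

    @property
    def n_modules(self) -> int:
        return self.meta_profiles.shape[0]

    def members(self, module_index: int) -> list:
        return list(
            self.module_assignments.index[self.module_assignments == module_index]
        )


@dataclass
class DichotomySplit:
    """Binary sample grouping induced by thresholding one candidate probe."""

    candidate_probe: object
    threshold: float
    methylated_samples: list
    unmethylated_samples: list
    excluded_samples: list
    minority_fraction: float
    valid: bool

    @property
    def n_methylated(self) -> int:
        return len(self.methylated_samples)

    @property
    def n_unmethylated(self) -> int:
        return len(self.unmethylated_samples)


@dataclass
class MarkerPanel:
    """Top-ranked CCR-associated probes, score-descending."""

    probe_ids: list
    source_score_table: pd.DataFrame
    n_requested: int
    truncated: bool = False  # True when fewer valid candidates than requested


@dataclass
class ClusteringResult:
    """Hierarchical clustering of samples on a marker panel."""

    sample_order: list
    probe_order: list
    linkage_record: np.ndarray
    sample_group_labels: pd.Series | None = None


@dataclass
class DistanceBinSummary:
    """Per-distance-bin summary of pairwise probe correlations.

    ``table`` has one row per bin (plus an overflow row for distances beyond
    the last edge) with columns bin_lower, bin_upper, n_pairs, q1, median,
    q3, whisker_low, whisker_high.
    """

    bin_edges: np.ndarray
    table: pd.DataFrame
    n_overflow: int

    @property
    def total_pairs(self) -> int:
        return int(self.table["n_pairs"].sum())
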