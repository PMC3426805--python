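"""Reading and writing beta matrices and probe annotations.

The on-disk format mirrors TCGA HumanMethylation27 level-3 exports:
tab-separated text, first row = sample IDs, first column = probe IDs, each
cell a decimal beta in [0, 1] or a missing token.  Accepted missing tokens
(case-insensitive): empty string, ``NA``, ``null``, ``NaN`` — TCGA export
dialects vary.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ANNOTATION_COLUMNS, BetaMatrix, ValidationError

__all__ = [
    "load_beta_matrix",
    "write_beta_matrix",
    "load_probe_annotation",
    "write_probe_annotation",
    "MISSING_TOKENS",
]

MISSING_TOKENS = frozenset({"", "na", "null", "nan"})


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_cell(token: str, line_no: int, probe_id, sample_id) -> float:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric value {token!r} "
            f"(probe {probe_id!r}, sample {sample_id!r})"
        ) from None
    if not 0.0 <= value <= 1.0:
        raise ValidationError(
            f"beta value {value} out of [0, 1] at probe {probe_id!r}, "
            f"sample {sample_id!r} (line {line_no})"
        )
    return value


def load_beta_matrix(path) -> BetaMatrix:
    """Load a probes x samples beta matrix from a TSV file.

    Raises
    ------
    ParseError
        Malformed header or row (message names the line number).
    ValidationError
        Value outside [0, 1] or duplicate probe ID.
    """
    path = Path(path)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("line 1: empty file, expected a header row") from None
        if len(header) < 2:
            raise ParseError(
                "line 1: malformed header, expected a probe-ID column followed "
                "by at least one sample ID"
            )
        sample_ids = [s.strip() for s in header[1:]]
        n_samples = len(sample_ids)
        for line_no, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != n_samples + 1:
                raise ParseError(
                    f"line {line_no}: expected {n_samples + 1} fields, "
                    f"got {len(record)}"
                )
            probe_id = record[0].strip()
            probe_ids.append(probe_id)
            rows.append(
                [
                    _parse_cell(tok, line_no, probe_id, sample_ids[j])
                    for j, tok in enumerate(record[1:])
                ]
            )
    frame = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(probe_ids), n_samples),
        index=probe_ids,
        columns=sample_ids,
    )
    return BetaMatrix(frame)


def write_beta_matrix(m: BetaMatrix, path) -> None:
    """Write a beta matrix as TSV with ``NA`` for missing entries.

    Values are written with ``repr`` (shortest round-trip) precision, so a
    write/load round trip is bit-exact.
    """
    frame = m.data
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", *map(str, frame.columns)])
        values = frame.to_numpy()
        for i, probe_id in enumerate(frame.index):
            writer.writerow(
                [str(probe_id)]
                + ["NA" if np.isnan(v) else repr(float(v)) for v in values[i]]
            )


def load_probe_annotation(path) -> pd.DataFrame:
    """Load a probe annotation table (probe_id, chromosome, position, gene_symbol).

    Positions are 1-based base-pair coordinates; chromosome labels are
    strings ('1'..'22', 'X', 'Y').  ``gene_symbol`` may be empty.
    """
    ann = pd.read_csv(
        Path(path),
        sep="\t",
        dtype={"probe_id": str, "chromosome": str, "gene_symbol": str},
        keep_default_na=False,
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"annotation file missing columns: {missing}")
    ann["position"] = ann["position"].astype(int)
    if (ann["position"] < 1).any():
        bad = ann.loc[ann["position"] < 1, "probe_id"].tolist()
        raise ValidationError(f"positions must be >= 1; offending probes: {bad}")
    if ann["probe_id"].duplicated().any():
        dups = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"duplicate probe IDs in annotation: {dups}")
    return ann.set_index("probe_id", drop=False)


def write_probe_annotation(ann: pd.DataFrame, path) -> None:
    ann.loc[:, list(ANNOTATION_COLUMNS)].to_csv(Path(path), sep="\t", index=False)
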