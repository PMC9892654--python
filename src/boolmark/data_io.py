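"""Expression-matrix and response-label I/O.

The package operates on a quantified protein (or gene) abundance table —
features in rows, samples in columns — together with per-sample drug-response
classes.  Response classes may be given directly or derived from the log2 fold
change of the proliferation marker Ki67 after treatment: a sample with at
least a two-fold *decrease* in Ki67 positivity is a responder (RD), at least a
two-fold *increase* a poor responder (PR), and anything in between a
non-responder (NR).

Missing (undetectable) abundances are carried in an explicit boolean mask and
filled by :func:`impute_missing` with independent uniform draws, by default on
(0, 1) — one unit being the minimal machine-detectable protein amount on the
abundance scale the table uses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The three drug-response classes: responder, non-responder, poor responder.
CLASSES = ("RD", "NR", "PR")

#: Cell contents treated as missing values (compared case-insensitively).
MISSING_TOKENS = frozenset({"", "na", "nan"})


@dataclass
class ExpressionMatrix:
    """A features x samples abundance table with a missing-value mask.

    Parameters
    ----------
    feature_ids
        Unique row labels (protein or gene identifiers).
    sample_ids
        Unique column labels.
    values
        Float array of shape ``(len(feature_ids), len(sample_ids))``.  Cells
        flagged in ``missing_mask`` hold NaN until imputed; all other cells
        are finite.
    missing_mask
        Boolean array of the same shape; True marks a missing abundance.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_f, n_s = len(self.feature_ids), len(self.sample_ids)
        if self.values.shape != (n_f, n_s):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n_f} features x {n_s} samples"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        present = self.values[~self.missing_mask]
        if present.size and not np.all(np.isfinite(present)):
            raise ValueError("non-missing values must be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature ID: {feature_id!r}") from None

    def subset(self, features: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset the matrix to ``features``, preserving their order."""
        idx = [self.feature_index(f) for f in features]
        return ExpressionMatrix(
            feature_ids=list(features),
            sample_ids=list(self.sample_ids),
            values=self.values[idx].copy(),
            missing_mask=self.missing_mask[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        values = frame.to_numpy(dtype=float)
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=values,
            missing_mask=np.isnan(values),
        )


@dataclass
class ResponseLabels:
    """Per-sample drug-response classes, optionally with Ki67 fold changes."""

    sample_ids: list[str]
    classes: list[str]
    log2_ki67_fc: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        if len(self.classes) != len(self.sample_ids):
            raise ValueError("classes and sample_ids differ in length")
        bad = sorted({c for c in self.classes if c not in CLASSES})
        if bad:
            raise ValueError(f"invalid response class(es): {bad}; expected {CLASSES}")
        if self.log2_ki67_fc is not None:
            self.log2_ki67_fc = np.asarray(self.log2_ki67_fc, dtype=float)
            if self.log2_ki67_fc.shape != (len(self.sample_ids),):
                raise ValueError("log2_ki67_fc length does not match sample_ids")

    def class_array(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)

    def group_indices(self) -> dict[str, np.ndarray]:
        """Column indices of each response class, in (RD, NR, PR) order."""
        arr = self.class_array()
        return {c: np.flatnonzero(arr == c) for c in CLASSES}

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.class_array() == c)) for c in CLASSES}

    def aligned_to(self, sample_ids: Sequence[str]) -> "ResponseLabels":
        """Reorder to match ``sample_ids`` (must be the same sample set)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing or len(sample_ids) != len(self.sample_ids):
            raise ValueError(f"label/sample mismatch; unmatched: {missing[:5]}")
        order = [pos[s] for s in sample_ids]
        fc = None if self.log2_ki67_fc is None else self.log2_ki67_fc[order]
        return ResponseLabels(
            sample_ids=list(sample_ids),
            classes=[self.classes[i] for i in order],
            log2_ki67_fc=fc,
        )


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


def _dialect_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).lower().endswith((".tsv", ".txt")) else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_expression(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read an abundance table (first row sample IDs, first column feature IDs).

    Empty cells, ``NA`` and ``NaN`` (case-insensitive) denote missing values.
    The header row may or may not carry a leading label for the feature-ID
    column.  Raises ``ValueError`` on duplicate IDs (naming the duplicate),
    ragged rows (naming the line number) and non-numeric cells (naming the
    feature/sample coordinates).
    """
    sep = _dialect_sep(path, dialect)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r]  # drop fully blank lines
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header row and at least one feature row")
    header = rows[0]
    body_width = len(rows[1])
    if len(header) == body_width:
        sample_ids = header[1:]  # header includes a corner label
    elif len(header) == body_width - 1:
        sample_ids = header[:]
    else:
        raise ValueError(
            f"{path}: header width {len(header)} inconsistent with row width "
            f"{body_width} at line 2"
        )
    feature_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    mask = np.zeros_like(values, dtype=bool)
    for r, row in enumerate(rows[1:]):
        if len(row) != body_width:
            raise ValueError(
                f"{path}: ragged row at line {r + 2} "
                f"({len(row)} fields, expected {body_width})"
            )
        feature_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            if cell.strip().lower() in MISSING_TOKENS:
                values[r, c] = np.nan
                mask[r, c] = True
            else:
                try:
                    values[r, c] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at feature "
                        f"{row[0]!r}, sample {sample_ids[c]!r}"
                    ) from None
    return ExpressionMatrix(feature_ids, list(sample_ids), values, mask)


def write_expression(m: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    """Write a matrix; missing cells become ``NA``.

    Values are written with Python's shortest round-trip ``repr`` so that
    ``read_expression(write_expression(m))`` reproduces them bit-for-bit.
    """
    sep = _dialect_sep(path, dialect)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["feature_id", *m.sample_ids])
        for r, fid in enumerate(m.feature_ids):
            cells = [
                "NA" if m.missing_mask[r, c] else repr(float(m.values[r, c]))
                for c in range(m.n_samples)
            ]
            w.writerow([fid, *cells])


def impute_missing(
    m: ExpressionMatrix, low: float = 0.0, high: float = 1.0, seed: int = 0
) -> ExpressionMatrix:
    """Fill missing cells with independent Uniform(low, high) draws.

    Non-missing cells are unchanged; a matrix with no missing cells is
    returned as an identical copy.  Reproducible given ``seed``.
    """
    if not low < high:
        raise ValueError(f"require low < high, got low={low}, high={high}")
    values = m.values.copy()
    n_missing = int(m.missing_mask.sum())
    if n_missing:
        rng = np.random.default_rng(seed)
        values[m.missing_mask] = rng.uniform(low, high, size=n_missing)
    return ExpressionMatrix(
        feature_ids=list(m.feature_ids),
        sample_ids=list(m.sample_ids),
        values=values,
        missing_mask=np.zeros_like(m.missing_mask),
    )


def label_from_ki67(
    fc: Sequence[float] | np.ndarray, sample_ids: Sequence[str] | None = None
) -> ResponseLabels:
    """Derive RD/NR/PR classes from log2 Ki67 fold changes (treated/vehicle).

    RD iff log2 fc <= -1 (at least a two-fold decrease in Ki67 positivity),
    PR iff log2 fc >= +1, NR otherwise.  Thresholds are closed: a fold change
    of exactly two maps to the extreme class.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 1:
        raise ValueError("fold changes must be one-dimensional")
    if not np.all(np.isfinite(fc)):
        bad = np.flatnonzero(~np.isfinite(fc))
        raise ValueError(f"non-finite log2 fold change at position(s) {bad.tolist()}")
    classes = np.where(fc <= -1.0, "RD", np.where(fc >= 1.0, "PR", "NR"))
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(fc.size)]
    return ResponseLabels(
        sample_ids=list(sample_ids), classes=classes.tolist(), log2_ki67_fc=fc
    )


def read_labels(path: str | Path) -> ResponseLabels:
    """Read a two-column CSV: (sample_id, class) or (sample_id, log2_ki67_fc).

    The second column is treated as log2 Ki67 fold changes, and classes
    derived via :func:`label_from_ki67`, unless its values are class names.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, class|log2_ki67_fc)")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    second = df.iloc[:, 1].astype(str).str.strip()
    if second.str.upper().isin(CLASSES).all():
        return ResponseLabels(sample_ids=sample_ids, classes=second.str.upper().tolist())
    fc = pd.to_numeric(second, errors="raise").to_numpy(dtype=float)
    return label_from_ki67(fc, sample_ids=sample_ids)


def write_labels(labels: ResponseLabels, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": labels.sample_ids, "class": labels.classes})
    if labels.log2_ki67_fc is not None:
        df["log2_ki67_fc"] = labels.log2_ki67_fc
    df.to_csv(path, index=False)
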