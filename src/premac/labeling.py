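"""Windowed imminent-precursor labels and class rebalancing.

A feature row gets label 1 when it falls inside the pre-event window of
any precursor: 0 <= t(precursor) - t(row) <= W seconds, inclusive at
both ends (default W = 90 s).  Rows after the last precursor, and all
rows of sessions without precursors, are label 0.  Rows are labeled by
the time rule alone, regardless of the therapeutic condition they fall
in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .streams_io import EventLog


class LabelingError(ValueError):
    pass


@dataclass
class LabeledDataset:
    """Feature matrix plus binary imminent-precursor labels."""

    features: FeatureMatrix
    labels: np.ndarray
    window_s: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.features.n_rows:
            raise LabelingError("label count does not match feature rows")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.labels)) if self.n else 0.0

    @property
    def X(self) -> np.ndarray:
        return self.features.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def to_tsv(self, path) -> None:
        df = self.features.values.copy()
        df.insert(0, "timestamp_ms", self.features.timestamps)
        df["label"] = self.labels
        from pathlib import Path

        from .streams_io import _atomic_write
        _atomic_write(Path(path), df.to_csv(sep="\t", index=False))

    @classmethod
    def from_tsv(cls, path, window_s: float = 90.0,
                 subject_id: str = "") -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t")
        y = df.pop("label").to_numpy(dtype=int)
        ts = df.pop("timestamp_ms").to_numpy(dtype=np.int64)
        return cls(FeatureMatrix(ts, df), y, window_s, subject_id)


def assign_labels(
    fm: FeatureMatrix,
    log: EventLog,
    window_s: float = 90.0,
    subject_id: str = "",
) -> LabeledDataset:
    """Label rows collected within ``window_s`` seconds before a precursor.

    The boundary is inclusive at both ends; with several precursors a
    row is positive if any event's window covers it.
    """
    if window_s <= 0:
        raise LabelingError(f"window must be > 0 s, got {window_s}")
    prec = np.sort(log.precursor_times)
    if prec.size == 0:
        warnings.warn(
            f"event log '{log.session_id}' has no precursor events; "
            "all labels are 0", stacklevel=2)
        return LabeledDataset(fm, np.zeros(fm.n_rows, dtype=int), window_s,
                              subject_id)
    t = fm.timestamps
    # next precursor at or after each row; in-window iff within W seconds
    j = np.searchsorted(prec, t, side="left")
    has_next = j < prec.size
    delta = np.where(has_next, prec[np.minimum(j, prec.size - 1)] - t, np.inf)
    labels = (delta <= window_s * 1000.0).astype(int)
    return LabeledDataset(fm, labels, window_s, subject_id)


def concat_labeled(parts: list[LabeledDataset],
                   subject_id: str = "") -> LabeledDataset:
    """Concatenate per-session labeled data (e.g. the five visit sessions)."""
    if not parts:
        raise LabelingError("nothing to concatenate")
    cols = parts[0].features.columns
    for p in parts[1:]:
        if p.features.columns != cols:
            raise LabelingError("feature columns differ between parts")
    ts = np.concatenate([p.features.timestamps for p in parts])
    vals = pd.concat([p.features.values for p in parts], ignore_index=True)
    labels = np.concatenate([p.labels for p in parts])
    # session-local timestamps may repeat across sessions; labels were
    # already assigned per session so that is harmless downstream
    fm = FeatureMatrix(ts, vals)
    return LabeledDataset(fm, labels, parts[0].window_s,
                          subject_id or parts[0].subject_id)


def oversample_minority(d: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Duplicate minority rows (with replacement, seeded) to a 1:1 ratio.

    Majority rows are untouched; every added row is an exact duplicate
    of an existing minority row.
    """
    n0, n1 = d.class_counts
    if n0 == 0 or n1 == 0:
        raise LabelingError("both classes must be present to oversample")
    if n0 == n1:
        return d
    rng = np.random.default_rng(seed)
    minority = 1 if n1 < n0 else 0
    idx_min = np.nonzero(d.labels == minority)[0]
    extra = rng.choice(idx_min, size=abs(n0 - n1), replace=True)
    order = np.concatenate([np.arange(d.n), extra])
    fm = FeatureMatrix(
        np.arange(len(order), dtype=np.int64),
        d.features.values.iloc[order].reset_index(drop=True),
    )
    return LabeledDataset(fm, d.labels[order], d.window_s, d.subject_id)
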