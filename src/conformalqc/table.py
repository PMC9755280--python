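"""The per-example score table: probability vectors with optional truths.

A :class:`LabeledScoreTable` is the tabular currency of the package — one
row per biopsy (or, generally, per example) holding an identifier, an
optional subject identifier, an optional true label, a dataset tag, and a
probability vector over a fixed :class:`~conformalqc.labels.LabelSet`.
It wraps a pandas DataFrame with the column contract

    example_id, subject_id, true_label, dataset_tag, p_<label> ...

and validates the simplex constraint on ingest: probability vectors whose
sum deviates from 1 by at most ``1e-6`` are renormalized (a warning is
logged), larger deviations or negative entries are rejected with the row
index in the message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import LabelSet

logger = logging.getLogger(__name__)

SUM_TOLERANCE = 1e-6

_META_COLUMNS = ["example_id", "subject_id", "true_label", "dataset_tag"]


@dataclass
class LabeledScoreTable:
    """Per-example probability vectors with optional true labels.

    Attributes
    ----------
    label_set
        The ordered class labels the probability columns refer to.
    df
        DataFrame with columns ``example_id``, ``subject_id``,
        ``true_label``, ``dataset_tag`` and one ``p_<label>`` column per
        class, in label-set order. ``subject_id`` and ``true_label`` may
        be missing (NaN/None) per row.
    """

    label_set: LabelSet
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df, self.label_set)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probs(self) -> np.ndarray:
        """(n, k) array of probability vectors in label-set order."""
        return self.df[self.label_set.prob_columns].to_numpy(dtype=float)

    @property
    def has_truth(self) -> bool:
        return self.df["true_label"].notna().all() and len(self.df) > 0

    @property
    def true_labels(self) -> np.ndarray:
        """True labels as strings; raises if any are missing."""
        col = self.df["true_label"]
        if col.isna().any():
            n_missing = int(col.isna().sum())
            raise ValueError(f"{n_missing} rows have no true label")
        return col.to_numpy(dtype=object)

    @property
    def true_label_indices(self) -> np.ndarray:
        """True labels as integer indices into the label set."""
        idx = {lab: i for i, lab in enumerate(self.label_set)}
        return np.array([idx[lab] for lab in self.true_labels], dtype=np.intp)

    def argmax_labels(self) -> np.ndarray:
        """Point-prediction labels (argmax of probs, first label wins ties)."""
        order = np.argmax(self.probs, axis=1)
        labels = np.asarray(self.label_set.labels, dtype=object)
        return labels[order]

    def subset(self, mask_or_index) -> "LabeledScoreTable":
        return LabeledScoreTable(self.label_set, self.df.loc[mask_or_index].reset_index(drop=True))

    def with_tag(self, tag: str) -> "LabeledScoreTable":
        df = self.df.copy()
        df["dataset_tag"] = tag
        return LabeledScoreTable(self.label_set, df)

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path, sep: str = ",") -> None:
        """Write the table; floats at 12 significant digits, missing fields empty."""
        out = self.df[_META_COLUMNS + self.label_set.prob_columns]
        out.to_csv(path, sep=sep, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path, label_set: LabelSet) -> "LabeledScoreTable":
        """Read a table written by :meth:`write_csv` (TSV accepted by sniffing)."""
        df = pd.read_csv(
            path,
            sep=None,
            engine="python",
            dtype={"example_id": str, "subject_id": str, "true_label": str, "dataset_tag": str},
        )
        missing = [c for c in label_set.prob_columns if c not in df.columns]
        if missing:
            raise ValueError(f"missing probability column(s) {missing} in {path}")
        for col in _META_COLUMNS:
            if col not in df.columns:
                df[col] = None
        return cls(label_set, df)


def _validate_frame(df: pd.DataFrame, label_set: LabelSet) -> pd.DataFrame:
    df = df.reset_index(drop=True).copy()
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    pcols = label_set.prob_columns
    missing = [c for c in pcols if c not in df.columns]
    if missing:
        raise ValueError(f"missing probability column(s) {missing}")

    if df["example_id"].duplicated().any():
        dup = df.loc[df["example_id"].duplicated(), "example_id"].iloc[0]
        raise ValueError(f"duplicate example_id {dup!r}")

    known = df["true_label"].dropna()
    bad = ~known.isin(list(label_set))
    if bad.any():
        row = known.index[bad][0]
        raise ValueError(f"row {row}: unknown label {known[bad].iloc[0]!r}")

    probs = df[pcols].to_numpy(dtype=float)
    if not np.isfinite(probs).all():
        row = int(np.argwhere(~np.isfinite(probs).all(axis=1))[0, 0])
        raise ValueError(f"row {row}: non-finite probability")
    neg = probs < 0
    if neg.any():
        row = int(np.argwhere(neg.any(axis=1))[0, 0])
        raise ValueError(f"row {row}: negative probability {probs[neg][0]}")
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0) > SUM_TOLERANCE
    if off.any():
        row = int(np.argwhere(off)[0, 0])
        raise ValueError(
            f"row {row}: probability sum {sums[row]:.8f} deviates from 1 "
            f"by more than {SUM_TOLERANCE}"
        )
    needs = np.abs(sums - 1.0) > 1e-12
    if needs.any():
        logger.warning("renormalized %d probability vectors (sum off by <= %g)",
                       int(needs.sum()), SUM_TOLERANCE)
        probs = probs / sums[:, None]
        df[pcols] = probs
    df["example_id"] = df["example_id"].astype(str)
    return df


def concat_tables(tables: list[LabeledScoreTable]) -> LabeledScoreTable:
    """Stack tables sharing a label set; example ids must stay unique."""
    if not tables:
        raise ValueError("no tables to concatenate")
    label_set = tables[0].label_set
    if any(t.label_set != label_set for t in tables):
        raise ValueError("tables have differing label sets")
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return LabeledScoreTable(label_set, df)
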