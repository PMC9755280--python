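"""Mondrian inductive conformal prediction over classifier probabilities.

The predictor wraps any classifier that outputs a probability vector per
example. A held-out *calibration set* (by default 10% of the labeled
data, split by subject so no man contributes to both sides) supplies, for
each class, the empirical distribution of nonconformity scores

    alpha(x, y) = 1 - p_hat(y | x),

i.e. one minus the predicted probability of the true class. For a new
example and a candidate label y, the conformal p-value is the proportion
of calibration examples of true class y (plus the new one) whose score is
at least as extreme:

    p(y) = ( #{alpha_i >= alpha_new} + 1 ) / (n_y + 1)          (non-smoothed)
    p(y) = ( #{alpha_i > alpha_new} + tau * (#{alpha_i = alpha_new} + 1) )
           / (n_y + 1),   tau ~ U(0,1)                          (smoothed)

The label is included in the prediction region when p(y) > 1 - c(y),
where c(y) is the desired confidence, set globally or per class.
Stratifying calibration by the *true* class — the Mondrian construction —
bounds the error rate within each class, not just marginally, which
matters under the heavy class imbalance of biopsy grading.

Non-smoothed p-values are conservative (error rate <= epsilon) and
deterministic; smoothed p-values are exactly uniform under
exchangeability and are used for distributional diagnostics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .labels import LabelSet
from .table import LabeledScoreTable

logger = logging.getLogger(__name__)

#: Below this many calibration examples in a class stratum the coverage
#: guarantee is too coarse to be useful (p-values cannot resolve below
#: 1/(n+1)); calibrate() warns.
DEFAULT_MIN_PER_CLASS = 25


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitSpec:
    """Proper-training / calibration split specification.

    The default reserves 10% of the labeled data for calibration. When
    ``group_field`` is set (by default ``subject_id`` is used whenever
    present), whole groups go to one side only, mirroring a split by
    patient rather than by biopsy.
    """

    calibration_fraction: float = 0.10
    group_field: Optional[str] = "subject_id"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")


def split_train_calibration(
    table: LabeledScoreTable, spec: SplitSpec = SplitSpec()
) -> tuple[LabeledScoreTable, LabeledScoreTable]:
    """Split into (proper training, calibration) tables.

    The split is disjoint and exhaustive. With grouping, groups are
    shuffled and accumulated into the calibration side until its row
    count reaches the target fraction, so the achieved fraction is within
    one group of the target. Rows without the group field fall back to a
    row-level split.
    """
    if not table.has_truth:
        raise ValueError("split requires true labels on every row")
    n = len(table)
    rng = np.random.default_rng(spec.seed)
    target = spec.calibration_fraction * n

    group_col = None
    if spec.group_field is not None and spec.group_field in table.df.columns:
        col = table.df[spec.group_field]
        if col.notna().all():
            group_col = col.to_numpy(dtype=object)

    if group_col is None:
        order = rng.permutation(n)
        n_cal = max(1, int(round(target)))
        cal_idx = np.sort(order[:n_cal])
        train_idx = np.sort(order[n_cal:])
    else:
        groups = pd.unique(group_col)
        rng.shuffle(groups)
        sizes = pd.Series(range(n)).groupby(group_col).size()
        if (sizes.max() > (1.0 - spec.calibration_fraction) * n) and len(groups) > 1:
            warnings.warn(
                "one group holds most of the rows; the split is degenerate",
                stacklevel=2,
            )
        cal_groups = set()
        count = 0
        for g in groups:
            if count >= target:
                break
            cal_groups.add(g)
            count += int(sizes[g])
        mask = np.array([g in cal_groups for g in group_col])
        cal_idx = np.flatnonzero(mask)
        train_idx = np.flatnonzero(~mask)

    logger.info("split %d rows -> %d proper training, %d calibration",
                n, len(train_idx), len(cal_idx))
    return table.subset(train_idx), table.subset(cal_idx)


# ---------------------------------------------------------------------------
# nonconformity and calibration

def nonconformity(probs: Union[np.ndarray, Mapping[str, float]],
                  label: str, label_set: LabelSet) -> float:
    """One minus the predicted probability of ``label`` (in [0, 1])."""
    j = label_set.index(label)
    p = np.asarray(probs if not isinstance(probs, Mapping)
                   else [probs[l] for l in label_set], dtype=float)
    return float(1.0 - p[j])


@dataclass
class MondrianCalibrator:
    """Per-class sorted nonconformity scores from the calibration split."""

    label_set: LabelSet
    scores: dict[str, np.ndarray]  # label -> ascending array in [0, 1]

    def __post_init__(self) -> None:
        for lab in self.label_set:
            s = np.sort(np.asarray(self.scores.get(lab, []), dtype=float))
            if s.size and (s[0] < 0 or s[-1] > 1):
                raise ValueError(f"nonconformity scores for {lab!r} outside [0, 1]")
            self.scores[lab] = s

    @property
    def class_counts(self) -> dict[str, int]:
        return {lab: int(self.scores[lab].size) for lab in self.label_set}

    def pooled_scores(self) -> np.ndarray:
        """All calibration scores (true-label nonconformity), pooled over classes."""
        return np.concatenate([self.scores[lab] for lab in self.label_set])

    # -- persistence -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "labels": list(self.label_set.labels),
            "ordinal": self.label_set.ordinal,
            "scores": {lab: self.scores[lab].tolist() for lab in self.label_set},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MondrianCalibrator":
        with open(path) as fh:
            payload = json.load(fh)
        label_set = LabelSet(tuple(payload["labels"]), ordinal=payload.get("ordinal", False))
        scores = {lab: np.asarray(v, dtype=float) for lab, v in payload["scores"].items()}
        return cls(label_set, scores)


def calibrate(calibration_table: LabeledScoreTable,
              min_per_class: int = DEFAULT_MIN_PER_CLASS) -> MondrianCalibrator:
    """Build the Mondrian calibrator from a labeled calibration table.

    For each class the nonconformity scores of the rows whose *true*
    label is that class are stored sorted. Classes with fewer than
    ``min_per_class`` examples trigger a warning: with n scores the
    smallest attainable p-value is 1/(n+1), so small strata make tight
    significance levels unreachable.
    """
    if len(calibration_table) == 0:
        raise ValueError("empty calibration table")
    truths = calibration_table.true_labels
    probs = calibration_table.probs
    label_set = calibration_table.label_set
    idx = calibration_table.true_label_indices
    alpha = 1.0 - probs[np.arange(len(truths)), idx]

    scores = {}
    for j, lab in enumerate(label_set):
        scores[lab] = alpha[idx == j]
        if scores[lab].size < min_per_class:
            warnings.warn(
                f"class {lab!r} has only {scores[lab].size} calibration examples "
                f"(< {min_per_class}); its coverage guarantee is coarse",
                stacklevel=2,
            )
    return MondrianCalibrator(label_set, scores)


# ---------------------------------------------------------------------------
# p-values

def p_value(calibrator: MondrianCalibrator, label: str, alpha_new: float,
            smoothed: bool = False, tie_draw: Optional[float] = None) -> float:
    """Conformal p-value for one candidate label (scalar convenience)."""
    out = p_values(calibrator, label, np.asarray([alpha_new], dtype=float),
                   smoothed=smoothed,
                   tie_draws=None if tie_draw is None else np.asarray([tie_draw]))
    return float(out[0])


def p_values(calibrator: MondrianCalibrator, label: str, alpha_new: np.ndarray,
             smoothed: bool = False,
             tie_draws: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorized conformal p-values for one candidate label.

    Non-smoothed: ``(#{a_i >= a} + 1) / (n + 1)``. Smoothed:
    ``(#{a_i > a} + tau * (#{a_i = a} + 1)) / (n + 1)`` with ``tau`` the
    supplied tie draw per example. Both lie in (0, 1]; an empty class
    stratum forces p = 1 (non-smoothed) or p = tau.
    """
    s = calibrator.scores[label] if label in calibrator.scores else None
    if s is None:
        raise KeyError(f"label {label!r} not in calibrator")
    a = np.asarray(alpha_new, dtype=float)
    if ((a < 0) | (a > 1)).any():
        raise ValueError("alpha_new must lie in [0, 1]")
    n = s.size
    if smoothed:
        if tie_draws is None:
            raise ValueError("smoothed p-values need tie_draws")
        tau = np.asarray(tie_draws, dtype=float)
        n_gt = n - np.searchsorted(s, a, side="right")
        n_eq = np.searchsorted(s, a, side="right") - np.searchsorted(s, a, side="left")
        return (n_gt + tau * (n_eq + 1)) / (n + 1)
    n_ge = n - np.searchsorted(s, a, side="left")
    return (n_ge + 1.0) / (n + 1)


# ---------------------------------------------------------------------------
# confidence and regions

@dataclass(frozen=True)
class ConfidenceSpec:
    """Per-class desired confidence c(label) in (0, 1); eps = 1 - c."""

    confidence: Mapping[str, float]

    def __post_init__(self) -> None:
        for lab, c in self.confidence.items():
            if not 0.0 < c < 1.0:
                raise ValueError(f"confidence for {lab!r} must be in (0, 1), got {c}")
        object.__setattr__(self, "confidence", dict(self.confidence))

    @classmethod
    def global_level(cls, c: float, label_set: LabelSet) -> "ConfidenceSpec":
        return cls({lab: c for lab in label_set})

    def epsilon(self, label: str) -> float:
        if label not in self.confidence:
            raise KeyError(f"no confidence level for label {label!r}")
        return 1.0 - self.confidence[label]

    def covers(self, label_set: LabelSet) -> bool:
        return all(lab in self.confidence for lab in label_set)

    def describe(self) -> str:
        vals = set(self.confidence.values())
        if len(vals) == 1:
            return f"{100 * next(iter(vals)):g}%"
        return ", ".join(f"{lab}={100 * c:g}%" for lab, c in self.confidence.items())


@dataclass
class PredictionRegion:
    """Per-example label -> p-value map and the included label set."""

    example_id: str
    p_values: dict[str, float]
    included: frozenset[str]
    category: str = "unknown_truth"  # empty | correct_single | correct_multiple | error | unknown_truth

    @property
    def size(self) -> int:
        return len(self.included)


def categorize(included: frozenset[str], truth: Optional[str]) -> str:
    """Four-way outcome of a region against the truth (if known)."""
    if truth is None:
        return "unknown_truth"
    if len(included) == 0:
        return "empty"
    if truth not in included:
        return "error"
    return "correct_single" if len(included) == 1 else "correct_multiple"


def predict_region(calibrator: MondrianCalibrator, probs: np.ndarray,
                   conf: ConfidenceSpec, smoothed: bool = False,
                   seed: int = 0) -> PredictionRegion:
    """Prediction region for a single probability vector."""
    table_like = np.asarray(probs, dtype=float)[None, :]
    regions = predict_regions_from_probs(
        calibrator, table_like, conf, example_ids=["example-0"],
        smoothed=smoothed, seed=seed)
    return regions[0]


def predict_regions(calibrator: MondrianCalibrator, table: LabeledScoreTable,
                    conf: ConfidenceSpec, smoothed: bool = False,
                    seed: int = 0) -> list[PredictionRegion]:
    """Prediction regions for every row of a score table (vectorized)."""
    truths = table.df["true_label"].to_numpy(dtype=object) if "true_label" in table.df else None
    return predict_regions_from_probs(
        calibrator, table.probs, conf,
        example_ids=table.df["example_id"].tolist(),
        truths=truths, smoothed=smoothed, seed=seed)


def predict_regions_from_probs(calibrator: MondrianCalibrator, probs: np.ndarray,
                               conf: ConfidenceSpec,
                               example_ids: Sequence[str],
                               truths: Optional[np.ndarray] = None,
                               smoothed: bool = False,
                               seed: int = 0) -> list[PredictionRegion]:
    label_set = calibrator.label_set
    if not conf.covers(label_set):
        raise ValueError("confidence spec does not cover every label")
    probs = np.asarray(probs, dtype=float)
    n, k = probs.shape
    if k != len(label_set):
        raise ValueError(f"probability vectors have {k} entries, expected {len(label_set)}")
    _warn_unreachable_eps(calibrator, conf)

    rng = np.random.default_rng(seed)
    pmat = np.empty((n, k))
    inc = np.empty((n, k), dtype=bool)
    for j, lab in enumerate(label_set):
        a = 1.0 - probs[:, j]
        tau = rng.random(n) if smoothed else None
        pmat[:, j] = p_values(calibrator, lab, a, smoothed=smoothed, tie_draws=tau)
        inc[:, j] = pmat[:, j] > conf.epsilon(lab)

    labels = label_set.labels
    regions = []
    for i in range(n):
        included = frozenset(labels[j] for j in range(k) if inc[i, j])
        truth = None
        if truths is not None and truths[i] is not None and not pd.isna(truths[i]):
            truth = truths[i]
        regions.append(PredictionRegion(
            example_id=str(example_ids[i]),
            p_values={labels[j]: float(pmat[i, j]) for j in range(k)},
            included=included,
            category=categorize(included, truth),
        ))
    return regions


def true_label_p_values(calibrator: MondrianCalibrator, table: LabeledScoreTable,
                        smoothed: bool = False, seed: int = 0) -> np.ndarray:
    """p-value of each row's *true* label — the validity diagnostic.

    Under exchangeability these are conservative-uniform (non-smoothed)
    or exactly uniform on (0, 1] (smoothed); departures indicate drift.
    """
    probs = table.probs
    idx = table.true_label_indices
    n = len(table)
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    for j, lab in enumerate(table.label_set):
        mask = idx == j
        if not mask.any():
            continue
        a = 1.0 - probs[mask, j]
        tau = rng.random(int(mask.sum())) if smoothed else None
        out[mask] = p_values(calibrator, lab, a, smoothed=smoothed, tie_draws=tau)
    return out


def _warn_unreachable_eps(calibrator: MondrianCalibrator, conf: ConfidenceSpec) -> None:
    for lab in calibrator.label_set:
        n_c = calibrator.scores[lab].size
        eps = conf.epsilon(lab)
        if (n_c + 1) < 1.0 / eps:
            warnings.warn(
                f"class {lab!r}: {n_c} calibration scores cannot yield p <= "
                f"{eps:g}; the region always contains this label",
                stacklevel=3,
            )


def regions_to_frame(regions: Sequence[PredictionRegion], label_set: LabelSet) -> pd.DataFrame:
    """Regions as a DataFrame: pval_<label> columns, semicolon-joined region."""
    rows = []
    for r in regions:
        row = {"example_id": r.example_id}
        for lab in label_set:
            row[f"pval_{lab}"] = r.p_values[lab]
        row["region"] = ";".join(lab for lab in label_set if lab in r.included)
        row["category"] = r.category
        rows.append(row)
    return pd.DataFrame(rows)


def regions_from_frame(df: pd.DataFrame, label_set: LabelSet) -> list[PredictionRegion]:
    regions = []
    for _, row in df.iterrows():
        included = frozenset(x for x in str(row["region"]).split(";") if x) \
            if not pd.isna(row["region"]) else frozenset()
        regions.append(PredictionRegion(
            example_id=str(row["example_id"]),
            p_values={lab: float(row[f"pval_{lab}"]) for lab in label_set},
            included=included,
            category=row.get("category", "unknown_truth"),
        ))
    return regions
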