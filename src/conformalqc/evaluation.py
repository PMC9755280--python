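"""Evaluation of prediction regions and point predictions.

Mirrors the reporting surfaces used when conformal prediction is audited
as a quality-control layer:

* a four-way tally of regions per class — *error* (non-empty region that
  misses the truth), *empty*, *correct single*, *correct multiple* — and
  the *efficiency* (share of correct singletons);
* the point-prediction (argmax) error, the CP-free baseline;
* the calibration curve of observed error versus significance level,
  whose closeness to the diagonal diagnoses validity;
* coverage of an expert-panel's individual votes by the regions;
* region-size statistics;
* a simulated human-in-the-loop experiment: AUC when flagged (empty or
  multiple) predictions are referred to an expert of stated accuracy.

Two error notions coexist and are deliberately kept apart: the tally's
"error" row counts non-empty regions excluding the truth (so the four
categories partition n), while the calibration curve counts every true
label outside the region — including empty regions — as an error, which
is the quantity the conformal guarantee bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .conformal import PredictionRegion, categorize
from .labels import LabelSet
from .table import LabeledScoreTable

CATEGORIES = ("error", "empty", "correct_single", "correct_multiple")


@dataclass
class EvaluationReport:
    """Per-class and overall region tallies plus efficiency."""

    label_set: LabelSet
    counts: pd.DataFrame  # index: class labels + "all"; columns: CATEGORIES + "n"

    @property
    def efficiency(self) -> float:
        row = self.counts.loc["all"]
        return float(row["correct_single"] / row["n"]) if row["n"] else 0.0

    def percentages(self) -> pd.DataFrame:
        """Whole-percent table alongside counts, table-style."""
        pct = self.counts[list(CATEGORIES)].div(self.counts["n"], axis=0) * 100
        return pct.fillna(0.0).round(0).astype(int)  # classes with n=0 show 0%

    def to_long_frame(self, dataset_tag: str = "") -> pd.DataFrame:
        rows = []
        for cls in self.counts.index:
            n = int(self.counts.loc[cls, "n"])
            for cat in CATEGORIES:
                cnt = int(self.counts.loc[cls, cat])
                rows.append({
                    "dataset_tag": dataset_tag, "class": cls, "category": cat,
                    "count": cnt, "percent": 100.0 * cnt / n if n else 0.0,
                })
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        pct = self.percentages()
        lines = [f"{'':18s}" + "".join(f"{c:>18s}" for c in self.counts.index)]
        for cat in CATEGORIES:
            cells = [f"{int(self.counts.loc[c, cat])} ({pct.loc[c, cat]}%)"
                     for c in self.counts.index]
            lines.append(f"{cat:18s}" + "".join(f"{s:>18s}" for s in cells))
        lines.append(f"{'n':18s}" + "".join(f"{int(self.counts.loc[c, 'n']):>18d}"
                                            for c in self.counts.index))
        lines.append(f"efficiency {self.efficiency:.3f}")
        return "\n".join(lines)


def tally_regions(regions: Sequence[PredictionRegion], truths: Sequence[str],
                  label_set: LabelSet) -> EvaluationReport:
    """Categorize each region against its truth and tally per class.

    Every example lands in exactly one of the four categories, so the
    rows sum to the class size.
    """
    if len(regions) != len(truths):
        raise ValueError(f"{len(regions)} regions but {len(truths)} truths")
    idx = list(label_set.labels) + ["all"]
    counts = pd.DataFrame(0, index=idx, columns=list(CATEGORIES) + ["n"], dtype=int)
    for region, truth in zip(regions, truths):
        if truth not in label_set:
            raise ValueError(f"unknown truth {truth!r}")
        cat = categorize(region.included, truth)
        for cls in (truth, "all"):
            counts.loc[cls, cat] += 1
            counts.loc[cls, "n"] += 1
    return EvaluationReport(label_set, counts)


def point_prediction_tally(table: LabeledScoreTable) -> pd.DataFrame:
    """Argmax baseline: per-class error/correct counts (ties -> first label)."""
    truths = table.true_labels
    preds = table.argmax_labels()
    idx = list(table.label_set.labels) + ["all"]
    out = pd.DataFrame(0, index=idx, columns=["error", "correct", "n"], dtype=int)
    for truth, pred in zip(truths, preds):
        col = "correct" if pred == truth else "error"
        for cls in (truth, "all"):
            out.loc[cls, col] += 1
            out.loc[cls, "n"] += 1
    return out


@dataclass
class CalibrationCurve:
    """Observed error rate versus significance level epsilon."""

    epsilon: np.ndarray
    observed_error: np.ndarray
    n: int

    def max_deviation(self) -> float:
        """sup |observed error - epsilon| over the grid."""
        return float(np.max(np.abs(self.observed_error - self.epsilon)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epsilon": self.epsilon,
                             "observed_error": self.observed_error,
                             "n": self.n})


def calibration_curve(true_label_pvalues: np.ndarray, grid_size: int = 1001) -> CalibrationCurve:
    """Observed error (fraction of true-label p-values <= eps) on a uniform grid.

    For a valid predictor the curve hugs the diagonal from below; for
    smoothed p-values on exchangeable data it matches the diagonal up to
    Monte-Carlo noise.
    """
    p = np.asarray(true_label_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    eps = np.linspace(0.0, 1.0, grid_size)
    p_sorted = np.sort(p)
    err = np.searchsorted(p_sorted, eps, side="right") / p.size
    return CalibrationCurve(eps, err, n=p.size)


@dataclass
class PanelVotes:
    """Independent labels assigned per example by a rater panel."""

    votes: list[tuple[str, ...]]  # one tuple of labels per example

    def total(self) -> int:
        return sum(len(v) for v in self.votes)


def panel_coverage(regions: Sequence[PredictionRegion], votes: PanelVotes) -> float:
    """Fraction of individual panel votes falling inside the regions.

    Each rater's label for each example counts once; a vote is covered
    when the label is in that example's prediction region.
    """
    if len(regions) != len(votes.votes):
        raise ValueError(f"{len(regions)} regions but {len(votes.votes)} vote tuples")
    total = votes.total()
    if total == 0:
        raise ValueError("panel has no votes")
    covered = sum(
        sum(1 for v in vote_tuple if v in region.included)
        for region, vote_tuple in zip(regions, votes.votes)
    )
    return covered / total


def region_size_stats(regions: Sequence[PredictionRegion],
                      multiples_only: bool = False) -> dict:
    """Median and distribution of region sizes (optionally multiples only)."""
    sizes = [r.size for r in regions]
    if multiples_only:
        sizes = [s for s in sizes if s >= 2]
    if not sizes:
        return {"n": 0, "median": float("nan"), "distribution": {}}
    arr = np.asarray(sizes)
    dist = {int(k): int(v) for k, v in zip(*np.unique(arr, return_counts=True))}
    return {"n": int(arr.size), "median": float(np.median(arr)), "distribution": dist}


def human_in_loop_auc(table: LabeledScoreTable, regions: Sequence[PredictionRegion],
                      expert_accuracy: float = 1.0, seed: int = 0,
                      positive_label: Optional[str] = None) -> tuple[float, float]:
    """Simulated referral workflow for binary detection.

    The standalone AUC uses the classifier's positive-class probability.
    In the combined workflow, every example the conformal predictor flags
    as unreliable (empty or multiple region) is referred to an expert who
    returns the truth-indicating extreme score (1 for a true positive, 0
    for a true negative) with probability ``expert_accuracy``, else the
    opposite extreme. Returns (standalone AUC, combined AUC).
    """
    if len(table.label_set) != 2:
        raise ValueError("human-in-the-loop AUC requires a binary label set")
    if not 0.0 <= expert_accuracy <= 1.0:
        raise ValueError("expert_accuracy must be in [0, 1]")
    if len(regions) != len(table):
        raise ValueError("regions and table are misaligned")
    pos = positive_label or table.label_set.labels[1]
    j = table.label_set.index(pos)
    y = (table.true_labels == pos).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC undefined: only one class present")
    scores = table.probs[:, j].copy()

    rng = np.random.default_rng(seed)
    flagged = np.array([r.size != 1 for r in regions])
    standalone = float(roc_auc_score(y, scores))
    if flagged.any():
        correct = rng.random(int(flagged.sum())) < expert_accuracy
        truth_extreme = y[flagged].astype(float)
        scores[flagged] = np.where(correct, truth_extreme, 1.0 - truth_extreme)
    combined = float(roc_auc_score(y, scores))
    return standalone, combined
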