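"""Drift detection and power analysis for a deployed conformal predictor.

The conformal guarantee rests on exchangeability between the calibration
data and incoming data. When a deployment site changes something
systematic — a new slide scanner, a different laboratory, tissue the
model never saw — the nonconformity-score distribution shifts, and a
two-sample Kolmogorov-Smirnov (KS) test between calibration scores and
deployment scores detects it.

Two operationalizations of "the distribution of the predictions" are
provided and always recorded in the result:

``labeled``
    deployment scores at the *true* label (requires ground truth);
``predicted_label``
    deployment scores at the argmax label (no truth needed — the
    monitoring setting).

:func:`power_curve` estimates, by repeated subsampling from a shifted
pool, how many deployment observations are needed before the KS test
detects the shift with a requested probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .conformal import MondrianCalibrator
from .table import LabeledScoreTable

#: Use the exact KS null distribution when both samples are at most this
#: size; asymptotic otherwise.
EXACT_KS_MAX_N = 100


@dataclass
class DriftTestResult:
    ks_statistic: float
    p_value: float
    n_cal: int
    n_test: int
    mode: str  # labeled | predicted_label
    alpha: float = 0.05
    method: str = "asymp"  # exact | asymp

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "ks_statistic": self.ks_statistic, "p_value": self.p_value,
            "n_cal": self.n_cal, "n_test": self.n_test, "mode": self.mode,
            "alpha": self.alpha, "method": self.method,
            "significant": self.significant,
        }


def ks_two_sample(sample_a: Sequence[float],
                  sample_b: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided two-sample KS test.

    Returns (statistic, p-value, method). The statistic is the sup
    distance between the two empirical distribution functions; the
    p-value comes from the exact null distribution when both samples
    hold at most 100 observations, from the asymptotic Kolmogorov
    distribution otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size <= EXACT_KS_MAX_N and b.size <= EXACT_KS_MAX_N) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def _test_scores(calibrator: MondrianCalibrator, table: LabeledScoreTable,
                 mode: str) -> np.ndarray:
    probs = table.probs
    if mode == "labeled":
        idx = table.true_label_indices
    elif mode == "predicted_label":
        idx = np.argmax(probs, axis=1)
    else:
        raise ValueError(f"unknown drift mode {mode!r}")
    return 1.0 - probs[np.arange(len(table)), idx]


def drift_test(calibrator: MondrianCalibrator, test_table: LabeledScoreTable,
               mode: str = "labeled", alpha: float = 0.05) -> DriftTestResult:
    """KS-compare calibration nonconformity scores against a test table.

    Labeled mode pools the calibrator's true-label scores and compares
    them with the test rows' true-label scores; predicted_label mode uses
    each test row's argmax label instead, so it runs without ground truth.
    """
    cal = calibrator.pooled_scores()
    test = _test_scores(calibrator, test_table, mode)
    stat, pval, method = ks_two_sample(cal, test)
    return DriftTestResult(stat, pval, n_cal=cal.size, n_test=test.size,
                           mode=mode, alpha=alpha, method=method)


@dataclass
class PowerCurve:
    """KS-test power as a function of deployment sample size."""

    n_grid: np.ndarray
    power: np.ndarray
    n_reps: int
    alpha: float
    power_threshold: float

    @property
    def n_required(self) -> Optional[int]:
        """Smallest grid size reaching the power threshold, if any."""
        hit = np.flatnonzero(self.power >= self.power_threshold)
        return int(self.n_grid[hit[0]]) if hit.size else None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"n": self.n_grid, "power": self.power,
                             "n_reps": self.n_reps, "alpha": self.alpha})


def power_curve(calibrator: MondrianCalibrator, shifted_pool: LabeledScoreTable,
                n_grid: Sequence[int], n_reps: int = 1000, alpha: float = 0.05,
                power_threshold: float = 0.80, seed: int = 0,
                mode: str = "labeled") -> PowerCurve:
    """Estimate KS detection power by repeated subsampling.

    For each n in the (strictly increasing) grid, draw ``n_reps``
    subsamples of n rows without replacement from the shifted pool, run
    the drift test on each, and estimate power as the rejection fraction
    at ``alpha``. ``n_required`` is the smallest grid n whose estimated
    power reaches ``power_threshold``.
    """
    grid = np.asarray(list(n_grid), dtype=int)
    if grid.size == 0 or (np.diff(grid) <= 0).any():
        raise ValueError("n_grid must be a non-empty strictly increasing sequence")
    if grid[0] < 1:
        raise ValueError("grid sizes must be >= 1")
    if grid[-1] > len(shifted_pool):
        raise ValueError(f"grid size {grid[-1]} exceeds pool size {len(shifted_pool)}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    cal = calibrator.pooled_scores()
    pool = _test_scores(calibrator, shifted_pool, mode)
    rng = np.random.default_rng(seed)
    power = np.empty(grid.size)
    for gi, n in enumerate(grid):
        rejections = 0
        for _ in range(n_reps):
            sub = rng.choice(pool, size=int(n), replace=False)
            _, pval, _ = ks_two_sample(cal, sub)
            if pval < alpha:
                rejections += 1
        power[gi] = rejections / n_reps
    return PowerCurve(grid, power, n_reps=n_reps, alpha=alpha,
                      power_threshold=power_threshold)
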