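"""Canned validity and drift experiments on synthetic scores.

These functions bundle the package's headline checks into single calls
used by the acceptance script, the test suite and the examples:

* :func:`marginal_validity_experiment` — empirical error rate of the
  Mondrian predictor at a given confidence on exchangeable binary data;
* :func:`shift_detection_experiment` — KS drift-test p-values when a
  temperature distortion is applied to a test set;
* :func:`mondrian_validity_experiment` — per-class error rates at chosen
  significance levels under class imbalance;
* :func:`pvalue_uniformity_experiment` — the calibration-curve deviation
  of pooled smoothed true-label p-values from the diagonal.

Every experiment takes one integer seed and derives its internal streams
from it, so results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .conformal import calibrate, true_label_p_values
from .drift import drift_test
from .evaluation import calibration_curve
from .labels import BINARY, GRADING, LabelSet
from .pipeline import derive_seed
from .synthetic import (GRADING_PREVALENCE_COUNTS, ShiftSpec, SyntheticConfig,
                        apply_shift, generate_table, normalize_prevalence)
from .table import LabeledScoreTable


def _balanced_calibration(label_set: LabelSet, n_per_class: int,
                          seed: int, discriminability: float = 1.0) -> LabeledScoreTable:
    """Calibrated-mode table truncated to exactly n_per_class rows per class.

    Rows are generated i.i.d. and each class stratum keeps its first
    n_per_class rows; truncating an i.i.d. stream class-wise preserves
    exchangeability with future draws from the same generator.
    """
    k = len(label_set)
    n_draw = int(np.ceil(n_per_class * k * 1.25)) + 200
    for attempt in range(5):
        cfg = SyntheticConfig(label_set, n_draw, (1.0 / k,) * k,
                              discriminability=discriminability,
                              seed=derive_seed(seed, f"balcal{attempt}"),
                              dataset_tag="calibration")
        table = generate_table(cfg)
        truths = table.true_labels
        keep: list[int] = []
        ok = True
        for lab in label_set:
            rows = np.flatnonzero(truths == lab)
            if rows.size < n_per_class:
                ok = False
                break
            keep.extend(rows[:n_per_class])
        if ok:
            return table.subset(sorted(keep))
        n_draw *= 2
    raise RuntimeError("could not fill calibration strata")  # pragma: no cover


def marginal_validity_experiment(seed: int, n_cal_per_class: int = 5500,
                                 n_test: int = 100_000, n_seeds: int = 20,
                                 confidence: float = 0.999) -> dict:
    """Pooled marginal error rate of the non-smoothed Mondrian predictor.

    Binary calibrated-mode data; the error counts every test example
    whose true-label p-value is at or below eps = 1 - confidence (truth
    excluded from the region). With n_c calibration scores per class the
    exact error probability is floor(eps * (n_c + 1)) / (n_c + 1) <= eps.
    Returns the pooled error as a percentage.
    """
    eps = 1.0 - confidence
    errors = 0
    total = 0
    for s in range(n_seeds):
        sub = derive_seed(seed, f"marginal{s}")
        cal_table = _balanced_calibration(BINARY, n_cal_per_class, sub)
        calibrator = calibrate(cal_table)
        test = generate_table(SyntheticConfig(
            BINARY, n_test, (0.5, 0.5), seed=derive_seed(sub, "test"),
            dataset_tag="test"))
        pv = true_label_p_values(calibrator, test, smoothed=False)
        errors += int((pv <= eps).sum())
        total += n_test
    return {
        "error_rate_percent": 100.0 * errors / total,
        "bound_percent": 100.0 * eps,
        "n_errors": errors,
        "n_total": total,
        "n_seeds": n_seeds,
    }


def shift_detection_experiment(seed: int, n_cal: int = 1000, n_test: int = 449,
                               temperature: float = 2.0, n_seeds: int = 50,
                               alpha: float = 0.05) -> dict:
    """Labeled-mode KS drift test against a temperature-distorted test set.

    Repeats calibration + shifted test generation over ``n_seeds`` seeds;
    reports the median KS p-value and the rejection rate at ``alpha``.
    """
    pvals = []
    for s in range(n_seeds):
        sub = derive_seed(seed, f"shift{s}")
        cal_table = generate_table(SyntheticConfig(
            BINARY, n_cal, (0.5, 0.5), seed=sub, dataset_tag="calibration"))
        calibrator = calibrate(cal_table)
        test = generate_table(SyntheticConfig(
            BINARY, n_test, (0.5, 0.5), seed=derive_seed(sub, "test"),
            dataset_tag="test"))
        shifted = apply_shift(test, ShiftSpec("temperature", temperature),
                              seed=derive_seed(sub, "shiftapply"))
        result = drift_test(calibrator, shifted, mode="labeled", alpha=alpha)
        pvals.append(result.p_value)
    pvals = np.asarray(pvals)
    return {
        "median_p_value": float(np.median(pvals)),
        "rejection_rate": float((pvals < alpha).mean()),
        "n_seeds": n_seeds,
        "n_test": n_test,
        "alpha": alpha,
    }


def mondrian_validity_experiment(seed: int, n_cal: int = 150_000,
                                 n_test: int = 10_000,
                                 prevalence=GRADING_PREVALENCE_COUNTS,
                                 epsilons=(0.15, 0.33)) -> dict:
    """Per-class error of smoothed p-values under class imbalance.

    Six-class calibrated-mode generator at the stated prevalences; for
    each significance level eps the within-class error rate (smoothed
    true-label p-value <= eps) is reported with its class size, so the
    caller can compare against eps within binomial noise.

    Error indicators share one calibration set, so the observed rate
    fluctuates on the scale of the calibration strata as well as the
    test strata; the default sizes keep every calibration stratum an
    order of magnitude larger than its test stratum so that test-side
    binomial noise dominates.
    """
    prev = normalize_prevalence(prevalence, len(GRADING))
    cal_table = generate_table(SyntheticConfig(
        GRADING, n_cal, tuple(prev), seed=derive_seed(seed, "cal"),
        dataset_tag="calibration"))
    calibrator = calibrate(cal_table)
    test = generate_table(SyntheticConfig(
        GRADING, n_test, tuple(prev), seed=derive_seed(seed, "test"),
        dataset_tag="test"))
    pv = true_label_p_values(calibrator, test, smoothed=True,
                             seed=derive_seed(seed, "smooth"))
    truths = test.true_labels
    out: dict = {"per_class": {}, "n_test": n_test}
    for lab in GRADING:
        mask = truths == lab
        n_c = int(mask.sum())
        out["per_class"][lab] = {
            "n": n_c,
            "errors": {eps: float((pv[mask] <= eps).mean()) for eps in epsilons},
        }
    return out


def pvalue_uniformity_experiment(seed: int, n_cal: int = 300_000,
                                 n_test: int = 20_000,
                                 grid_size: int = 1001) -> dict:
    """Max deviation of the smoothed calibration curve from the diagonal.

    The calibration set is kept much larger than the test set so the
    curve's fluctuations are dominated by test-sampling noise (the
    quantity the three-sigma bound refers to), not by calibration noise.
    """
    cal_table = generate_table(SyntheticConfig(
        BINARY, n_cal, (0.5, 0.5), seed=derive_seed(seed, "cal"),
        dataset_tag="calibration"))
    calibrator = calibrate(cal_table)
    test = generate_table(SyntheticConfig(
        BINARY, n_test, (0.5, 0.5), seed=derive_seed(seed, "test"),
        dataset_tag="test"))
    pv = true_label_p_values(calibrator, test, smoothed=True,
                             seed=derive_seed(seed, "smooth"))
    curve = calibration_curve(pv, grid_size=grid_size)
    return {
        "max_deviation": curve.max_deviation(),
        "bound": 3.0 * float(np.sqrt(0.25 / n_test)),
        "n_test": n_test,
    }
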