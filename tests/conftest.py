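import numpy as np
import pandas as pd
import pytest

from conformalqc import (BINARY, GRADING, ConfidenceSpec, LabeledScoreTable,
                         SyntheticConfig, attach_subjects, calibrate,
                         generate_table)


def oracle_p_value(scores, alpha_new, smoothed=False, tau=None):
    """Brute-force counting definition of the conformal p-value."""
    s = np.asarray(scores, dtype=float)
    n = s.size
    if smoothed:
        return (np.sum(s > alpha_new) + tau * (np.sum(s == alpha_new) + 1)) / (n + 1)
    return (np.sum(s >= alpha_new) + 1) / (n + 1)


def oracle_auc(y, scores):
    """All-pairs Mann-Whitney AUC with half credit for ties."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


def oracle_ks_statistic(a, b):
    """Brute-force sup |F_a - F_b| over all sample points."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pts = np.concatenate([a, b])
    return max(abs(np.mean(a <= t) - np.mean(b <= t)) for t in pts)


def make_table(label_set, probs, truths=None, subjects=None, tag="test"):
    """Small hand-built score table."""
    probs = np.asarray(probs, dtype=float)
    df = pd.DataFrame({
        "example_id": [f"ex{i}" for i in range(len(probs))],
        "subject_id": subjects,
        "true_label": truths,
        "dataset_tag": tag,
    })
    df[label_set.prob_columns] = probs
    return LabeledScoreTable(label_set, df)


@pytest.fixture(scope="session")
def binary_calibrated():
    """A calibrated-mode binary table with subjects, plus its calibrator."""
    cfg = SyntheticConfig(BINARY, n_examples=3000, prevalence=(0.5, 0.5), seed=11)
    table = attach_subjects(generate_table(cfg), biopsies_per_subject=6)
    return table


@pytest.fixture(scope="session")
def binary_calibrator(binary_calibrated):
    cal = binary_calibrated.subset(range(1000))
    return calibrate(cal)


@pytest.fixture(scope="session")
def grading_table():
    cfg = SyntheticConfig(GRADING, n_examples=2000,
                          prevalence=(3724, 1530, 539, 263, 469, 426),
                          discriminability=4.0, mode="class_conditional", seed=5)
    return generate_table(cfg)
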