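"""Synthetic classifier-output generator.

The analyses in this package operate on probability vectors emitted by a
trained classifier (for the motivating application, an AI system grading
prostate biopsies). Since no trained network ships with the package, this
module generates score tables with the statistical structure the conformal
analysis assumes — exchangeable rows, stated class prevalences, tunable
score sharpness — plus distortion scenarios standing in for deployment
shifts (a different scanner or laboratory, atypical tissue).

Two generative regimes are provided:

``calibrated``
    A probability vector is drawn from a Dirichlet prior with
    concentration ``discriminability * K * prevalence`` (the symmetric
    Dirichlet(discriminability) at uniform prevalence) and the true label
    is then sampled *from* that vector. Scores are perfectly calibrated
    by construction and rows are i.i.d., so calibration/test splits are
    exchangeable — the regime validity experiments require. The marginal
    class frequencies equal ``prevalence``.

``class_conditional``
    Labels are drawn first from ``prevalence``; the probability vector is
    then drawn from Dirichlet(1, ..., 1) with ``discriminability`` added
    to the true class's concentration. One parameter controls task
    difficulty; large values concentrate mass on the truth. Scores are
    not calibrated, mimicking an imperfect classifier.

Both regimes are stand-ins: real classifier scores come from a trained
model and carry structure (spatial aggregation, ensemble averaging) that
no closed-form law reproduces. See ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labels import LabelSet
from .table import LabeledScoreTable

#: ISUP-grade distribution of the motivating study's training biopsies
#: (benign, ISUP 1-5 counts 3724/1530/539/263/469/426 of n=6951).
GRADING_PREVALENCE_COUNTS = (3724, 1530, 539, 263, 469, 426)

#: Symmetric Dirichlet concentration used for near-uniform contamination
#: vectors; high enough that vectors are almost flat, finite so exact
#: nonconformity ties stay rare.
CONTAMINATION_CONCENTRATION = 200.0


def normalize_prevalence(prevalence: Sequence[float], n_classes: int) -> np.ndarray:
    """Validate a prevalence vector; raw counts are normalized to sum 1."""
    prev = np.asarray(prevalence, dtype=float)
    if prev.shape != (n_classes,):
        raise ValueError(f"prevalence has length {prev.size}, expected {n_classes}")
    if (prev < 0).any() or not np.isfinite(prev).all():
        raise ValueError("prevalence entries must be finite and >= 0")
    total = prev.sum()
    if total <= 0:
        raise ValueError("prevalence sums to zero")
    prev = prev / total
    if abs(prev.sum() - 1.0) > 1e-9:  # numerically unreachable, guards the contract
        raise ValueError("prevalence failed to normalize")
    return prev


@dataclass(frozen=True)
class ShiftSpec:
    """A deployment-shift scenario applied to a score table.

    kind
        ``temperature`` — raise each probability vector to the power
        ``1/magnitude`` and renormalize (magnitude is the temperature
        T > 0; T=1 is the identity, T→∞ flattens scores toward uniform).
        Stands in for a systematic score distortion such as a scanner or
        laboratory change.
        ``contamination`` — replace a fraction ``magnitude`` of rows
        (chosen at random) with near-uniform vectors, emulating tissue
        unlike anything in training.
        ``prevalence_shift`` — resample rows so class frequencies follow
        ``target_prevalence``.
    """

    kind: str
    magnitude: float = 0.0
    target_prevalence: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("temperature", "contamination", "prevalence_shift"):
            raise ValueError(f"unknown shift kind {self.kind!r}")
        if self.kind == "temperature" and not self.magnitude > 0:
            raise ValueError("temperature must be > 0")
        if self.kind == "contamination" and not (0.0 <= self.magnitude <= 1.0):
            raise ValueError("contamination fraction must be in [0, 1]")
        if self.kind == "prevalence_shift" and self.target_prevalence is None:
            raise ValueError("prevalence_shift requires target_prevalence")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic score table."""

    label_set: LabelSet
    n_examples: int
    prevalence: tuple[float, ...]
    discriminability: float = 1.0
    mode: str = "calibrated"
    shift: Optional[ShiftSpec] = None
    seed: int = 0
    dataset_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_examples < 1:
            raise ValueError("n_examples must be >= 1")
        if self.mode not in ("calibrated", "class_conditional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.discriminability > 0:
            raise ValueError("discriminability must be > 0")
        prev = normalize_prevalence(self.prevalence, len(self.label_set))
        object.__setattr__(self, "prevalence", tuple(prev))


def generate_labels(n: int, prevalence: Sequence[float], seed: int,
                    label_set: LabelSet) -> np.ndarray:
    """Draw ``n`` labels i.i.d. from the categorical ``prevalence``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    prev = normalize_prevalence(prevalence, len(label_set))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(label_set), size=n, p=prev)
    return np.asarray(label_set.labels, dtype=object)[idx]


def generate_probs(labels: Sequence[str], config: SyntheticConfig) -> LabeledScoreTable:
    """Attach probability vectors to labels according to ``config``.

    In ``class_conditional`` mode the supplied labels are the truths and
    vectors are drawn conditionally on them. In ``calibrated`` mode only
    the *length* of ``labels`` is used: vectors are drawn from the prior
    and the truths are re-sampled from each vector (the property that
    defines calibration), so the supplied labels are replaced.
    """
    labels = np.asarray(list(labels), dtype=object)
    n = len(labels)
    k = len(config.label_set)
    prev = np.asarray(config.prevalence)
    rng = np.random.default_rng(config.seed)

    if config.mode == "class_conditional":
        conc = np.ones((n, k))
        label_idx = np.array([config.label_set.index(l) for l in labels], dtype=np.intp)
        conc[np.arange(n), label_idx] += config.discriminability
        probs = _dirichlet_rows(conc, rng)
        true = labels
    else:  # calibrated
        conc = np.broadcast_to(config.discriminability * k * prev, (n, k))
        probs = _dirichlet_rows(np.ascontiguousarray(conc), rng)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        label_idx = np.minimum((u[:, None] > cum).sum(axis=1), k - 1)
        true = np.asarray(config.label_set.labels, dtype=object)[label_idx]

    probs = probs / probs.sum(axis=1, keepdims=True)
    df = pd.DataFrame({
        "example_id": [f"{config.dataset_tag}-{i:06d}" for i in range(n)],
        "subject_id": None,
        "true_label": true,
        "dataset_tag": config.dataset_tag,
    })
    df[config.label_set.prob_columns] = probs
    table = LabeledScoreTable(config.label_set, df)
    if config.shift is not None:
        # derive the shift seed from the table seed so one config = one table
        table = apply_shift(table, config.shift, seed=config.seed + 1)
    return table


def generate_table(config: SyntheticConfig) -> LabeledScoreTable:
    """One-call generation: labels from prevalence, then scores."""
    labels = generate_labels(config.n_examples, config.prevalence,
                             seed=config.seed, label_set=config.label_set)
    return generate_probs(labels, config)


def attach_subjects(table: LabeledScoreTable, biopsies_per_subject: int,
                    prefix: str = "subj") -> LabeledScoreTable:
    """Assign consecutive rows to synthetic subjects of fixed size.

    Emulates the grouped structure of biopsy data (several cores per man)
    so group-aware splitting can be exercised.
    """
    if biopsies_per_subject < 1:
        raise ValueError("biopsies_per_subject must be >= 1")
    df = table.df.copy()
    df["subject_id"] = [f"{prefix}{i // biopsies_per_subject:05d}" for i in range(len(df))]
    return LabeledScoreTable(table.label_set, df)


def apply_shift(table: LabeledScoreTable, shift: ShiftSpec, seed: int) -> LabeledScoreTable:
    """Apply a deployment-shift scenario, returning a new table.

    The dataset tag is suffixed with the shift kind. Identity parameters
    (T=1, contamination 0) leave probabilities bit-identical.
    """
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    pcols = table.label_set.prob_columns
    probs = table.probs

    if shift.kind == "temperature":
        if shift.magnitude != 1.0:
            probs = probs ** (1.0 / shift.magnitude)
            probs = probs / probs.sum(axis=1, keepdims=True)
            df[pcols] = probs
    elif shift.kind == "contamination":
        n = len(df)
        n_hit = int(round(shift.magnitude * n))
        hit = rng.choice(n, size=n_hit, replace=False)
        k = probs.shape[1]
        flat = rng.dirichlet(np.full(k, CONTAMINATION_CONCENTRATION), size=n_hit)
        probs[hit] = flat
        df[pcols] = probs
    else:  # prevalence_shift
        target = normalize_prevalence(shift.target_prevalence, len(table.label_set))
        truths = table.true_labels
        new_labels = np.asarray(table.label_set.labels, dtype=object)[
            rng.choice(len(table.label_set), size=len(df), p=target)
        ]
        rows = []
        for lab in new_labels:
            pool = np.flatnonzero(truths == lab)
            if pool.size == 0:
                raise ValueError(f"no source rows with label {lab!r} to resample from")
            rows.append(rng.choice(pool))
        df = df.iloc[rows].reset_index(drop=True)
        df["example_id"] = [f"{eid}-r{i}" for i, eid in enumerate(df["example_id"])]

    df["dataset_tag"] = df["dataset_tag"].astype(str) + f"+{shift.kind}"
    return LabeledScoreTable(table.label_set, df)


def _dirichlet_rows(concentration: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise Dirichlet draws via normalized gammas (vectorized)."""
    g = rng.standard_gamma(concentration)
    # a zero row is possible only at absurdly small concentrations
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)
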