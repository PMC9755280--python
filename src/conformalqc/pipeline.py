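"""End-to-end study-replica pipeline on synthetic scores.

Chains simulation -> subject-aware split -> Mondrian calibration ->
prediction regions at each requested confidence -> evaluation tallies ->
calibration curve -> (for shifted scenarios) drift test and power curve,
writing every artifact plus a manifest of seeds and file hashes into a
run directory. Two runs with the same config and master seed produce
hash-identical artifacts.

Per-stage seeds are derived by hashing the master seed together with a
stable stage name, so adding a scenario never perturbs the random
streams of existing stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__
from .conformal import (ConfidenceSpec, MondrianCalibrator, SplitSpec,
                        calibrate, predict_regions, regions_to_frame,
                        split_train_calibration, true_label_p_values)
from .drift import drift_test, power_curve
from .evaluation import calibration_curve, point_prediction_tally, tally_regions
from .labels import LabelSet
from .synthetic import (ShiftSpec, SyntheticConfig, attach_subjects,
                        generate_table)
from .table import LabeledScoreTable

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from the master seed and a name."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class ScenarioConfig:
    name: str
    n_examples: int
    shift: Optional[ShiftSpec] = None


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``examples/demo_config.yaml``."""

    label_set: LabelSet
    out_dir: Path
    master_seed: int = 0
    n_train: int = 2000
    prevalence: Optional[tuple[float, ...]] = None
    discriminability: float = 1.0
    mode: str = "calibrated"
    biopsies_per_subject: int = 6
    calibration_fraction: float = 0.10
    confidence_specs: Sequence[ConfidenceSpec] = field(default_factory=list)
    scenarios: Sequence[ScenarioConfig] = field(default_factory=list)
    drift_mode: str = "labeled"
    drift_alpha: float = 0.05
    power_grid: tuple[int, ...] = (10, 25, 50, 100, 200)
    power_reps: int = 200
    power_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.prevalence is None:
            k = len(self.label_set)
            self.prevalence = tuple(np.full(k, 1.0 / k))
        if not self.confidence_specs:
            self.confidence_specs = [ConfidenceSpec.global_level(0.999, self.label_set)]
        errors = []
        for spec in self.confidence_specs:
            if not spec.covers(self.label_set):
                errors.append(f"confidence spec {spec.confidence} does not cover the label set")
        for sc in self.scenarios:
            if sc.shift is not None and sc.shift.kind == "prevalence_shift":
                if len(sc.shift.target_prevalence) != len(self.label_set):
                    errors.append(f"scenario {sc.name}: target_prevalence length mismatch")
        if errors:
            raise ValueError("invalid pipeline config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        label_set = LabelSet(tuple(raw["labels"]), ordinal=bool(raw.get("ordinal", False)))
        specs = []
        for item in raw.get("confidence_levels", [0.999]):
            if isinstance(item, dict):
                specs.append(ConfidenceSpec(item))
            else:
                specs.append(ConfidenceSpec.global_level(float(item), label_set))
        scenarios = []
        for name, sc in raw.get("scenarios", {}).items():
            shift = None
            if "shift" in sc and sc["shift"]:
                sh = dict(sc["shift"])
                if "target_prevalence" in sh and sh["target_prevalence"] is not None:
                    sh["target_prevalence"] = tuple(sh["target_prevalence"])
                shift = ShiftSpec(**sh)
            scenarios.append(ScenarioConfig(name=name, n_examples=int(sc["n"]), shift=shift))
        drift = raw.get("drift", {})
        power = raw.get("power", {})
        return cls(
            label_set=label_set,
            out_dir=Path(raw.get("out_dir", "runs/run")),
            master_seed=int(raw.get("master_seed", 0)),
            n_train=int(raw.get("n_train", 2000)),
            prevalence=tuple(raw["prevalence"]) if raw.get("prevalence") else None,
            discriminability=float(raw.get("discriminability", 1.0)),
            mode=raw.get("mode", "calibrated"),
            biopsies_per_subject=int(raw.get("biopsies_per_subject", 6)),
            calibration_fraction=float(raw.get("calibration_fraction", 0.10)),
            confidence_specs=specs,
            scenarios=scenarios,
            drift_mode=drift.get("mode", "labeled"),
            drift_alpha=float(drift.get("alpha", 0.05)),
            power_grid=tuple(power.get("grid", (10, 25, 50, 100, 200))),
            power_reps=int(power.get("n_reps", 200)),
            power_threshold=float(power.get("threshold", 0.80)),
        )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save_csv(df, name):
        path = out / name
        df.to_csv(path, index=False, float_format="%.12g")
        files.append(path)

    def save_json(obj, name):
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
        files.append(path)

    # -- training data, split, calibration --------------------------------
    train_cfg = SyntheticConfig(
        label_set=config.label_set, n_examples=config.n_train,
        prevalence=config.prevalence, discriminability=config.discriminability,
        mode=config.mode, seed=derive_seed(config.master_seed, "train"),
        dataset_tag="training")
    train = attach_subjects(generate_table(train_cfg), config.biopsies_per_subject)
    train.write_csv(out / "training_scores.csv")
    files.append(out / "training_scores.csv")

    split = SplitSpec(calibration_fraction=config.calibration_fraction,
                      seed=derive_seed(config.master_seed, "split"))
    _, cal_table = split_train_calibration(train, split)
    calibrator = calibrate(cal_table)
    calibrator.to_json(out / "calibrator.json")
    files.append(out / "calibrator.json")
    logger.info("calibrated on %d rows; class counts %s",
                len(cal_table), calibrator.class_counts)

    # -- scenarios ---------------------------------------------------------
    for sc in config.scenarios:
        tag = sc.name
        sc_cfg = SyntheticConfig(
            label_set=config.label_set, n_examples=sc.n_examples,
            prevalence=config.prevalence, discriminability=config.discriminability,
            mode=config.mode, shift=sc.shift,
            seed=derive_seed(config.master_seed, f"scenario:{tag}"),
            dataset_tag=tag)
        table = generate_table(sc_cfg)
        save_csv(table.df, f"{tag}_scores.csv")

        for spec in config.confidence_specs:
            suffix = _spec_slug(spec)
            regions = predict_regions(
                calibrator, table, spec,
                seed=derive_seed(config.master_seed, f"regions:{tag}:{suffix}"))
            save_csv(regions_to_frame(regions, config.label_set),
                     f"{tag}_regions_{suffix}.csv")
            report = tally_regions(regions, table.true_labels, config.label_set)
            save_csv(report.to_long_frame(dataset_tag=tag), f"{tag}_tally_{suffix}.csv")

        save_csv(point_prediction_tally(table).reset_index(names="class"),
                 f"{tag}_point_predictions.csv")

        pvals = true_label_p_values(
            calibrator, table, smoothed=True,
            seed=derive_seed(config.master_seed, f"curve:{tag}"))
        save_csv(calibration_curve(pvals).to_frame(), f"{tag}_calibration_curve.csv")

        if sc.shift is not None:
            result = drift_test(calibrator, table, mode=config.drift_mode,
                                alpha=config.drift_alpha)
            save_json(result.to_dict(), f"{tag}_drift.json")
            grid = tuple(n for n in config.power_grid if n <= len(table))
            if grid:
                curve = power_curve(
                    calibrator, table, grid, n_reps=config.power_reps,
                    alpha=config.drift_alpha, power_threshold=config.power_threshold,
                    seed=derive_seed(config.master_seed, f"power:{tag}"),
                    mode=config.drift_mode)
                save_csv(curve.to_frame(), f"{tag}_power.csv")
                save_json({"n_required": curve.n_required,
                           "power_threshold": config.power_threshold},
                          f"{tag}_power_summary.json")

    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "labels": list(config.label_set.labels),
        "scenarios": [sc.name for sc in config.scenarios],
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("run complete: %d artifacts in %s", len(files), out)
    return out


def _spec_slug(spec: ConfidenceSpec) -> str:
    vals = sorted(set(spec.confidence.values()))
    if len(vals) == 1:
        return f"c{vals[0] * 1000:.0f}"
    return "classwise_" + "_".join(f"{v * 1000:.0f}" for v in vals)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
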