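# Demo pipeline configuration: binary cancer detection on synthetic scores.
#
# labels        class names, in probability-column order
# master_seed   single seed; per-stage seeds are derived from it
# n_train       labeled rows generated for the training pool (split 90/10
#               into proper training and calibration, by subject)
# prevalence    class frequencies (raw counts accepted, normalized internally)
# mode          calibrated | class_conditional (see docs/methods.md)
# confidence_levels
#               each entry is a global level or a per-class map
# scenarios     test sets to generate; a scenario with a `shift` entry also
#               gets a drift test and a power curve
labels: [benign, cancer]
ordinal: false
master_seed: 7
n_train: 2000
prevalence: [0.55, 0.45]
discriminability: 1.0
mode: calibrated
biopsies_per_subject: 6
calibration_fraction: 0.10
confidence_levels:
  - 0.999
  - 0.80
scenarios:
  baseline:
    n: 794
  external_scanner:
    n: 449
    shift: {kind: temperature, magnitude: 2.0}
  atypical_tissue:
    n: 179
    shift: {kind: contamination, magnitude: 0.8}
drift:
  mode: labeled
  alpha: 0.05
power:
  grid: [10, 25, 50, 100, 200]
  n_reps: 100
  threshold: 0.8
out_dir: runs/demo
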