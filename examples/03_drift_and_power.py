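"""Detecting a deployment shift and sizing the monitoring sample.

Calibrates on baseline synthetic scores, distorts a test set with a
temperature shift (standing in for a scanner/laboratory change), runs
the KS drift test, and estimates how many deployment observations the
test needs to detect the shift with 80% power.
"""

from conformalqc import (BINARY, ShiftSpec, SyntheticConfig, apply_shift,
                         calibrate, drift_test, generate_table, power_curve)

cal_table = generate_table(SyntheticConfig(BINARY, 1000, (0.5, 0.5), seed=3))
calibrator = calibrate(cal_table)

test = generate_table(SyntheticConfig(BINARY, 449, (0.5, 0.5), seed=4,
                                      dataset_tag="external"))
shifted = apply_shift(test, ShiftSpec("temperature", 2.0), seed=5)

result = drift_test(calibrator, shifted, mode="labeled")
print(f"KS statistic {result.ks_statistic:.3f}, p = {result.p_value:.3g} "
      f"-> {'shift detected' if result.significant else 'no shift detected'} "
      f"at alpha = {result.alpha}")

pool = apply_shift(
    generate_table(SyntheticConfig(BINARY, 2000, (0.5, 0.5), seed=6,
                                   dataset_tag="pool")),
    ShiftSpec("temperature", 2.0), seed=7)
curve = power_curve(calibrator, pool, [10, 25, 50, 100, 200], n_reps=400, seed=8)
for n, p in zip(curve.n_grid, curve.power):
    print(f"  n = {n:4d}: estimated power {p:.2f}")
print(f"observations needed for >= {curve.power_threshold:.0%} power: "
      f"{curve.n_required}")
print()
print("Power is the probability that a KS test on n deployment predictions")
print("flags the distorted score distribution at the 5% level; n_required is")
print("the smallest monitoring sample on the grid reaching the 80% threshold.")
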