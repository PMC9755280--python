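"""Validity diagnostics: error bound and calibration-curve diagonality.

On exchangeable (perfectly calibrated) synthetic scores the conformal
guarantee holds by construction: the marginal error rate at 99.9%
confidence stays below 0.1%, and the curve of observed error versus
significance level hugs the diagonal.
"""

from conformalqc import (marginal_validity_experiment,
                         pvalue_uniformity_experiment)

validity = marginal_validity_experiment(seed=1, n_seeds=5)
print(f"error rate at 99.9% confidence: {validity['error_rate_percent']:.4f}% "
      f"(bound {validity['bound_percent']:.1f}%, "
      f"{validity['n_errors']} errors in {validity['n_total']:,} predictions)")

uniformity = pvalue_uniformity_experiment(seed=1)
print(f"max |observed error - eps| over the significance grid: "
      f"{uniformity['max_deviation']:.4f} "
      f"(three-sigma uniformity bound {uniformity['bound']:.4f}, "
      f"n = {uniformity['n_test']:,})")
print()
print("The first number is the fraction of test biopsies whose true label was")
print("excluded from the region - the quantity the conformal predictor bounds.")
print("The second says smoothed true-label p-values are uniform: the observed")
print("error matches the tolerated error at every significance level.")
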