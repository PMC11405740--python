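"""Two-group comparison with the normality-gated test router.

Both groups passing Shapiro-Wilk get Student's t with Cohen's d and a CI;
otherwise a Mann-Whitney U with rank-biserial correlation and the
common-language effect size.  All effects read as group 1 relative to
group 0.
"""

import numpy as np

from pupilclust import compare_groups, chi_square_2x2

rng = np.random.default_rng(1)

normal = compare_groups(rng.normal(850, 60, 33), rng.normal(770, 60, 37),
                        variable="mean_nn_ms")
print(f"normal data -> {normal.test}: t = {normal.statistic:.2f}, "
      f"p = {normal.p_value:.2g}, d = {normal.d:.2f} "
      f"[{normal.d_ci_low:.2f}, {normal.d_ci_high:.2f}]")

skewed = compare_groups(rng.exponential(1.0, 33) ** 2, rng.exponential(1.6, 37) ** 2,
                        variable="blink_count")
print(f"skewed data -> {skewed.test}: U = {skewed.statistic:.0f}, "
      f"p = {skewed.p_value:.2g}, RBC = {skewed.rbc:.2f}, CLES = {skewed.cles:.2f}")

chi2, p = chi_square_2x2([[15, 18], [8, 29]])
print(f"smoking 2x2 -> chi2 = {chi2:.3f}, p = {p:.3f}")
# CLES is the probability that a random group-1 value exceeds a random
# group-0 value; RBC = 2*CLES - 1 maps it onto [-1, 1].
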