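"""Timepoint comparison with the package's statistical conventions.

Simulates per-coverslip GFAP+ percentages for four culture ages (DIV 7 to 28,
nine coverslips each, rising means), summarizes them as mean +/- SEM, and
tests the differences by one-way ANOVA with Bonferroni-adjusted pairwise
comparisons, reporting significance stars (* p<0.05, ** p<0.01, *** p<0.001).
"""

import numpy as np

from astroquant import anova_bonferroni, mean_sem

rng = np.random.default_rng(9)
true_means = {"DIV7": 20.0, "DIV14": 53.0, "DIV21": 65.0, "DIV28": 74.0}
groups = {div: rng.normal(mu, 12.0, size=9) for div, mu in true_means.items()}

for div, values in groups.items():
    mean, sem, n = mean_sem(values)
    print(f"{div:>6}: {mean:5.2f} +/- {sem:4.2f} %  (n = {n})")

result = anova_bonferroni(groups)
print(f"\nANOVA omnibus: F = {result.statistic:.2f}, "
      f"p = {result.p_value:.2e} {result.stars}")
for pw in result.pairwise:
    print(f"  {pw['group_a']:>6} vs {pw['group_b']:<6} "
          f"p_adj = {pw['p_adjusted']:.4g} {pw['stars']}")
print()
print("Bonferroni multiplies each raw pairwise p by the number of pairs (6),")
print("capped at 1; stars derive from the adjusted p-values.")
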