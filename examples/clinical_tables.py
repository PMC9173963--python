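"""Contingency statistics for a two-arm wound-healing comparison.

Recovers integer counts from percentages printed to two decimals, tests
healing-grade homogeneity between arms (chi-square), tests a small
secondary-suture table exactly (Fisher), and summarizes a detector's
confusion matrix.
"""

from retinexmed import (
    ConfusionMatrix,
    chi_square_homogeneity,
    counts_from_percentages,
    diagnostic_performance,
    fisher_exact_2x2,
)

drain = counts_from_percentages([88.57, 8.57, 2.86], 35)
no_drain = counts_from_percentages([45.71, 40.00, 14.29], 35)
print(f"healing grades I/II/III, drainage arm   : {drain}")
print(f"healing grades I/II/III, no-drainage arm: {no_drain}")

stat, df, p = chi_square_homogeneity([drain, no_drain])
print(f"chi-square = {stat:.2f}, df = {df}, p = {p:.2e} "
      f"-> healing-grade distributions differ (p < 0.05)")

p_fisher = fisher_exact_2x2([[2, 33], [4, 31]])
print(f"secondary sutures 2/35 vs 4/35: Fisher exact p = {p_fisher:.3f} "
      f"-> no significant difference (p > 0.05)")

sens, spec, acc = diagnostic_performance(ConfusionMatrix(tp=9, fp=0, tn=10, fn=1))
print(f"confusion tp=9 fp=0 tn=10 fn=1: sensitivity {sens}%, "
      f"specificity {spec}%, accuracy {acc}%")
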