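"""Analyse the packaged London air-sampling counts.

430 Penicillium isolates scored as P. chrysogenum / P. rubens / other across
five location groups: species percentages, the pairwise-location chi-square
matrix for four ratio comparisons, mating-type goodness-of-fit, and the
inhaled-conidia exposure estimator.
"""

from chrysodiag import (
    chi2_goodness_of_fit,
    exposure_rate,
    proportion_table,
    ratio_comparison_matrix,
)
from chrysodiag.datasets import load_group_counts
from chrysodiag.io import CountTable

counts = load_group_counts()
print("counts per location group:")
print(counts.to_dataframe())

total = CountTable(["all"], counts.col_labels, counts.col_totals()[None, :])
pct = proportion_table(total)
print(
    f"\nheadline: {pct.loc['all', 'chrysogenum']} % chrysogenum, "
    f"{pct.loc['all', 'rubens']} % rubens of {counts.grand_total()} isolates"
)

mats = ratio_comparison_matrix(counts)
print("\nchrysogenum:rubens ratio, pairwise-location chi-square p-values:")
print(mats["C:R"].round(3).fillna(""))
print("\nrubens:other ratio (small p = the two locations differ):")
print(mats["R:O"].round(3).fillna(""))

for label, obs in (("chrysogenum", [13, 11]), ("rubens", [8, 14])):
    res = chi2_goodness_of_fit(obs)
    print(f"\nmating types {label} {obs}: chi2={res.statistic:.3f}, p={res.p_value:.2f}")
print("(p > 0.05: a 1:1 mating-type ratio cannot be rejected — consistent with recombination)")

rate = exposure_rate(53, 500)
print(f"\n53 colonies from 500 l of air -> {rate:.3f} viable conidia inhaled per minute")
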