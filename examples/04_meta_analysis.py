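"""Combine per-cohort evidence with Fisher's combined probability test.

Individually non-significant interaction p-values from several cohorts can
combine to a significant meta-analysis result: -2 sum(ln p) ~ chi-square
with 2k degrees of freedom.
"""

from dnamesig import chisq_test, fisher_combined, meta_interaction

# four cohorts' univariate interaction p-values, only one below 0.05
per_cohort = [("COHORT-A", 0.017), ("COHORT-B", 0.084), ("COHORT-C", 0.33), ("COHORT-D", 0.063)]
combined = meta_interaction(per_cohort, stratum="univariate")
print(f"combined over {len(per_cohort)} cohorts: chi2 {combined.statistic:.2f} "
      f"on {combined.df} df, p {combined.p:.4f}")
# 2 x 4 = 8 df; the combined p is far below any individual input

# a single p-value round-trips through the identity -2 ln p ~ chi2(2)
print(f"single-p identity: {fisher_combined([0.05]).p:.6f}")

# contingency association, e.g. marker status vs a clinical feature
stat, df, p = chisq_test([[24, 15], [38, 57]])
print(f"2x2 chi-square: statistic {stat:.2f}, df {df}, p {p:.3f}")
# Pearson chi-square without continuity correction, the convention under
# which published clinicopathological tables reproduce
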