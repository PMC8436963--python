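"""Cohort-level statistics: correlations, PCA, variation, asymmetry.

Generates a synthetic cohort with replicate photographs, measures it, and
prints the highlights of the downstream statistical report.
"""

import logging

logging.basicConfig(level=logging.WARNING)

from pattquant.pipeline import measure_regions, stats_report
from pattquant.synth import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(n_geckos=10, n_replicates=4, seed=2))
indices = measure_regions(cohort.images)
report = stats_report(indices, n_perm=500, seed=2)

frac = report["pca"]["explained_fraction"]
print("PCA: first three components explain "
      f"{frac[0]:.0%} / {frac[1]:.0%} / {frac[2]:.0%} of the variance")

cov = report["coefficient_of_variation"]["ALL"]
top = sorted(cov.items(), key=lambda kv: -(kv[1] or 0))[:3]
print("most variable indices (coefficient of variation):",
      ", ".join(f"{k} = {v:.2f}" for k, v in top))

anova = report.get("anova_front_legs", {})
if "SA" in anova:
    a = anova["SA"]
    print(f"front-leg asymmetry ANOVA for SA: F_interaction = "
          f"{a['F_interaction']:.1f} (p = {a['p_interaction']:.3g})")

h = report["hierarchy"]
print("patterning hierarchy violations:",
      h["legs_imply_trunk"]["violations"], "(legs->trunk),",
      h["trunk_implies_head_and_tail"]["violations"], "(trunk->head,tail)")
# The ANOVA interaction term compares left-right (fluctuating) asymmetry
# against replicate measurement error; a large F means the asymmetry is
# real biology, not photography noise.
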