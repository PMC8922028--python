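"""Integrated Biomarker Response: scores, star geometry, factorial ANOVA.

Computes per-species IBR values from a simulated biomarker matrix, shows
the star-plot decomposition for one condition, and tests temperature and
predation effects on the published 34 IBR values.
"""

import coralstress as cs

config = cs.DesignConfig(seed=1)
fragments = cs.simulate_condition_outcomes(
    cs.generate_design(config), seed=config.rng("condition")
)
matrix = cs.simulate_biomarkers(
    fragments, seed=config.rng("biomarkers"), on_shortfall="all"
)

ibr, scores = cs.ibr_table(matrix, return_scores=True)
print("IBR per surviving (species, temperature, predation) cell:")
print(ibr.round(3).head(8).to_string(index=False))
print(f"... {len(ibr)} cells total")

# star-plot decomposition for one condition
ss = scores["Acropora tenuis"]
cond = ss.score.index[0]
res = cs.star_area(ss.score.loc[cond].to_numpy(), species="Acropora tenuis",
                   condition=cond)
print(f"\nA. tenuis {int(cond[0])} degC, {cond[1]}: scores {res.scores.round(3)}, "
      f"segment areas {res.areas.round(3)}, IBR = {res.value:.3f}")
print(res.vertices().round(3).to_string(index=False))

print("\nfactorial ANOVA on the 34 published IBR values (Type III):")
for term, r in cs.ibr_anova(cs.datasets.ibr_values()).items():
    print(f"  {term:25s} F = {r.statistic:.3f}  p = {r.pvalue:.3f}")

# Each IBR is the summed area of the star polygon over the three biomarker
# scores (alpha = 120 degrees for n = 3).  On the published values neither
# temperature (F = 0.04) nor predation (F = 2.06) is significant.
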