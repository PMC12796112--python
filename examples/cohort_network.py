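"""Co-expression network of a simulated brain cohort.

Generates a CTL/AD/PSP cohort matrix with four planted co-expression modules
(one linked to Braak stage and AD diagnosis), normalizes it with the
GIS-anchored median polish, regresses out age/sex/PMI, detects signed-bicor
modules and correlates module eigengenes with the traits.
"""

import turbomap as tm

cfg = tm.CohortSimConfig(seed=7, trait_effects={"braak": [0.8, 0, 0, 0],
                                                "dx_AD": [1.0, 0, 0, 0]})
matrix, design, traits, truth = tm.simulate_cohort(cfg)
print(f"simulated {matrix.n_proteins} proteins x {matrix.n_samples} samples "
      f"({design.table['is_gis'].sum()} GIS anchors)")

normalized = tm.median_polish_normalize(matrix, design)
regressed = tm.bootstrap_regress(
    normalized, design,
    tm.RegressSpec(covariates=("age", "sex", "pmi"), protected=("group",),
                   n_boot=200, seed=7))

model = tm.detect_modules(regressed, tm.CoexprConfig(), design=design)
sizes = {m: len(model.members(m)) for m in model.modules()}
print("detected modules (planted sizes 150/100/60/30):", sizes)

mt = tm.module_trait_correlation(model, traits)
braak = mt[mt["trait"] == "braak"].set_index("module")
print("module-trait bicor with Braak stage:")
for mod, row in braak.iterrows():
    print(f"  {mod}: r = {row['r']:+.2f} {row['stars']}")
print("the module carrying the planted Braak effect shows the strongest "
      "positive correlation; planted-null modules sit near zero. A small "
      "extra module beyond the four planted ones can appear: median "
      "normalization leaves a faint mirror of the dominant module in every "
      "protein, and chance branches aligned with it can pass the size floor.")

hubs = model.kme.loc[model.members("M1"), "M1"].nlargest(3)
print("top M1 hubs by kME:", {p: round(k, 3) for p, k in hubs.items()})
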