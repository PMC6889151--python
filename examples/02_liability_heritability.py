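"""Liability-scale SNP heritability from a reported Nagelkerke delta-R2.

Reproduces the desk calculation for a childhood brain-tumor cohort:
delta-R2 = 0.012 from 245 cases / 489 controls, population prevalence
0.04%.
"""

import grskit as gk

result = gk.full_chain(
    r2_nagelkerke=0.012,
    prevalence_K=0.0004,
    case_fraction_P=245 / 734,
)
print(f"Nagelkerke dR2 in     : {result.r2_nagelkerke_in}")
print(f"observed-scale R2     : {result.r2_observed:.6f}")
print(f"liability threshold t : {result.threshold_t:.4f}")
print(f"density at threshold  : {result.density_z:.6f}")
print(f"h2 (liability scale)  : {result.h2_liability:.5f}  -> rounds to "
      f"{round(result.h2_liability, 3)}")

# The transform undoes the Nagelkerke rescaling (back to the Cox-Snell
# observed scale), then maps observed-scale variance explained onto the
# latent liability scale, correcting for the case-enriched sampling
# (34% cases in the sample vs 0.04% in the population).
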