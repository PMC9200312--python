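"""Liability-scale heritability of a late-onset disease across assumed
population prevalences, with and without correction for undetected cases.

Calibrates the observed-scale heritability so the clinical curve gives 6.95%
at a 5% population prevalence (sample prevalence 0.344, as in an ascertained
case-control GWAS of Alzheimer's disease), then sweeps the assumed prevalence.
The biological curve treats each prevalence as the rate of underlying disease
pathology and corrects for the biological cases hiding among clinically
screened controls (false-classification rate = K - 0.0285).
"""

import numpy as np

from proxymeta import LiabilityParams, liability_to_obs, prevalence_sweep

h2_obs = liability_to_obs(0.0695, LiabilityParams(p_sample=0.344, p_population=0.05))
grid = np.arange(0.03, 0.31, 0.03)

clinical = prevalence_sweep(h2_obs, 0.344, grid, mode="clinical")
biological = prevalence_sweep(h2_obs, 0.344, grid, mode="biological")

print(f"{'prevalence':>10} {'clinical h2 (%)':>16} {'biological h2 (%)':>18}")
for k, hc, hb in zip(grid, clinical["h2_liability"], biological["h2_liability"]):
    print(f"{k:>10.2f} {100 * hc:>16.2f} {100 * hb:>18.2f}")

print(
    "\nEach row converts the same case-control contrast under a different "
    "assumed prevalence; the biological column rises faster because a higher "
    "pathology prevalence implies more contaminated controls."
)
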