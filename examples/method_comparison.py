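"""Compare heritability recovery of the relaxed model against conventional
GWAS+GWAX meta-analysis across simulation replicates.

Uses a small number of replicates of the binary condition with the empirically
motivated attenuation coefficients.  %BE is the mean percent deviation of the
estimate from the simulated truth; the uncorrected approach is severely
downwardly biased, the standard (x2 / N/4) correction helps, and the relaxed
model, which estimates the attenuation from the data, is essentially unbiased.
"""

from proxymeta import condition_registry, run_study

registry = condition_registry()
summary = run_study(
    {"cond3_binary": registry["cond3_binary"]},
    methods=("uncorrected", "standard_corrected", "standard_liability", "relaxed"),
    reps=20,
    m=50_000,
    seed=3,
)
cols = ["method", "truth", "mean_estimate", "sd_estimate", "mean_se", "pct_bias_abs"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(
    "\npct_bias_abs is |%BE| against the simulated liability-scale "
    "heritability of 0.073; the relaxed model estimates the proxy attenuation "
    "instead of assuming the standard factor of one half."
)
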