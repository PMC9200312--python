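# Methods

## The relaxed proxy-GWAS factor model

A direct case-control GWAS and k−1 proxy (family-history) GWAX of the same
disease share genetic signal through a latent factor F:

    Y = Λ F + U,    implied genetic covariance  Σ(θ) = Λ Ψ Λ' + Θ,

where Λ holds the loadings (the proxy *attenuation coefficients*), Ψ = σ²_F
the factor variance and Θ = diag(σ²_u) residual genetic variances that are
mutually uncorrelated and independent of F.  The standard first-degree proxy
model is the special case λ_proxy = 0.5, Θ = 0.  Two identifications are
offered: λ_direct = 1 (default; σ²_F is the SNP heritability of the
meta-analysed phenotype on the direct-GWAS scale) and σ²_F = 1 (the squared
direct loading plays that role).  Both are just-identified for k = 3 and give
equivalent fits.  For k = 1 the residual variance cannot be separated from the
factor variance, so θ is fixed at 0 and the model degenerates to a
passthrough.

## Stage 1: multivariate LD-score regression

For traits i, k with per-SNP association statistics z(j),

    E[z_i(j) z_k(j)] = sqrt(N_i N_k) σ_g,ik ℓ(j)/M + δ_ik(1 + a_i) + ρ_ik N_s,ik/sqrt(N_i N_k),

with ℓ(j) the LD score, M the reference-panel SNP count, a confounding
inflation and the last term sample overlap.  Each of the k(k+1)/2 regressions
of z_i z_k on ℓ uses standard LDSC weights — an over-counting factor
1/max(ℓ,1) times the inverse squared conditional mean of the product — with
two weight iterations seeded by a 1/ℓ-weighted pass.  Slopes convert to
genetic covariances via M / sqrt(mean N_i · mean N_k); intercepts are always
estimated freely.  M is entered as the pre-exclusion reference count
(estimates then keep their usual genome-wide interpretation after MHC/APOE
removal); supplying a different M rescales estimates exactly proportionally.
The number of weight iterations is configurable (one-step weighting is
available for sensitivity checks), and an optional maximum-chi-square filter
(`chisq_max`, off by default) can drop extreme statistics before the
regressions — removing the APOE block at munging plays the same role and is
the default route.

Standard errors and the full sampling covariance V of vech(S) come from a
delete-one block jackknife over 200 contiguous genomic blocks (configurable).
All pairs share one block partition, so V captures cross-element dependence
from shared SNPs and overlapping samples.  For binary traits each element of
S is converted to the liability scale by the square-root product of the
per-trait ascertainment factors K²(1−K)²/(v(1−v)φ(t)²); V is rescaled from
the same pseudovalues.  No maximum-χ² SNP filter is applied by default
because the APOE block is removed instead; a threshold can be imposed
upstream at munging.

## Stage 2: DWLS fit with sandwich standard errors

Free parameters minimise (s − σ(θ))' D⁻¹ (s − σ(θ)) with s = vech(S) and
D = diag(V); V is first projected to the nearest positive semidefinite matrix
by eigenvalue flooring at 1e−10 of its largest eigenvalue.  The optimizer is
a trust-region least-squares routine with the analytic Jacobian of σ(θ); on
failure up to five random restarts perturb the closed-form start values, and
a non-converged result is returned flagged.  Parameter covariance is the
sandwich (J'D⁻¹J)⁻¹ J'D⁻¹ V D⁻¹ J (J'D⁻¹J)⁻¹; p-values are two-sided normal.

Box constraints keep estimates in the scientifically meaningful region:
θ ∈ [0, 1] (residual variances of standardized traits), |σ²_F| ≤ 1, |λ| ≤ 10.
The lower θ bound matters: without any bounds the just-identified three-trait
model is unidentified in the no-shared-signal limit (the exact solution
behaves like S12·S13/S23, which is unbounded as S23 → 0), and the σ²_F bound
is what keeps null-simulation estimates finite.  σ²_F itself may go negative
so that null simulations stay mean-unbiased.  Because a true θ = 0 sits on
the boundary, the bounded estimator's replicate-to-replicate spread is
smaller than the sandwich SE predicts — inference is then conservative, which
is the desired direction for a null test; with the boundary released
(`theta_lower=None`, a diagnostics toggle) the sandwich SEs are calibrated
(replicate SD/mean SE ≈ 0.93–0.99 in our simulations).

Model fit for over-identified specifications uses the residual-based
statistic r' P (P'VP)⁻¹ P'r, where r = s − σ(θ̂) and P is an orthonormal
basis of the orthogonal complement of the Jacobian column space; it is
asymptotically χ² on the model degrees of freedom, and nested models are
compared by its difference.  Named constraints implement the standard-model
variants: `lambda=0.5` (all proxy loadings at one half) and `theta_direct=0`
(the direct GWAS carries no ancillary genetic signal).

## Per-SNP meta-analysis and Q_SNP

Summary statistics are first standardized per trait: the per-allele effect on
a unit-variance (liability) outcome is recovered from the association Z as
b = z / sqrt(2·maf(1−maf)·N_w), with N_w = 4v(1−v)n for binary traits and n
for continuous ones, and SE = 1/sqrt(2·maf(1−maf)·N_w).  When a trait's
univariate LDSC intercept exceeds 1, SEs are inflated by its square root
(genomic control).  Multiplying by the SNP variance 2·maf(1−maf) turns these
into SNP–trait genetic covariances, which expand S by one row/column; the
expanded sampling covariance uses the per-trait SEs with cross-trait LDSC
intercepts supplying the overlap-induced correlations.

With Λ and Θ fixed at their genome-wide estimates, the SNP's effect on F
(F = γx + e) has the closed-form DWLS solution

    γ̂ = Σ_i λ_i b_i / se_i²  /  Σ_i λ_i² / se_i²,

in per-effect-allele units on the direct-GWAS scale, with a sandwich SE under
the intercept-correlated SNP block.  Q_SNP is the generalised-least-squares
discrepancy difference between this common-pathway model and a saturated
model with free per-trait SNP effects; under proportional effects it is
exactly zero and under homogeneity it calibrates to χ² with k−1 degrees of
freedom (a df = 1 reporting mode is available, since single-degree summaries
are common in applied reports).  Estimated cross-trait intercepts enter the
SNP block only when they exceed twice their jackknife SE: genuine overlap
passes this gate easily, while at reduced reference-panel sizes raw intercept
noise would otherwise distort the weights and the Q calibration.  When an
extreme-effect SNP would make the expanded S non-positive-definite (APOE
scale signals), its working MAF is shrunk by bisection until the Schur
condition 2·maf(1−maf)·b'S⁻¹b < 1 holds; per-allele outputs are unaffected
because the SNP variance cancels from γ̂, and the SNP is flagged.  The
effective N reported with the output is N_eff,direct + Σ λ̂²_proxy N_eff,proxy,
with per-cohort N_eff = 4v(1−v)n, so downstream LDSC should pair it with a
sample prevalence of 0.5.

## Conventional baselines

The inverse-variance route multiplies proxy betas and SEs by a correction
factor (2 under the standard model, 1/λ̂ empirically) before pooling; the
Z-statistic route divides each study's N by the squared factor (4) — the two
are algebraically identical when SEs follow the 1/sqrt(N) information scaling.
The *uncorrected* pipeline deliberately mirrors naive practice: raw Z, raw
summed N, liability conversion at the pooled sample prevalence.  The
*standard+liability* variant weights per-cohort effective Ns by the assumed
λ² (N_eff,direct + .25 N_eff,mat + .25 N_eff,pat) and converts at sample
prevalence 0.5, removing ascertainment-mixture bias while retaining the fixed
λ = .5 assumption.

## The simulator and what it does not emulate

Summary statistics are drawn per SNP from a multivariate normal with the LDSC
covariance above — the implied population Σ comes from the factor model, the
LD scores from a right-skewed gamma (mean 110, shape 2, floored at 1, the
shape of European reference panels), with the LD table's own M as
denominator.  For binary conditions the liability-scale Σ is converted to the
observed scale per trait before the draw, so the full pipeline (conversion
included) is exercised end to end.  Defaults mirror the empirical cohorts:
N = (63,926; 288,676; 260,279), sample prevalences (0.344, 0.096, 0.055),
population prevalence 5%, no overlap, no confounding; the registry holds the
three attenuation regimes λ_proxy ∈ {(.5,.5), (.25,.25), (.463,.366)}, each
continuous and binary, plus a null condition whose genetic covariance is
diagonal (.10/.025/.025) so the factor heritability is truly zero.  The true
factor heritability defaults to 0.073 (the direct-GWAS liability-scale
estimate at 5% prevalence); evaluation metrics are bias-relative, so
conclusions are insensitive to this anchor.  Draws are independent across
SNPs: LD-score-level structure is emulated but the LD matrix is not, so the
output supports LDSC-style analyses and per-variant meta-analysis but not
clumping, lead-SNP definition or LD-matrix-based heritability methods — and
passing tests say nothing about those uses.  A separate single-SNP generator
draws observed per-trait betas around γΛ with sampling variance
(1 − 2maf(1−maf)b²)/(2maf(1−maf)·n) (an extra v(1−v) in the denominator for
ascertained binary traits), default γ = 0.068 at MAF = 0.305, an
APOE-adjacent genome-wide-significant scale.

## Liability conversions

For an ascertained sample with case fraction P_s and population prevalence K,
h²_liability = h²_observed · K²(1−K)²/(P_s(1−P_s)(1−FCR)²φ(t)²), t = Φ⁻¹(1−K).
FCR is the false-classification rate among controls; FCR = 0 recovers the
classical transformation, and for a disease whose biological substrate
outruns clinical diagnosis FCR = K_bio − K_clinical with K_clinical fixed
(default 0.0285, the age-specific clinical rate at the mean control age of
72.4 years).  Negative observed-scale estimates propagate un-truncated so
simulation nulls stay unbiased.  φ and Φ⁻¹ are double-precision scipy
routines.

## Evaluation harness

`run_study` crosses registry conditions with four methods (uncorrected,
standard-corrected, standard+liability, relaxed), with replicate r of
condition c drawn from RNG stream [seed, c, r] for bit-reproducibility.
Percent bias error is 100·mean(estimate/truth − 1); at truth 0 the mean
estimate is reported instead.  Type-I error counts use the two-sided normal
p-value of σ̂²_F against its sandwich SE with θ bounded at zero, the
conservative default.  Default problem sizes in the shipped tests and the
acceptance script are 100,000 simulated SNPs for the null and
ceiling-recovery studies and 20,000 for the parameter-recovery and ordering
studies, with 100–200 replicates per cell — sizes at which Monte-Carlo error
on the reported summaries is well below the margins being asserted.

## Known limitations

- Attenuation is modelled as a single scalar per proxy source; heterogeneous
  attenuation across cohorts within one GWAX is absorbed into λ.
- The Q_SNP reference distribution assumes the genome-wide Λ, Θ are known;
  their sampling error is ignored per SNP (negligible at genome-wide SNP
  counts, not at toy sizes).
- The simulator's independence across SNPs understates the effective
  correlation of jackknife blocks relative to real LD; coverage results at
  small synthetic panels are slightly conservative.
- Liability conversions assume a strictly normal liability and that clinical
  cases are a random subset of biological cases; violations shift the
  biological curve by more than its SE at high assumed prevalence.
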