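"""Per-SNP multivariate meta-analysis on the factor model.

With the genome-wide loadings and residual variances fixed, each SNP's effect
``gamma`` on the latent factor F is the DWLS solution of the SNP-extended
model: the per-trait SNP-trait genetic covariances ``s_i = beta_i * 2maf(1-maf)``
are regressed on the fixed pattern ``u_i = lambda_i * 2maf(1-maf)``.  A
heterogeneity statistic Q_SNP contrasts this common-pathway restriction with a
saturated model that gives every trait its own SNP effect: it is the
generalised-least-squares discrepancy of the residuals under the SNP-block
sampling covariance (which carries cross-trait LDSC intercepts so overlap is
accounted for), asymptotically chi^2 with k-1 degrees of freedom when one
factor-mediated effect suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import GenCovStructure, vech_indices
from .sem import FactorModelFit
from .sumstats import CohortMeta, snp_variance, standardize_effects

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "MAF",
    "BETA", "SE", "Z", "P", "Q_SNP", "Q_DF", "Q_P", "NEFF",
]


@dataclass
class SnpResult:
    """Meta-analytic estimate for one SNP."""

    snp_id: str
    gamma: float
    se_gamma: float
    z: float
    p: float
    q_snp: float
    q_df: int
    q_p: float
    n_eff: float
    pd_adjusted: bool = False


def meta_neff(neff_per_trait, lambdas) -> float:
    """Effective N of the factor GWAS: ``sum_i Neff_i * lambda_i^2``.

    The direct GWAS (lambda = 1) contributes its full effective N; proxies
    contribute proportionally to their squared attenuation coefficients.
    """
    neff = np.asarray(neff_per_trait, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    return float(np.sum(neff * lam**2))


def expand_matrices(
    S_V: GenCovStructure, snp: list[tuple[float, float]], maf: float
):
    """Expand (S, V) with one SNP's covariances with every trait.

    ``snp`` holds per-trait ``(beta_std, se_std)`` on the standardized scale.
    The SNP occupies the first row/column: its variance ``2maf(1-maf)`` on the
    diagonal and ``beta_i * 2maf(1-maf)`` against each trait.  The SNP block
    of the expanded sampling covariance uses the per-trait SEs and the
    cross-trait LDSC intercepts, so overlap-induced dependence between the
    per-trait SNP estimates is retained; SNP-block x trait-block sampling
    covariances are set to zero (the genome-wide block is estimated from
    orders of magnitude more data than one SNP contributes).
    """
    k = S_V.k
    if len(snp) != k:
        raise ValueError("one (beta, se) pair per trait required")
    var = float(snp_variance(maf))
    betas = np.array([b for b, _ in snp], dtype=float)
    ses = np.array([s for _, s in snp], dtype=float)

    S_full = np.zeros((k + 1, k + 1))
    S_full[0, 0] = var
    S_full[1:, 0] = S_full[0, 1:] = betas * var
    S_full[1:, 1:] = S_V.S

    R = _intercept_correlation(S_V)
    idx = vech_indices(k + 1)
    q_full = len(idx)
    V_full = np.zeros((q_full, q_full))
    pos = {ij: a for a, ij in enumerate(idx)}
    # SNP-trait block
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            V_full[pos[(i, 0)], pos[(j, 0)]] = ses[i - 1] * ses[j - 1] * var**2 * R[i - 1, j - 1]
    # genome-wide block
    trait_idx = vech_indices(k)
    for a, (i, j) in enumerate(trait_idx):
        for b, (l, m_) in enumerate(trait_idx):
            V_full[pos[(i + 1, j + 1)], pos[(l + 1, m_ + 1)]] = S_V.V[a, b]
    return S_full, V_full


def _intercept_correlation(
    S_V: GenCovStructure, se_threshold: float = 0.0
) -> np.ndarray:
    """Cross-trait intercept matrix as a correlation-like matrix (unit diagonal).

    With ``se_threshold > 0`` an off-diagonal intercept is applied only when it
    exceeds that many of its jackknife SEs: genuine sample overlap produces
    intercepts far from zero relative to their SE, whereas at small reference
    panels the intercept noise would otherwise distort the SNP-block weights.
    """
    k = S_V.k
    out = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            val = S_V.intercepts[i, j]
            if se_threshold > 0 and S_V.intercept_ses is not None:
                if abs(val) <= se_threshold * S_V.intercept_ses[i, j]:
                    val = 0.0
            out[i, j] = np.clip(val, -0.99, 0.99)
    return out


def estimate_gamma(
    S_full: np.ndarray,
    V_full: np.ndarray,
    fixed: tuple[np.ndarray, np.ndarray],
) -> tuple[float, float]:
    """DWLS estimate of the SNP effect on F with Lambda, Theta fixed.

    Returns ``(gamma, se_gamma)`` in per-effect-allele units on the
    direct-GWAS scale.  Only the SNP-trait covariances inform gamma because
    every other model element is fixed at its genome-wide value.
    """
    lambdas, _ = fixed
    lambdas = np.asarray(lambdas, dtype=float)
    k = len(lambdas)
    var = S_full[0, 0]
    s = S_full[1:, 0]
    idx = vech_indices(k + 1)
    pos = {ij: a for a, ij in enumerate(idx)}
    Vb = np.array(
        [[V_full[pos[(i, 0)], pos[(j, 0)]] for j in range(1, k + 1)] for i in range(1, k + 1)]
    )
    d = np.diag(Vb)
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("singular SNP weight block")
    u = lambdas * var
    w = u / d
    denom = float(w @ u)
    gamma = float(w @ s) / denom
    se = float(np.sqrt(w @ Vb @ w)) / denom
    return gamma, se


def q_snp(
    S_full: np.ndarray,
    V_full: np.ndarray,
    fixed: tuple[np.ndarray, np.ndarray],
    q_df_mode: str = "k_minus_1",
) -> tuple[float, int, float]:
    """Heterogeneity of the SNP's per-trait effects around the factor pathway.

    The statistic is the GLS discrepancy difference between the common-pathway
    model (one gamma) and the saturated model (free per-trait SNP effects),
    computed under the SNP-block sampling covariance.  ``q_df_mode`` selects
    the reference distribution: ``"k_minus_1"`` (default) or ``"one"``.
    """
    lambdas, _ = fixed
    lambdas = np.asarray(lambdas, dtype=float)
    k = len(lambdas)
    var = S_full[0, 0]
    s = S_full[1:, 0]
    idx = vech_indices(k + 1)
    pos = {ij: a for a, ij in enumerate(idx)}
    Vb = np.array(
        [[V_full[pos[(i, 0)], pos[(j, 0)]] for j in range(1, k + 1)] for i in range(1, k + 1)]
    )
    u = lambdas * var
    Vi = np.linalg.inv(Vb)
    uu = float(u @ Vi @ u)
    q = float(s @ Vi @ s) - float(u @ Vi @ s) ** 2 / uu
    q = max(q, 0.0)
    df = 1 if q_df_mode == "one" else k - 1
    return q, df, float(stats.chi2.sf(q, df))


def _deflate_maf(betas, ses, maf, S, max_steps: int = 20):
    """Shrink the working MAF until the expanded S is positive definite.

    Very large effects (APOE scale) can make [var, c; c', S] non-PD; per the
    Schur complement this happens when ``2maf(1-maf) * b' S^-1 b >= 1``.
    Per-allele outputs are unaffected (the SNP variance cancels from the
    gamma estimator); the adjustment only concerns the covariance bookkeeping.
    """
    Sinv = np.linalg.inv(S)
    quad = float(betas @ Sinv @ betas)
    var = float(snp_variance(maf))
    if var * quad < 1.0 - 1e-9:
        return maf, False
    lo, hi = 0.0, maf
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        if mid <= 0:
            break
        if float(snp_variance(max(mid, 1e-9))) * quad < 1.0 - 1e-9:
            lo = mid
        else:
            hi = mid
    return max(lo, 1e-9), True


def run_multivariate_gwas(
    tables: list[pd.DataFrame],
    S_V: GenCovStructure,
    fit: FactorModelFit,
    cohorts: list[CohortMeta] | None = None,
    maf_min: float = 0.005,
    info_min: float = 0.6,
    q_df_mode: str = "k_minus_1",
    intercept_se_threshold: float = 2.0,
) -> pd.DataFrame:
    """Meta-analytic summary statistics for F across all SNPs shared by the traits.

    Tables must be standardized (``standardize_effects``); alternatively pass
    ``cohorts`` and standardization is applied here using the univariate LDSC
    intercepts from ``S_V``.  SNP-level QC drops variants with reference MAF
    below ``maf_min`` or INFO below ``info_min`` in any trait; SNPs missing
    from any trait are skipped and counted.  Output columns:
    ``SNP CHR BP A1 A2 MAF BETA SE Z P Q_SNP Q_DF Q_P NEFF``.
    """
    k = len(tables)
    if cohorts is not None:
        tables = [
            standardize_effects(t, c, ldsc_intercept=S_V.intercepts[i, i])
            for i, (t, c) in enumerate(zip(tables, cohorts))
        ]
    for t in tables:
        if not t.attrs.get("standardized"):
            raise ValueError("tables must be standardized (or pass cohorts)")

    base_cols = [c for c in ("SNP", "CHR", "BP", "A1", "A2", "MAF") if c in tables[0]]
    merged = tables[0][base_cols + ["BETA", "SE"]
                       + (["INFO"] if "INFO" in tables[0] else [])].rename(
        columns={"BETA": "BETA0", "SE": "SE0", "INFO": "INFO0"}
    )
    n_union = len(set().union(*[set(t["SNP"]) for t in tables]))
    for i in range(1, k):
        cols = {"BETA": f"BETA{i}", "SE": f"SE{i}"}
        use = ["SNP", "BETA", "SE"] + (["INFO"] if "INFO" in tables[i] else [])
        if "INFO" in tables[i]:
            cols["INFO"] = f"INFO{i}"
        merged = merged.merge(tables[i][use].rename(columns=cols), on="SNP", how="inner")
    n_missing = n_union - len(merged)
    if n_missing:
        logger.info("skipped %d SNPs absent from at least one trait", n_missing)

    qc = merged["MAF"] >= maf_min
    info_cols = [c for c in merged.columns if c.startswith("INFO")]
    for c in info_cols:
        qc &= merged[c].isna() | (merged[c] >= info_min)
    n_qc = int((~qc).sum())
    merged = merged[qc].reset_index(drop=True)

    lam = fit.lambdas
    betas = merged[[f"BETA{i}" for i in range(k)]].to_numpy(float)
    ses = merged[[f"SE{i}" for i in range(k)]].to_numpy(float)
    zmat = betas / ses

    R = _intercept_correlation(S_V, se_threshold=intercept_se_threshold)
    Rinv = np.linalg.inv(R)

    # gamma: diagonally weighted least squares (SNP variance cancels)
    w = lam[None, :] / ses**2
    denom = (w * lam[None, :]).sum(axis=1)
    gamma = (w * betas).sum(axis=1) / denom
    # sandwich SE under the intercept-correlated SNP block
    num = np.zeros(len(merged))
    for i in range(k):
        for j in range(k):
            num += w[:, i] * w[:, j] * ses[:, i] * ses[:, j] * R[i, j]
    se_gamma = np.sqrt(num) / denom
    zscore = gamma / se_gamma

    # Q_SNP via GLS with the full intercept-correlated block
    ut = lam[None, :] / ses  # u scaled by 1/(var*se)
    sVs = np.einsum("ni,ij,nj->n", zmat, Rinv, zmat)
    uVs = np.einsum("ni,ij,nj->n", ut, Rinv, zmat)
    uVu = np.einsum("ni,ij,nj->n", ut, Rinv, ut)
    q = np.maximum(sVs - uVs**2 / uVu, 0.0)
    q_df = 1 if q_df_mode == "one" else k - 1
    q_pv = stats.chi2.sf(q, q_df)

    # PD bookkeeping for extreme effects
    Sinv = np.linalg.inv(S_V.S)
    quad = np.einsum("ni,ij,nj->n", betas, Sinv, betas)
    var = 2.0 * merged["MAF"].to_numpy() * (1.0 - merged["MAF"].to_numpy())
    pd_flag = var * quad >= 1.0 - 1e-9

    neff_traits = np.median(1.0 / (ses**2 * var[:, None]), axis=0)
    n_eff = meta_neff(neff_traits, lam)

    log10p = (np.log(2.0) + stats.norm.logsf(np.abs(zscore))) / np.log(10.0)
    out = pd.DataFrame({c: merged[c] for c in base_cols})
    out["BETA"] = gamma
    out["SE"] = se_gamma
    out["Z"] = zscore
    out["P"] = np.power(10.0, np.maximum(log10p, -320.0))
    out["NEG_LOG10_P"] = -log10p
    out["Q_SNP"] = q
    out["Q_DF"] = q_df
    out["Q_P"] = q_pv
    out["NEFF"] = n_eff
    out["PD_ADJUSTED"] = pd_flag
    out["N"] = n_eff  # for direct consumption by LDSC
    out.attrs["log"] = {"n_missing_any_trait": n_missing, "n_qc_removed": n_qc,
                        "n_emitted": len(out), "n_pd_adjusted": int(pd_flag.sum())}
    out.attrs["standardized"] = True
    return out
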