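"""Simulation of GWAS/GWAX summary statistics from the multivariate LDSC model.

Per SNP j the vector of association Z statistics across the direct GWAS and
the two proxy GWAX is drawn from a trivariate normal with zero mean and

    cov(z_i, z_k) = sqrt(N_i N_k) * sigma_g,ik * l(j) / M
                    + delta_ik * (1 + a_i) + rho_ik * N_s,ik / sqrt(N_i N_k),

where sigma_g is the population genetic covariance implied by the one-factor
model (Lambda Psi Lambda' + Theta), ``a`` is confounding inflation and the
last term reflects sample overlap.  Draws are independent across SNPs: the
generator emulates LD-score-level structure, not the LD matrix itself, so the
output is suitable for LDSC-style analyses but not for clumping or local
heritability methods.

For binary traits the factor model lives on the liability scale; the observed
scale genetic covariances entering the Z covariance are obtained by dividing
by the per-trait ascertainment conversion factors for the given sample and
population prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ldscore import LDScoreTable
from .liability import LiabilityParams, conversion_factor
from .sem import implied_sigma
from .sumstats import snp_variance

#: reference-panel SNP count of the European HapMap3 LD-score panel
M_HAPMAP3 = 1_184_461

#: per-trait sample sizes of the empirical cohorts (direct, maternal, paternal)
DEFAULT_NS = (63_926, 288_676, 260_279)
#: sample prevalences of the empirical cohorts
DEFAULT_VS = (0.344, 0.096, 0.055)
DEFAULT_K = 0.05


@dataclass
class SimulationCondition:
    """Complete parameterisation of one simulation cell."""

    name: str
    lambdas: tuple = (1.0, 0.5, 0.5)
    h2_F: float = 0.073
    theta: tuple = (0.0, 0.0, 0.0)
    ns: tuple = DEFAULT_NS
    trait_type: str = "continuous"  # "continuous" | "binary"
    vs: tuple | None = None  # sample prevalences (binary only)
    k_pop: float = DEFAULT_K  # population prevalence (binary only)
    a: tuple = (0.0, 0.0, 0.0)  # confounding intercepts
    n_overlap: np.ndarray | None = None  # pairwise overlapping sample counts
    rho_overlap: np.ndarray | None = None  # phenotypic correlation in the overlap
    m: float = M_HAPMAP3  # LDSC denominator

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.vs is None:
                raise ValueError("binary conditions need sample prevalences vs")
            for v in self.vs:
                if not 0.0 < v < 1.0:
                    raise ValueError("sample prevalences must lie in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.lambdas)

    def liability_factors(self) -> np.ndarray:
        """Per-trait sqrt observed->liability conversion factors (1 if continuous)."""
        if self.trait_type == "continuous":
            return np.ones(self.k)
        return np.array(
            [
                np.sqrt(conversion_factor(LiabilityParams(p_sample=v, p_population=self.k_pop)))
                for v in self.vs
            ]
        )

    def prevalences(self) -> list[tuple[float, float] | None]:
        if self.trait_type == "continuous":
            return [None] * self.k
        return [(v, self.k_pop) for v in self.vs]

    def effective_ns(self) -> np.ndarray:
        """Per-trait effective sample sizes (4v(1-v)n for binary, n otherwise)."""
        ns = np.asarray(self.ns, dtype=float)
        if self.trait_type == "continuous":
            return ns
        vs = np.asarray(self.vs, dtype=float)
        return 4.0 * vs * (1.0 - vs) * ns


def implied_population_sigma(cond: SimulationCondition) -> np.ndarray:
    """Population genetic covariance matrix of the condition.

    On the liability scale for binary conditions, observed scale otherwise.
    """
    return implied_sigma(cond.lambdas, cond.h2_F, cond.theta)


def condition_registry(h2_F: float = 0.073) -> dict[str, SimulationCondition]:
    """The named simulation cells of the heritability study.

    Conditions 1-3 vary the proxy attenuation coefficients (.5/.5, .25/.25 and
    the empirically estimated .463/.366), each in a continuous and a binary
    (ascertained, prevalence-matched) version; the null condition has a
    diagonal genetic covariance (trait heritabilities .10/.025/.025) so the
    shared-factor heritability is truly zero.
    """
    lam = {
        "cond1": (1.0, 0.5, 0.5),
        "cond2": (1.0, 0.25, 0.25),
        "cond3": (1.0, 0.463, 0.366),
    }
    reg: dict[str, SimulationCondition] = {}
    for key, lambdas in lam.items():
        reg[key] = SimulationCondition(name=key, lambdas=lambdas, h2_F=h2_F)
        reg[key + "_binary"] = SimulationCondition(
            name=key + "_binary",
            lambdas=lambdas,
            h2_F=h2_F,
            trait_type="binary",
            vs=DEFAULT_VS,
            k_pop=DEFAULT_K,
        )
    reg["null"] = SimulationCondition(
        name="null",
        lambdas=(1.0, 0.5, 0.5),
        h2_F=0.0,
        theta=(0.10, 0.025, 0.025),
        trait_type="binary",
        vs=DEFAULT_VS,
        k_pop=DEFAULT_K,
    )
    return reg


def synth_ldscores(
    m: int, seed: int = 0, mean_l2: float = 110.0, shape: float = 2.0
) -> LDScoreTable:
    """Generate a synthetic LD-score table of ``m`` SNPs.

    LD scores are drawn from a right-skewed gamma distribution (mean
    ``mean_l2``, shape ``shape``) floored at 1, and assigned synthetic
    chromosome/position labels in genomic order.  Deterministic given seed.
    """
    if m < 10_000:
        import warnings

        warnings.warn(f"M={m} synthetic SNPs is small; jackknife SEs may be unstable")
    rng = np.random.default_rng(seed)
    l2 = np.maximum(rng.gamma(shape, mean_l2 / shape, size=m), 1.0)
    chrom = 1 + (np.arange(m) * 22) // m
    pos = np.zeros(m, dtype=int)
    for c in range(1, 23):
        mask = chrom == c
        pos[mask] = 10_000 * (1 + np.arange(mask.sum()))
    df = pd.DataFrame(
        {"SNP": [f"rs{i}" for i in range(m)], "CHR": chrom, "BP": pos, "L2": l2}
    )
    return LDScoreTable(df=df, m=float(m))


def _z_covariances(cond: SimulationCondition, m: float):
    """Constant (A) and per-unit-LD-score (B) parts of the Z covariance.

    ``m`` is the reference-panel count of the LD-score table the draws are
    conditioned on, so that LDSC applied to the output with the same table
    recovers the condition's parameters.
    """
    f = cond.liability_factors()
    sigma_obs = implied_population_sigma(cond) / np.outer(f, f)
    ns = np.asarray(cond.ns, dtype=float)
    sqrt_n = np.sqrt(ns)
    B = np.outer(sqrt_n, sqrt_n) * sigma_obs / m
    A = np.eye(cond.k) + np.diag(np.asarray(cond.a, dtype=float))
    if cond.n_overlap is not None:
        rho = cond.rho_overlap if cond.rho_overlap is not None else np.zeros((cond.k, cond.k))
        overlap = np.asarray(cond.n_overlap, dtype=float) * np.asarray(rho, dtype=float)
        overlap = overlap / np.outer(sqrt_n, sqrt_n)
        np.fill_diagonal(overlap, 0.0)
        A = A + overlap
    return A, B


def simulate_zstats(
    cond: SimulationCondition, ld: LDScoreTable, seed: int | np.random.Generator = 0
) -> list[pd.DataFrame]:
    """Draw one replicate of summary statistics for all traits of a condition.

    Returns one table per trait in the munged layout
    (``SNP CHR BP A1 A2 MAF INFO BETA SE Z N``) with constant per-trait N.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    l2 = ld.df["L2"].to_numpy(float)
    n_snp = len(l2)
    A, B = _z_covariances(cond, float(ld.m))
    covs = A[None, :, :] + l2[:, None, None] * B[None, :, :]
    try:
        chol = np.linalg.cholesky(covs)
    except np.linalg.LinAlgError:
        eigs = np.linalg.eigvalsh(covs)
        bad = int(np.argmin(eigs[:, 0]))
        raise ValueError(
            f"per-SNP Z covariance not positive definite at SNP "
            f"{ld.df['SNP'].iloc[bad]} (min eigenvalue {eigs[bad, 0]:.3g})"
        ) from None
    z = np.einsum("jab,jb->ja", chol, rng.standard_normal((n_snp, cond.k)))

    maf = rng.uniform(0.05, 0.5, size=n_snp)
    var = snp_variance(maf)
    n_w = cond.effective_ns()
    tables = []
    for i in range(cond.k):
        se = 1.0 / np.sqrt(var * n_w[i])
        df = pd.DataFrame(
            {
                "SNP": ld.df["SNP"].to_numpy(),
                "CHR": ld.df["CHR"].to_numpy() if "CHR" in ld.df else 0,
                "BP": ld.df["BP"].to_numpy() if "BP" in ld.df else 0,
                "A1": "A",
                "A2": "G",
                "MAF": maf,
                "INFO": 1.0,
                "BETA": z[:, i] * se,
                "SE": se,
                "Z": z[:, i],
                "N": float(cond.ns[i]),
            }
        )
        df.attrs["standardized"] = True
        tables.append(df)
    return tables


def simulate_snp_effect(
    cond: SimulationCondition,
    gamma: float = 0.068,
    maf: float = 0.305,
    seed: int | np.random.Generator = 0,
):
    """Draw observed per-trait effects for a single SNP with known effect on F.

    The true per-trait betas are ``gamma * lambda_i`` (per effect allele, in
    direct-GWAS liability SD units).  Observed betas are drawn independently
    per trait with sampling variance ``(1 - 2maf(1-maf) b_i^2) / (2maf(1-maf)
    n_i)`` for continuous traits, with an extra ``v_i (1 - v_i)`` factor in the
    denominator for ascertained binary traits; SEs are the square roots.

    Returns ``(beta_obs, se, beta_true)`` arrays of length k.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var = float(snp_variance(maf))
    b_true = gamma * np.asarray(cond.lambdas, dtype=float)
    if np.any(var * b_true**2 >= 1.0):
        raise ValueError("2maf(1-maf)*b^2 >= 1: implied sampling variance is negative")
    ns = np.asarray(cond.ns, dtype=float)
    denom = var * ns
    if cond.trait_type == "binary":
        vs = np.asarray(cond.vs, dtype=float)
        denom = denom * vs * (1.0 - vs)
    sampling_var = (1.0 - var * b_true**2) / denom
    se = np.sqrt(sampling_var)
    beta_obs = rng.normal(b_true, se)
    return beta_obs, se, b_true
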