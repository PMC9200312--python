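"""Univariate, bivariate and multivariate LD-score regression.

Products of association Z statistics are regressed on LD scores: for traits i
and k with per-SNP statistics ``z_i(j)``,

    E[z_i(j) z_k(j)] = sqrt(N_i N_k) * sigma_g,ik * l(j) / M + delta_ik
                       + (cross-trait intercept),

so the slope recovers the genetic (co)variance ``sigma_g`` and the intercept
absorbs confounding and sample overlap.  Standard errors and the full sampling
covariance V of the vectorised genetic covariance matrix come from a
delete-one block jackknife over contiguous genomic blocks; running every pair
on the same block partition lets V capture the dependence between elements
induced by shared SNPs and overlapping samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldscore import LDScoreTable
from .liability import LiabilityParams, conversion_factor

_MIN_OVERLAP = 200


def vech_indices(k: int) -> list[tuple[int, int]]:
    """Row-wise lower-triangle ordering used for vech(S) and V."""
    return [(i, j) for i in range(k) for j in range(i + 1)]


def vech(mat: np.ndarray) -> np.ndarray:
    return np.array([mat[i, j] for i, j in vech_indices(mat.shape[0])])


def unvech(v: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((k, k))
    for a, (i, j) in enumerate(vech_indices(k)):
        out[i, j] = out[j, i] = v[a]
    return out


@dataclass
class GenCovStructure:
    """Stage-1 output: genetic covariances, their sampling covariance, intercepts.

    ``S`` is on the liability scale for traits with prevalence metadata (and on
    the observed scale otherwise); ``V`` is the jackknife sampling covariance
    of ``vech(S)``; the intercept matrix holds univariate intercepts on the
    diagonal and cross-trait (overlap) intercepts off it.
    """

    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    labels: list[str]
    prevalences: list[tuple[float, float] | None] = field(default=None)
    S_obs: np.ndarray | None = None
    intercept_ses: np.ndarray | None = None
    m: float | None = None
    n_blocks: int | None = None

    @property
    def k(self) -> int:
        return self.S.shape[0]

    def se_matrix(self) -> np.ndarray:
        return unvech(np.sqrt(np.diag(self.V)), self.k)

    def to_json(self, path) -> None:
        payload = {
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "intercepts": self.intercepts.tolist(),
            "labels": self.labels,
            "prevalences": self.prevalences,
            "S_obs": None if self.S_obs is None else self.S_obs.tolist(),
            "m": self.m,
            "n_blocks": self.n_blocks,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GenCovStructure":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            S=np.array(d["S"]),
            V=np.array(d["V"]),
            intercepts=np.array(d["intercepts"]),
            labels=d["labels"],
            prevalences=[tuple(p) if p is not None else None for p in d["prevalences"]]
            if d.get("prevalences") is not None
            else None,
            S_obs=np.array(d["S_obs"]) if d.get("S_obs") is not None else None,
            m=d.get("m"),
            n_blocks=d.get("n_blocks"),
        )


@dataclass
class LdscFit:
    """One univariate or bivariate regression result (observed scale)."""

    gencov: float
    gencov_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float | None = None

    @property
    def h2_obs(self) -> float:  # alias for univariate fits
        return self.gencov

    @property
    def h2_se(self) -> float:
        return self.gencov_se


def _block_ids(n_snp: int, n_blocks: int) -> np.ndarray:
    """Assign contiguous (genomic-order) block labels of near-equal size."""
    return np.minimum((np.arange(n_snp) * n_blocks) // n_snp, n_blocks - 1)


def _wls_jackknife(y, x, w, block_id, n_blocks):
    """Weighted regression of y on [1, x] with delete-one-block jackknife.

    Returns the full-sample (intercept, slope) and the n_blocks x 2 matrix of
    jackknife pseudovalues.
    """
    ones = np.ones_like(x)
    # per-block components of X'WX (2x2 symmetric) and X'Wy (2)
    s11 = np.bincount(block_id, weights=w, minlength=n_blocks)
    s1x = np.bincount(block_id, weights=w * x, minlength=n_blocks)
    sxx = np.bincount(block_id, weights=w * x * x, minlength=n_blocks)
    s1y = np.bincount(block_id, weights=w * y, minlength=n_blocks)
    sxy = np.bincount(block_id, weights=w * x * y, minlength=n_blocks)

    A = np.array([[s11.sum(), s1x.sum()], [s1x.sum(), sxx.sum()]])
    c = np.array([s1y.sum(), sxy.sum()])
    est = np.linalg.solve(A, c)

    A_loo = A[None, :, :] - np.stack(
        [np.stack([s11, s1x], axis=-1), np.stack([s1x, sxx], axis=-1)], axis=1
    )
    c_loo = c[None, :] - np.stack([s1y, sxy], axis=-1)
    loo = np.linalg.solve(A_loo, c_loo[:, :, None])[:, :, 0]
    pseudo = n_blocks * est[None, :] - (n_blocks - 1) * loo
    return est, pseudo


def _pair_weights(l2, n_prod, slope_like, int_like, het1, het2, m):
    """Standard LDSC weights: over-counting (1/l) x heteroskedasticity."""
    l = np.maximum(l2, 1.0)
    mean_term = np.sqrt(n_prod) * slope_like * l2 / m + int_like
    het = het1 * het2 + mean_term**2
    return 1.0 / (l * np.maximum(het, 1e-12))


def _run_pair(z1, z2, n1, n2, l2, m, block_id, n_blocks, prelim,
              weight_iterations: int = 2):
    """Iteratively weighted regression of z1*z2 on l2 for one trait pair.

    One iteration corresponds to one-step weighting from the preliminary
    slopes; the two-iteration default refines the weights once with the
    estimated slope and intercept.
    """
    y = z1 * z2
    n_prod = n1 * n2
    h1, a1 = prelim[0]
    h2, a2 = prelim[1]
    het1 = np.maximum(n1 * np.clip(h1, 0, 1) * l2 / m + a1, 0.05)
    het2 = np.maximum(n2 * np.clip(h2, 0, 1) * l2 / m + a2, 0.05)

    slope_like, int_like = np.clip(h1, 0, 1), 1.0  # crude start; refined below
    est = None
    for _ in range(max(int(weight_iterations), 1)):
        w = _pair_weights(l2, n_prod, slope_like, int_like, het1, het2, m)
        est, pseudo = _wls_jackknife(y, l2, w, block_id, n_blocks)
        slope_cov = est[1] * m / np.sqrt(np.mean(n_prod))
        slope_like = np.clip(slope_cov, -1, 1)
        int_like = est[0]
    return est, pseudo


def _prepare(tables: list[pd.DataFrame], ld: LDScoreTable):
    """Inner-join trait tables with the LD scores, in genomic order."""
    cols = [c for c in ("SNP", "CHR", "BP", "L2") if c in ld.df.columns]
    merged = ld.df[cols].copy()
    for i, t in enumerate(tables):
        if "Z" not in t or "N" not in t:
            raise ValueError("each sumstats table needs Z and N columns")
        sub = t[["SNP", "Z", "N"]].rename(columns={"Z": f"Z{i}", "N": f"N{i}"})
        merged = merged.merge(sub, on="SNP", how="inner")
    if merged.empty or len(merged) < _MIN_OVERLAP:
        raise ValueError(
            f"only {len(merged)} SNPs shared between traits and LD scores "
            f"(need >= {_MIN_OVERLAP})"
        )
    if "CHR" in merged and "BP" in merged:
        merged = merged.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    z = np.column_stack([merged[f"Z{i}"].to_numpy(float) for i in range(len(tables))])
    n = np.column_stack([merged[f"N{i}"].to_numpy(float) for i in range(len(tables))])
    return z, n, merged["L2"].to_numpy(float)


def multivariate_ldsc(
    tables: list[pd.DataFrame],
    ld: LDScoreTable,
    prevalences: list[tuple[float, float] | None] | None = None,
    n_blocks: int = 200,
    labels: list[str] | None = None,
    chisq_max: float | None = None,
    weight_iterations: int = 2,
) -> GenCovStructure:
    """Estimate the genetic covariance matrix S, its sampling covariance V and
    the intercept matrix for a set of traits.

    ``prevalences`` holds one ``(sample, population)`` prevalence pair per
    binary trait (``None`` for continuous traits); the corresponding rows and
    columns of S are converted to the liability scale, with V rescaled from
    the same jackknife pseudovalues.

    ``chisq_max`` drops SNPs whose chi-square exceeds the threshold in any
    trait before the regressions (off by default: removing the APOE region at
    munging plays the same role); ``weight_iterations`` selects one-step or
    iterated (default) regression weights.
    """
    k = len(tables)
    z, n, l2 = _prepare(tables, ld)
    if chisq_max is not None:
        keep = (z**2 <= chisq_max).all(axis=1)
        z, n, l2 = z[keep], n[keep], l2[keep]
        if len(l2) < _MIN_OVERLAP:
            raise ValueError("chisq_max filter removed nearly all SNPs")
    n_snp = len(l2)
    if n_snp < 2 * n_blocks:
        raise ValueError(f"{n_snp} SNPs is too few for {n_blocks} jackknife blocks")
    block_id = _block_ids(n_snp, n_blocks)
    m = float(ld.m)
    nbar = n.mean(axis=0)

    # preliminary univariate slopes (unweighted by signal) for the weight model
    prelim = []
    for i in range(k):
        est0, _ = _wls_jackknife(z[:, i] ** 2, l2, 1.0 / np.maximum(l2, 1.0), block_id, n_blocks)
        prelim.append((est0[1] * m / nbar[i], max(est0[0], 0.05)))

    idx = vech_indices(k)
    q = len(idx)
    S_obs = np.zeros((k, k))
    intercepts = np.zeros((k, k))
    intercept_ses = np.zeros((k, k))
    pseudo_all = np.zeros((n_blocks, q))
    for a, (i, j) in enumerate(idx):
        est, pseudo = _run_pair(
            z[:, i], z[:, j], n[:, i], n[:, j], l2, m, block_id, n_blocks,
            (prelim[i], prelim[j]), weight_iterations=weight_iterations,
        )
        scale = m / np.sqrt(nbar[i] * nbar[j])
        S_obs[i, j] = S_obs[j, i] = est[1] * scale
        intercepts[i, j] = intercepts[j, i] = est[0]
        intercept_ses[i, j] = intercept_ses[j, i] = float(
            np.std(pseudo[:, 0], ddof=1) / np.sqrt(n_blocks)
        )
        pseudo_all[:, a] = pseudo[:, 1] * scale

    V_obs = np.cov(pseudo_all, rowvar=False, ddof=1) / n_blocks
    V_obs = np.atleast_2d(V_obs)

    factors = np.ones(k)
    if prevalences is not None:
        if len(prevalences) != k:
            raise ValueError("one prevalence entry (or None) per trait required")
        for i, prev in enumerate(prevalences):
            if prev is not None:
                v, pop = prev
                factors[i] = np.sqrt(
                    conversion_factor(LiabilityParams(p_sample=v, p_population=pop))
                )
    S = S_obs * np.outer(factors, factors)
    g = np.array([factors[i] * factors[j] for i, j in idx])
    V = V_obs * np.outer(g, g)

    return GenCovStructure(
        S=S,
        V=V,
        intercepts=intercepts,
        labels=labels or [f"trait{i + 1}" for i in range(k)],
        prevalences=list(prevalences) if prevalences is not None else [None] * k,
        S_obs=S_obs,
        intercept_ses=intercept_ses,
        m=m,
        n_blocks=n_blocks,
    )


def univariate_ldsc(t: pd.DataFrame, ld: LDScoreTable, n_blocks: int = 200) -> LdscFit:
    """Observed-scale SNP heritability for one trait: regress z^2 on l(j).

    Returns the heritability (slope * M / mean N), its jackknife SE, the
    regression intercept (~1 + confounding) and the intercept SE.  Negative
    estimates are returned untruncated.
    """
    gcs = multivariate_ldsc([t], ld, prevalences=None, n_blocks=n_blocks)
    z, _, _ = _prepare([t], ld)
    return LdscFit(
        gencov=gcs.S_obs[0, 0],
        gencov_se=float(np.sqrt(gcs.V[0, 0])),
        intercept=gcs.intercepts[0, 0],
        intercept_se=gcs.intercept_ses[0, 0],
        mean_chi2=float(np.mean(z[:, 0] ** 2)),
    )


def bivariate_ldsc(
    t1: pd.DataFrame, t2: pd.DataFrame, ld: LDScoreTable, n_blocks: int = 200
) -> LdscFit:
    """Genetic covariance between two traits: regress z1*z2 on l(j).

    The intercept estimates the sample-overlap term ``rho * N_s / sqrt(N1 N2)``
    and is ~0 for independent cohorts.
    """
    gcs = multivariate_ldsc([t1, t2], ld, prevalences=None, n_blocks=n_blocks)
    # cross-pair is vech index 1 -> (1, 0)
    return LdscFit(
        gencov=gcs.S_obs[1, 0],
        gencov_se=float(np.sqrt(gcs.V[1, 1])),
        intercept=gcs.intercepts[1, 0],
        intercept_se=gcs.intercept_ses[1, 0],
    )
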