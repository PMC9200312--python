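"""One-factor genomic structural equation model fit by diagonally weighted
least squares.

The model for k indicator traits (one direct GWAS plus proxy GWAX) is

    Sigma(theta) = Lambda Psi Lambda' + Theta,

with Lambda the k-vector of factor loadings (the GWAX attenuation
coefficients), Psi the factor variance sigma_F^2 and Theta a diagonal matrix
of residual genetic variances.  Under the default identification
``lambda_direct = 1`` the factor takes the scale of the direct GWAS and
sigma_F^2 is an unbiased estimate of the SNP heritability of the meta-analysed
phenotype; under the alternative ``sigma_F^2 = 1`` identification the squared
direct loading plays that role.

Fitting minimises ``(s - sigma(theta))' D^-1 (s - sigma(theta))`` with
``s = vech(S)`` and ``D = diag(V)``; parameter standard errors use the full
sandwich ``(J'D^-1 J)^-1 J'D^-1 V D^-1 J (J'D^-1 J)^-1``.  Model fit for
over-identified specifications is the residual-based statistic
``r' P (P'VP)^-1 P' r`` with P an orthonormal basis for the orthogonal
complement of the Jacobian column space, asymptotically chi^2 on the model
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .ldsc import GenCovStructure, vech, vech_indices


@dataclass
class FactorModelSpec:
    """Specification of the one-factor model.

    ``fixed_lambda``/``fixed_theta`` map indicator index to a fixed value;
    everything else is free.  Exactly one identification constraint is active:
    ``identification="direct"`` fixes the first loading at 1 (Psi free) and
    ``identification="factor"`` fixes Psi at 1 (all loadings free).
    """

    k: int
    identification: str = "direct"  # "direct" | "factor"
    fixed_lambda: dict[int, float] = field(default_factory=dict)
    fixed_theta: dict[int, float] = field(default_factory=dict)
    theta_lower: float | None = 0.0  # None allows negative residual variances
    # box bounds keeping estimates in the scientifically meaningful region:
    # variances of standardized (liability-scale) traits cannot exceed 1, and
    # without them the just-identified model is unidentified when the traits
    # share no genetic signal (psi ~ S12*S13/S23 with S23 -> 0 is unbounded)
    psi_bound: float | None = 1.0
    lambda_bound: float | None = 10.0
    theta_upper: float | None = 1.0

    def __post_init__(self) -> None:
        if self.identification not in ("direct", "factor"):
            raise ValueError(f"unknown identification {self.identification!r}")
        if self.identification == "direct" and 0 not in self.fixed_lambda:
            self.fixed_lambda = {0: 1.0, **self.fixed_lambda}
        # a single indicator cannot separate factor and residual variance
        if self.k == 1 and not self.fixed_theta:
            self.fixed_theta = {0: 0.0}
        for i, v in self.fixed_theta.items():
            if self.theta_lower is not None and v < self.theta_lower - 1e-12:
                raise ValueError(f"fixed theta[{i}]={v} conflicts with lower bound")

    @property
    def psi_free(self) -> bool:
        return self.identification == "direct"

    def free_names(self) -> list[str]:
        names = [f"lambda_{i}" for i in range(self.k) if i not in self.fixed_lambda]
        if self.psi_free:
            names.append("psi")
        names += [f"theta_{i}" for i in range(self.k) if i not in self.fixed_theta]
        return names

    @property
    def n_free(self) -> int:
        return len(self.free_names())

    @property
    def df(self) -> int:
        return self.k * (self.k + 1) // 2 - self.n_free


@dataclass
class FactorModelFit:
    """Result of one DWLS fit."""

    spec: FactorModelSpec
    lambdas: np.ndarray
    psi: float
    theta: np.ndarray
    se: dict[str, float]
    estimates: dict[str, float]
    h2_F: float
    h2_F_se: float
    chi2: float
    df: int
    p_chi2: float
    converged: bool
    n_restarts: int = 0

    def z(self, name: str) -> float:
        return self.estimates[name] / self.se[name]

    def p(self, name: str) -> float:
        return 2.0 * stats.norm.sf(abs(self.z(name)))

    def summary(self) -> str:
        lines = [f"{'param':<10}{'est':>10}{'se':>10}{'z':>8}{'p':>10}"]
        for name, est in self.estimates.items():
            se = self.se[name]
            z = est / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"{name:<10}{est:>10.4f}{se:>10.4f}{z:>8.2f}{p:>10.3g}")
        lines.append(f"h2_F = {self.h2_F:.4f} (SE {self.h2_F_se:.4f}); "
                     f"chi2({self.df}) = {self.chi2:.3f}, p = {self.p_chi2:.3g}")
        return "\n".join(lines)


def implied_sigma(lambdas, psi, theta) -> np.ndarray:
    """Model-implied genetic covariance matrix ``Lambda Psi Lambda' + Theta``."""
    lambdas = np.asarray(lambdas, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if lambdas.shape != theta.shape:
        raise ValueError("lambda and theta must have the same length")
    return np.outer(lambdas, lambdas) * float(psi) + np.diag(theta)


def smooth_to_pd(mat: np.ndarray, floor_ratio: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix by eigenvalue
    flooring at ``floor_ratio * max(eigenvalue)``."""
    mat = 0.5 * (mat + mat.T)
    w, u = np.linalg.eigh(mat)
    floor = floor_ratio * max(w.max(), 1e-300)
    if w.min() >= floor:
        return mat
    w = np.maximum(w, floor)
    return (u * w) @ u.T


def _unpack(spec: FactorModelSpec, x: np.ndarray):
    lambdas = np.empty(spec.k)
    theta = np.empty(spec.k)
    pos = 0
    for i in range(spec.k):
        if i in spec.fixed_lambda:
            lambdas[i] = spec.fixed_lambda[i]
        else:
            lambdas[i] = x[pos]
            pos += 1
    psi = x[pos] if spec.psi_free else 1.0
    pos += spec.psi_free
    for i in range(spec.k):
        if i in spec.fixed_theta:
            theta[i] = spec.fixed_theta[i]
        else:
            theta[i] = x[pos]
            pos += 1
    return lambdas, psi, theta


def _jacobian(spec: FactorModelSpec, lambdas, psi) -> np.ndarray:
    """d vech(Sigma) / d free parameters, columns ordered as free_names()."""
    idx = vech_indices(spec.k)
    cols = []
    for a in range(spec.k):
        if a in spec.fixed_lambda:
            continue
        col = [(lambdas[j] if i == a else 0.0) * psi + (lambdas[i] if j == a else 0.0) * psi
               for i, j in idx]
        cols.append(col)
    if spec.psi_free:
        cols.append([lambdas[i] * lambdas[j] for i, j in idx])
    for a in range(spec.k):
        if a in spec.fixed_theta:
            continue
        cols.append([1.0 if (i == j == a) else 0.0 for i, j in idx])
    return np.array(cols).T  # q x p


def _start_values(spec: FactorModelSpec, S: np.ndarray, rng=None) -> np.ndarray:
    k = spec.k
    s00 = max(abs(S[0, 0]), 1e-6)
    psi0 = np.clip(2.0 * S[1, 0], -s00, s00) if k > 1 else S[0, 0]
    if abs(psi0) < 1e-4 * s00 or psi0 == 0:
        psi0 = 0.5 * s00
    lam0 = np.ones(k)
    for i in range(1, k):
        lam0[i] = np.clip(S[0, i] / psi0, -2.0, 2.0)
    theta0 = np.maximum(np.diag(S) - lam0**2 * psi0, 1e-3 * s00)
    if rng is not None:
        psi0 *= rng.uniform(0.3, 1.7)
        lam0 = lam0 * rng.uniform(0.5, 1.5, size=k) + rng.normal(0, 0.1, size=k)
        theta0 = theta0 * rng.uniform(0.3, 1.7, size=k)
    x = []
    for i in range(k):
        if i not in spec.fixed_lambda:
            x.append(lam0[i])
    if spec.psi_free:
        x.append(psi0)
    lo = spec.theta_lower if spec.theta_lower is not None else -np.inf
    for i in range(k):
        if i not in spec.fixed_theta:
            x.append(max(theta0[i], lo))
    return np.array(x)


def _bounds(spec: FactorModelSpec):
    lo, hi = [], []
    lb = spec.lambda_bound if spec.lambda_bound is not None else np.inf
    pb = spec.psi_bound if spec.psi_bound is not None else np.inf
    tl = spec.theta_lower if spec.theta_lower is not None else -np.inf
    tu = spec.theta_upper if spec.theta_upper is not None else np.inf
    for i in range(spec.k):
        if i not in spec.fixed_lambda:
            lo.append(-lb)
            hi.append(lb)
    if spec.psi_free:
        lo.append(-pb)
        hi.append(pb)
    for i in range(spec.k):
        if i not in spec.fixed_theta:
            lo.append(tl)
            hi.append(tu)
    return np.array(lo), np.array(hi)


def fit_dwls(
    S_V: GenCovStructure,
    spec: FactorModelSpec | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> FactorModelFit:
    """Fit the one-factor model to (S, V) by diagonally weighted least squares.

    V is smoothed to the nearest positive (semi)definite matrix before use.
    On optimizer failure up to ``n_restarts`` random restarts are attempted;
    a persistently non-converged fit is returned flagged, never silently.
    """
    if spec is None:
        spec = FactorModelSpec(k=S_V.k)
    if spec.k != S_V.k:
        raise ValueError("spec and S dimension mismatch")

    S = 0.5 * (S_V.S + S_V.S.T)
    V = smooth_to_pd(S_V.V)
    s = vech(S)
    d = np.maximum(np.diag(V), 1e-30)
    sd = np.sqrt(d)

    def resid(x):
        lambdas, psi, theta = _unpack(spec, x)
        return (vech(implied_sigma(lambdas, psi, theta)) - s) / sd

    def jac(x):
        lambdas, psi, _ = _unpack(spec, x)
        return _jacobian(spec, lambdas, psi) / sd[:, None]

    lo, hi = _bounds(spec)
    rng = np.random.default_rng(seed)
    best, used_restarts = None, 0
    for attempt in range(n_restarts + 1):
        x0 = _start_values(spec, S, rng=None if attempt == 0 else rng)
        x0 = np.clip(x0, lo + 1e-12, hi)
        try:
            res = optimize.least_squares(resid, x0, jac=jac, bounds=(lo, hi),
                                         method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
            used_restarts = attempt
        if res.success and res.cost < 1e-10:
            break
    if best is None:
        raise RuntimeError("DWLS optimization failed on all restarts")

    x_hat = best.x
    lambdas, psi, theta = _unpack(spec, x_hat)
    J = _jacobian(spec, lambdas, psi)
    Dinv = 1.0 / d
    B = J.T @ (J * Dinv[:, None])
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError:
        Binv = np.linalg.pinv(B)
    middle = (J * Dinv[:, None]).T @ V @ (J * Dinv[:, None])
    cov = Binv @ middle @ Binv
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))

    names = spec.free_names()
    estimates = dict(zip(names, x_hat))
    se = dict(zip(names, ses))

    r = s - vech(implied_sigma(lambdas, psi, theta))
    df = spec.df
    if df > 0:
        P = linalg.null_space(J.T)
        Vp = P.T @ V @ P
        chi2 = float(r @ P @ np.linalg.solve(Vp, P.T @ r))
        p_chi2 = float(stats.chi2.sf(chi2, df))
    else:
        chi2, p_chi2 = 0.0, 1.0

    if spec.identification == "direct":
        h2 = float(psi)
        h2_se = se.get("psi", 0.0)
    else:
        h2 = float(lambdas[0] ** 2)
        h2_se = 2.0 * abs(lambdas[0]) * se.get("lambda_0", 0.0)

    return FactorModelFit(
        spec=spec,
        lambdas=lambdas,
        psi=float(psi),
        theta=theta,
        se=se,
        estimates=estimates,
        h2_F=h2,
        h2_F_se=h2_se,
        chi2=chi2,
        df=df,
        p_chi2=p_chi2,
        converged=bool(best.success),
        n_restarts=used_restarts,
    )


def fit_constrained(
    S_V: GenCovStructure,
    spec: FactorModelSpec | None = None,
    constraints: str = "none",
    **kwargs,
) -> FactorModelFit:
    """Fit with a named constraint.

    ``"theta_direct=0"`` fixes the direct-GWAS residual variance at zero
    (MTAG-like assumption); ``"lambda=0.5"`` imposes the standard first-degree
    proxy attenuation on every GWAX loading; ``"none"`` reproduces
    :func:`fit_dwls`.
    """
    if spec is None:
        spec = FactorModelSpec(k=S_V.k)
    if constraints == "none":
        return fit_dwls(S_V, spec, **kwargs)
    if constraints == "theta_direct=0":
        if 0 in spec.fixed_theta and spec.fixed_theta[0] != 0.0:
            raise ValueError("contradictory constraint on theta_direct")
        new = FactorModelSpec(
            k=spec.k,
            identification=spec.identification,
            fixed_lambda=dict(spec.fixed_lambda),
            fixed_theta={**spec.fixed_theta, 0: 0.0},
            theta_lower=spec.theta_lower,
            psi_bound=spec.psi_bound,
            lambda_bound=spec.lambda_bound,
            theta_upper=spec.theta_upper,
        )
        return fit_dwls(S_V, new, **kwargs)
    if constraints == "lambda=0.5":
        fixed = dict(spec.fixed_lambda)
        for i in range(1, spec.k):
            if i in fixed and fixed[i] != 0.5:
                raise ValueError(f"contradictory constraint on lambda_{i}")
            fixed[i] = 0.5
        new = FactorModelSpec(
            k=spec.k,
            identification=spec.identification,
            fixed_lambda=fixed,
            fixed_theta=dict(spec.fixed_theta),
            theta_lower=spec.theta_lower,
            psi_bound=spec.psi_bound,
            lambda_bound=spec.lambda_bound,
            theta_upper=spec.theta_upper,
        )
        return fit_dwls(S_V, new, **kwargs)
    raise ValueError(f"unknown constraint {constraints!r}")


def chisq_diff(fit_restricted: FactorModelFit, fit_full: FactorModelFit):
    """Chi-square difference test between nested fits: (dchi2, ddf, p)."""
    ddf = fit_restricted.df - fit_full.df
    if ddf < 0:
        raise ValueError("restricted model must have more degrees of freedom")
    dchi2 = max(fit_restricted.chi2 - fit_full.chi2, 0.0)
    if ddf == 0:
        p = 1.0 if dchi2 <= 1e-12 else 0.0
    else:
        p = float(stats.chi2.sf(dchi2, ddf))
    return dchi2, ddf, p
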