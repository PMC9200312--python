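"""Conventional GWAS+GWAX meta-analysis baselines.

Two families are implemented, mirroring published practice: inverse-variance
weighting of regression coefficients (optionally multiplying proxy betas and
SEs by a correction factor, 2 for first-degree relatives under the standard
model) and sample-size-weighted Z-score meta-analysis (optionally dividing
each study's N by the squared correction factor, 4 under the standard model).
The uncorrected variants reproduce the naive practice of ignoring the proxy
nature of GWAX; they are deliberately biased comparators.
"""

from __future__ import annotations

import numpy as np

from .sumstats import CohortMeta, effective_n


def ivw_meta(per_trait, correction=None):
    """Inverse-variance-weighted meta-analysis of (beta, se) pairs.

    ``per_trait`` is a sequence of ``(beta, se)`` arrays or scalars;
    ``correction`` gives a per-trait multiplier applied to both beta and SE
    before combining (1 for direct GWAS, 2 for first-degree proxy GWAX under
    the standard correction, ``1/lambda_hat`` under an empirical correction).
    Returns ``(beta_meta, se_meta)``.
    """
    kk = len(per_trait)
    correction = np.ones(kk) if correction is None else np.asarray(correction, dtype=float)
    betas = [np.asarray(b, dtype=float) * c for (b, _), c in zip(per_trait, correction)]
    ses = [np.asarray(s, dtype=float) * c for (_, s), c in zip(per_trait, correction)]
    for s in ses:
        if np.any(s <= 0):
            raise ValueError("standard errors must be positive")
    weights = [1.0 / s**2 for s in ses]
    wsum = sum(weights)
    beta_meta = sum(w * b for w, b in zip(weights, betas)) / wsum
    se_meta = np.sqrt(1.0 / wsum)
    return beta_meta, se_meta


def z_meta(per_trait, n_correction=None):
    """Sample-size-weighted Z meta-analysis.

    ``per_trait`` is a sequence of ``(z, n)`` pairs; ``n_correction`` divides
    each study's sample size (4 for first-degree proxies under the standard
    correction, since betas and SEs would each be doubled).  Returns
    ``(z_meta, n_reported)`` where ``n_reported`` is the summed working N that
    should be entered in downstream LDSC.
    """
    kk = len(per_trait)
    div = np.ones(kk) if n_correction is None else np.asarray(n_correction, dtype=float)
    zs = [np.asarray(z, dtype=float) for z, _ in per_trait]
    ns = [np.asarray(n, dtype=float) / d for (_, n), d in zip(per_trait, div)]
    for n in ns:
        if np.any(n <= 0):
            raise ValueError("sample sizes must be positive")
    num = sum(np.sqrt(n) * z for n, z in zip(ns, zs))
    n_tot = sum(ns)
    return num / np.sqrt(n_tot), n_tot


def liability_corrected_neff(
    cohorts: list[CohortMeta], lambdas_assumed=(1.0, 0.5, 0.5)
) -> float:
    """Working effective N for the standard-plus-liability correction.

    Each cohort's effective N (``4v(1-v)n``) is weighted by the squared
    assumed attenuation coefficient (0.25 for first-degree proxies under the
    standard model).  Downstream LDSC should be given this N together with a
    sample prevalence of 0.5, since effective N describes an equivalently
    informative balanced design.
    """
    lam = np.asarray(lambdas_assumed, dtype=float)
    if len(lam) != len(cohorts):
        raise ValueError("one assumed lambda per cohort required")
    return float(sum(l**2 * effective_n(c) for l, c in zip(lam, cohorts)))
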