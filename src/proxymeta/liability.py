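"""Observed <-> liability scale conversion for ascertained case-control GWAS.

The liability-threshold model places a standard-normal liability behind the
binary phenotype; individuals above the threshold ``t = Phi^-1(1 - K)`` (K the
population prevalence) are affected.  For an ascertained sample with case
fraction ``P_sample`` the observed-scale heritability converts to the
liability scale as

    h2_l = h2_o * K^2 (1-K)^2 / (P_s (1-P_s) * (1-FCR)^2 * phi(t)^2),

where ``FCR`` is the false-classification rate: the fraction of nominal
controls who in fact carry the (undetected, biological) disease.  ``FCR = 0``
recovers the classical ascertained-sample transformation; a positive FCR
deflates the case-control contrast and so inflates the implied liability
heritability.  For a disorder like Alzheimer's disease, whose pathology is far
more prevalent than its clinical diagnosis, ``FCR`` is the excess of the
biological over the clinical prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LiabilityParams:
    """Parameters of one observed-to-liability conversion."""

    p_sample: float
    p_population: float
    fcr: float = 0.0
    t: float = field(init=False)
    phi_t: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_sample < 1.0:
            raise ValueError("p_sample must lie in (0, 1)")
        if not 0.0 < self.p_population < 1.0:
            raise ValueError("p_population must lie in (0, 1)")
        if not 0.0 <= self.fcr < 1.0:
            raise ValueError("FCR must lie in [0, 1)")
        self.t = stats.norm.isf(self.p_population)
        self.phi_t = stats.norm.pdf(self.t)


def conversion_factor(p: LiabilityParams) -> float:
    """Multiplier taking observed-scale h2 to the liability scale."""
    k = p.p_population
    num = k**2 * (1.0 - k) ** 2
    den = p.p_sample * (1.0 - p.p_sample) * (1.0 - p.fcr) ** 2 * p.phi_t**2
    return num / den


def obs_to_liability(h2_obs: float, p: LiabilityParams) -> float:
    """Convert observed-scale heritability (or genetic covariance) to liability scale.

    Negative inputs propagate with a warning: LDSC point estimates can be
    negative and truncating them would bias simulation nulls.
    """
    if h2_obs < 0:
        warnings.warn("negative observed-scale h2 passed through the liability conversion")
    return h2_obs * conversion_factor(p)


def liability_to_obs(h2_liab: float, p: LiabilityParams) -> float:
    """Inverse of :func:`obs_to_liability`."""
    return h2_liab / conversion_factor(p)


def fcr_biological(p_bio: float, p_clinical: float) -> float:
    """False-classification rate when controls are screened only clinically.

    Treating clinical cases as a random subset of biological cases, the
    fraction of biological cases left inside the screened control pool is the
    prevalence difference ``P_bio - P_clinical``.
    """
    if p_bio < p_clinical:
        raise ValueError("biological prevalence cannot be below clinical prevalence")
    return p_bio - p_clinical


def prevalence_sweep(
    h2_obs: float,
    p_sample: float,
    k_grid,
    mode: str = "clinical",
    p_clinical_fixed: float = 0.0285,
    se_obs: float | None = None,
) -> pd.DataFrame:
    """Liability-scale h2 across a grid of assumed population prevalences.

    ``mode="clinical"`` assumes perfectly screened controls (FCR = 0);
    ``mode="biological"`` treats each grid value as the biological prevalence
    and sets ``FCR = K - p_clinical_fixed`` with the clinical prevalence fixed
    (default 0.0285, the age-specific clinical rate matching the IGAP control
    mean age of 72.42 years).  Standard errors scale by the same factor.
    """
    if mode not in ("clinical", "biological"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for k in np.atleast_1d(np.asarray(k_grid, dtype=float)):
        if mode == "biological":
            if k < p_clinical_fixed:
                raise ValueError(
                    f"biological prevalence {k} below fixed clinical prevalence {p_clinical_fixed}"
                )
            fcr = fcr_biological(k, p_clinical_fixed)
        else:
            fcr = 0.0
        p = LiabilityParams(p_sample=p_sample, p_population=k, fcr=fcr)
        factor = conversion_factor(p)
        rows.append(
            {
                "K": k,
                "FCR": fcr,
                "h2_liability": h2_obs * factor,
                "se_scaled": se_obs * factor if se_obs is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
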