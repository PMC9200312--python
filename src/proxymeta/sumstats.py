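"""Reading, harmonising and rescaling GWAS/GWAX summary statistics.

Summary-statistic tables are plain :class:`pandas.DataFrame` objects with the
canonical columns ``SNP CHR BP A1 A2 FRQ MAF INFO BETA SE Z N`` (a subset may
be absent depending on the source file).  ``A1`` is the effect allele, ``BETA``
a per-allele effect (log-odds for binary traits) and ``Z`` the signed test
statistic.  Processing steps record what they dropped in ``df.attrs["log"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical output column order for munged tables
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "MAF", "INFO", "BETA", "SE", "Z", "N"]

#: header synonyms accepted by :func:`read_sumstats` (lower-cased)
COLUMN_SYNONYMS = {
    "SNP": ["snp", "rsid", "rs_id", "markername", "marker", "snpid", "id"],
    "CHR": ["chr", "chrom", "chromosome", "hg18chr", "hg19chr"],
    "BP": ["bp", "pos", "position", "base_pair", "bpos"],
    "A1": ["a1", "ea", "effect_allele", "allele1", "alt", "inc_allele"],
    "A2": ["a2", "oa", "other_allele", "allele2", "allele0", "ref", "nea", "dec_allele"],
    "BETA": ["beta", "b", "effect", "effects", "log_odds", "logor"],
    "OR": ["or", "odds_ratio", "oddsratio"],
    "Z": ["z", "zscore", "z_score", "zstat", "z_stat"],
    "SE": ["se", "stderr", "standard_error", "se_beta"],
    "N": ["n", "nobs", "sample_size", "n_total", "neff", "n_eff"],
    "INFO": ["info", "impinfo", "imputation_quality", "rsq", "r2"],
    "FRQ": ["frq", "freq", "eaf", "af", "a1freq", "frq_a1", "maf", "effect_allele_frequency"],
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: GRCh37 regions excluded by default from LD-score regression (1-based inclusive)
APOE_REGION = (19, 45_116_911, 46_318_605)
MHC_REGION = (6, 26_000_000, 34_000_000)


@dataclass
class CohortMeta:
    """Cohort-level metadata for one contributing GWAS/GWAX.

    For binary traits ``n_cases``/``n_controls`` define the sample prevalence
    ``v``; for continuous traits only ``n`` is needed.  ``relatedness_class``
    distinguishes direct case-control data from first-degree proxy reports.
    """

    trait_type: str = "binary"  # "binary" | "continuous"
    n_cases: int | None = None
    n_controls: int | None = None
    n: int | None = None
    relatedness_class: str = "direct"  # "direct" | "first_degree_proxy"

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_cases is None or self.n_controls is None:
                raise ValueError("binary cohorts need n_cases and n_controls")
            if self.n is None:
                self.n = self.n_cases + self.n_controls
        elif self.n is None:
            raise ValueError("continuous cohorts need n")

    @property
    def sample_prevalence(self) -> float | None:
        if self.trait_type == "continuous":
            return None
        return self.n_cases / (self.n_cases + self.n_controls)


def effective_n(cohorts: list[CohortMeta] | CohortMeta) -> float:
    """Total effective sample size, ``sum_k 4 v_k (1 - v_k) n_k``.

    A balanced case-control study of this size carries equivalent information.
    Continuous cohorts contribute their n unchanged.
    """
    if isinstance(cohorts, CohortMeta):
        cohorts = [cohorts]
    total = 0.0
    for c in cohorts:
        if c.trait_type == "continuous":
            total += c.n
        else:
            v = c.sample_prevalence
            if not 0.0 < v < 1.0:
                raise ValueError(f"sample prevalence {v} outside (0, 1)")
            total += 4.0 * v * (1.0 - v) * c.n
    return total


def snp_variance(maf):
    """Variance of an additively coded biallelic SNP, ``2 maf (1 - maf)``."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    return 2.0 * maf * (1.0 - maf)


def snp_cov(beta_std, maf):
    """Genetic covariance between a SNP and a trait: ``beta_std * 2 maf (1-maf)``."""
    return np.asarray(beta_std, dtype=float) * snp_variance(maf)


def _resolve_columns(header: list[str], column_map: dict | None) -> dict:
    """Map canonical names to file columns via the synonym dictionary."""
    resolved: dict[str, str] = {}
    lower = {h.lower(): h for h in header}
    user = {k.upper(): v for k, v in (column_map or {}).items()}
    for canon, syns in COLUMN_SYNONYMS.items():
        if canon in user:
            if user[canon] not in header:
                raise ValueError(f"column_map names {user[canon]!r} which is not in the header")
            resolved[canon] = user[canon]
            continue
        for s in syns:
            if s in lower and lower[s] not in resolved.values():
                resolved[canon] = lower[s]
                break
    # a column literally named MAF must not shadow an explicit FRQ
    if "FRQ" in resolved and resolved["FRQ"].lower() == "maf" and "frq" in lower:
        resolved["FRQ"] = lower["frq"]
    return resolved


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a whitespace/tab-delimited summary-statistic file.

    Column names are resolved through a synonym dictionary (override with
    ``column_map``, e.g. ``{"BETA": "Effect"}``).  Odds ratios are converted to
    log-odds.  Rows with missing or non-numeric required fields and duplicate
    SNP ids are dropped and counted in ``df.attrs["log"]``.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    resolved = _resolve_columns(list(raw.columns), column_map)

    missing = [c for c in ("SNP", "A1", "A2") if c not in resolved]
    if missing or not any(c in resolved for c in ("BETA", "OR", "Z")):
        raise ValueError(
            f"could not resolve required columns {missing or ['BETA/OR/Z']} in header "
            f"{list(raw.columns)}; known synonyms: "
            + "; ".join(f"{k}: {v}" for k, v in COLUMN_SYNONYMS.items())
        )

    df = pd.DataFrame({canon: raw[col] for canon, col in resolved.items()})
    log = {"n_input": len(df)}

    for col in ("A1", "A2"):
        df[col] = df[col].str.upper()
    numeric = [c for c in ("CHR", "BP", "BETA", "OR", "Z", "SE", "N", "INFO", "FRQ") if c in df]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    effect_cols = [c for c in ("BETA", "OR", "Z") if c in df]
    required = ["SNP", "A1", "A2"] + ([effect_cols[0]] if effect_cols else [])
    before = len(df)
    df = df.dropna(subset=required)
    log["n_dropped_missing"] = before - len(df)

    if "OR" in df:
        if np.any(df["OR"] <= 0):
            bad = int((df["OR"] <= 0).sum())
            df = df[df["OR"] > 0]
            log["n_dropped_nonpositive_or"] = bad
        df["BETA"] = np.log(df["OR"])
        df = df.drop(columns=["OR"])

    before = len(df)
    df = df.drop_duplicates(subset="SNP", keep="first")
    log["n_duplicates"] = before - len(df)
    if log["n_duplicates"]:
        logger.info("dropped %d duplicate SNP ids", log["n_duplicates"])

    if "FRQ" in df:
        df["MAF"] = np.minimum(df["FRQ"], 1.0 - df["FRQ"])

    df = df.reset_index(drop=True)
    df.attrs["log"] = log
    return df


def _in_regions(df: pd.DataFrame, regions) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    if "CHR" not in df or "BP" not in df:
        return mask
    for chrom, start, end in regions:
        mask |= (df["CHR"] == chrom) & (df["BP"] >= start) & (df["BP"] <= end)
    return mask.to_numpy()


def munge(
    t: pd.DataFrame,
    snplist: pd.DataFrame,
    maf_min: float = 0.01,
    info_min: float = 0.9,
    exclude_regions=(MHC_REGION, APOE_REGION),
) -> pd.DataFrame:
    """Filter and allele-align a summary-statistic table for LDSC.

    Retains SNPs present in ``snplist`` (a HapMap3-style reference with columns
    ``SNP`` and optionally ``A1 A2``) with MAF >= ``maf_min`` and INFO >
    ``info_min`` (missing INFO retained), outside the excluded regions
    (defaults: MHC and the APOE block chr19:45,116,911-46,318,605, GRCh37
    1-based inclusive).  Alleles are aligned to the reference: reversed
    allele order flips the sign of BETA/Z, strand flips are resolved via
    complements, and strand-ambiguous A/T and C/G SNPs are dropped.
    """
    log: dict[str, int] = {"n_input": len(t)}
    df = t.copy()

    keep = ~_in_regions(df, exclude_regions or [])
    log["n_region_excluded"] = int((~keep).sum())
    df = df[keep]

    if "MAF" in df:
        ok = df["MAF"] >= maf_min
        log["n_maf_excluded"] = int((~ok).sum())
        df = df[ok]
    if "INFO" in df:
        ok = df["INFO"].isna() | (df["INFO"] > info_min)
        log["n_info_excluded"] = int((~ok).sum())
        df = df[ok]

    ambiguous = [a + b in {"AT", "TA", "CG", "GC"} for a, b in zip(df["A1"], df["A2"])]
    ambiguous = np.array(ambiguous, dtype=bool)
    log["n_ambiguous"] = int(ambiguous.sum())
    df = df[~ambiguous]

    valid = df["A1"].isin(COMPLEMENT) & df["A2"].isin(COMPLEMENT)
    log["n_invalid_alleles"] = int((~valid).sum())
    df = df[valid]

    ref = snplist.rename(columns=str.upper)
    if "SNP" not in ref:
        raise ValueError("snplist must have a SNP column")
    if "A1" in ref and "A2" in ref:
        merged = df.merge(ref[["SNP", "A1", "A2"]], on="SNP", suffixes=("", "_ref"))
        a1, a2 = merged["A1"].to_numpy(), merged["A2"].to_numpy()
        r1, r2 = merged["A1_ref"].str.upper().to_numpy(), merged["A2_ref"].str.upper().to_numpy()
        c1 = np.array([COMPLEMENT[a] for a in a1])
        c2 = np.array([COMPLEMENT[a] for a in a2])
        same = (a1 == r1) & (a2 == r2) | (c1 == r1) & (c2 == r2)
        flipped = (a1 == r2) & (a2 == r1) | (c1 == r2) & (c2 == r1)
        log["n_allele_mismatch"] = int((~(same | flipped)).sum())
        keep_mask = same | flipped
        merged = merged[keep_mask].copy()
        flip = flipped[keep_mask]
        for col in ("BETA", "Z"):
            if col in merged:
                merged.loc[flip, col] = -merged.loc[flip, col]
        if "FRQ" in merged:
            merged.loc[flip, "FRQ"] = 1.0 - merged.loc[flip, "FRQ"]
            merged["MAF"] = np.minimum(merged["FRQ"], 1.0 - merged["FRQ"])
        # express every record on the reference allele frame
        merged["A1"] = r1[keep_mask]
        merged["A2"] = r2[keep_mask]
        df = merged.drop(columns=["A1_ref", "A2_ref"])
    else:
        in_list = df["SNP"].isin(set(ref["SNP"]))
        log["n_not_in_snplist"] = int((~in_list).sum())
        df = df[in_list]

    if df.empty:
        raise ValueError("no SNPs remain after intersecting with the reference snplist")

    before = len(df)
    df = df.drop_duplicates(subset="SNP", keep="first")
    log["n_duplicates"] = before - len(df)
    log["n_retained"] = len(df)

    df = df.reset_index(drop=True)
    df.attrs["log"] = log
    return df


def standardize_effects(
    t: pd.DataFrame, meta: CohortMeta, ldsc_intercept: float = 1.0
) -> pd.DataFrame:
    """Rescale effects to per-allele units on a unit-variance (liability) outcome.

    The standardized effect is recovered from the association Z statistic as
    ``beta_std = z / sqrt(2 maf (1-maf) N_w)`` with ``N_w`` the cohort effective
    sample size (``4 v (1-v) n`` for binary traits, ``n`` for continuous), so
    that ``beta_std * 2 maf (1-maf)`` is an LDSC-consistent genetic covariance.
    When ``ldsc_intercept > 1`` standard errors are inflated by its square root
    (genomic-control style), shrinking Z accordingly.
    """
    df = t.copy()
    if meta.trait_type == "binary" and meta.sample_prevalence is None:
        raise ValueError("binary trait requires case/control counts for the prevalence")
    if "MAF" not in df:
        raise ValueError("standardize_effects requires a MAF column")
    if "Z" not in df or df["Z"].isna().all():
        if "BETA" not in df or "SE" not in df:
            raise ValueError("need Z, or BETA and SE, to standardize")
        df["Z"] = df["BETA"] / df["SE"]

    gc = np.sqrt(max(float(ldsc_intercept), 1.0))
    df["Z"] = df["Z"] / gc

    n = df["N"].to_numpy(dtype=float) if "N" in df and df["N"].notna().all() \
        else np.full(len(df), float(meta.n))
    if meta.trait_type == "binary":
        v = meta.sample_prevalence
        n_w = 4.0 * v * (1.0 - v) * n
    else:
        n_w = n
    var = snp_variance(df["MAF"].to_numpy())
    df["SE"] = 1.0 / np.sqrt(var * n_w)
    df["BETA"] = df["Z"] * df["SE"]
    df["N"] = n
    df.attrs["standardized"] = True
    df.attrs["gc_factor"] = gc
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a munged table in the fixed tab-delimited layout."""
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")
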