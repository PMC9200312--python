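import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proxymeta.sumstats import (
    CohortMeta,
    effective_n,
    munge,
    read_sumstats,
    snp_cov,
    snp_variance,
    standardize_effects,
)


def _write(tmp_path, text, name="ss.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSumstats:
    def test_odds_ratio_converted_to_log_odds(self, tmp_path):
        p = _write(tmp_path, "SNP A1 A2 OR SE N\nrs1 A G 1.0 0.1 100\nrs2 C T 2.0 0.1 100\n")
        t = read_sumstats(p)
        assert t.loc[0, "BETA"] == 0.0
        assert t.loc[1, "BETA"] == pytest.approx(np.log(2.0))
        assert "OR" not in t.columns

    def test_zscore_only_table(self, tmp_path):
        p = _write(tmp_path, "SNP A1 A2 Zscore N\nrs1 A G 1.5 100\n")
        t = read_sumstats(p)
        assert t.loc[0, "Z"] == 1.5
        assert "BETA" not in t.columns and "SE" not in t.columns

    def test_duplicates_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path, "SNP A1 A2 BETA SE N\nrs1 A G .1 .1 9\nrs2 A G .2 .1 9\nrs1 A G .3 .1 9\n")
        t = read_sumstats(p)
        assert len(t) == 2
        assert t.attrs["log"]["n_duplicates"] == 1

    def test_nonnumeric_effect_rows_rejected(self, tmp_path):
        p = _write(tmp_path, "SNP A1 A2 BETA SE N\nrs1 A G .1 .1 9\nrs2 A G xx .1 9\n")
        t = read_sumstats(p)
        assert len(t) == 1
        assert t.attrs["log"]["n_dropped_missing"] == 1

    def test_unresolvable_column_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "FOO BAR\n1 2\n")
        with pytest.raises(ValueError, match="synonym"):
            read_sumstats(p)


def _toy_table():
    # 10 SNPs: 2 strand-ambiguous (A/T, C/G), 1 inside the MHC
    rows = []
    for i in range(10):
        a1, a2 = ("A", "G") if i not in (3, 7) else (("A", "T") if i == 3 else ("C", "G"))
        chrom, bp = (6, 30_000_000) if i == 5 else (1, 1_000_000 + i)
        rows.append(dict(SNP=f"rs{i}", CHR=chrom, BP=bp, A1=a1, A2=a2,
                         FRQ=0.3, MAF=0.3, INFO=0.99, BETA=0.1, SE=0.05, Z=2.0, N=1000))
    return pd.DataFrame(rows)


def _ref(snps, a1="A", a2="G"):
    return pd.DataFrame({"SNP": snps, "A1": a1, "A2": a2})


class TestMunge:
    def test_apoe_region_excluded(self):
        t = _toy_table()
        t.loc[0, ["CHR", "BP"]] = [19, 45_500_000]
        out = munge(t, _ref([f"rs{i}" for i in range(10)]))
        assert "rs0" not in set(out["SNP"])

    def test_maf_threshold_is_inclusive(self):
        t = _toy_table()
        t.loc[0, ["FRQ", "MAF"]] = 0.009
        t.loc[1, ["FRQ", "MAF"]] = 0.010
        out = munge(t, _ref([f"rs{i}" for i in range(10)]))
        assert "rs0" not in set(out["SNP"]) and "rs1" in set(out["SNP"])

    def test_toy_counts(self):
        out = munge(_toy_table(), _ref([f"rs{i}" for i in range(10)]))
        assert len(out) == 7
        assert out.attrs["log"]["n_ambiguous"] == 2
        assert out.attrs["log"]["n_region_excluded"] == 1

    def test_idempotent(self):
        once = munge(_toy_table(), _ref([f"rs{i}" for i in range(10)]))
        twice = munge(once, _ref([f"rs{i}" for i in range(10)]))
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True), check_dtype=False
        )

    def test_reversed_alleles_flip_sign(self):
        t = _toy_table()
        ref = _ref([f"rs{i}" for i in range(10)], a1="G", a2="A")
        out = munge(t, ref)
        assert np.allclose(out["BETA"], -0.1)
        assert (out["A1"] == "G").all()

    def test_empty_intersection_is_hard_error(self):
        with pytest.raises(ValueError, match="no SNPs"):
            munge(_toy_table(), _ref(["rsX"]))

    def test_missing_info_retained(self):
        t = _toy_table()
        t.loc[1, "INFO"] = np.nan
        out = munge(t, _ref([f"rs{i}" for i in range(10)]))
        assert "rs1" in set(out["SNP"])


class TestStandardize:
    def _meta(self):
        return CohortMeta(trait_type="binary", n_cases=500, n_controls=500)

    def test_unit_intercept_leaves_z(self):
        t = _toy_table()
        out = standardize_effects(t, self._meta(), ldsc_intercept=1.0)
        assert np.allclose(out["Z"], t["Z"])

    def test_gc_inflation_shrinks_z(self):
        t = _toy_table()
        out = standardize_effects(t, self._meta(), ldsc_intercept=1.21)
        assert np.allclose(out["Z"], t["Z"] / 1.1)
        # intercepts below 1 are not deflated
        out2 = standardize_effects(t, self._meta(), ldsc_intercept=0.9)
        assert np.allclose(out2["Z"], t["Z"])

    def test_binary_standardization_constant_ratio(self):
        # ratio standardized/raw logistic beta is SNP-independent at fixed v
        t = _toy_table()
        t.loc[0, "MAF"] = 0.1
        t.loc[1, "MAF"] = 0.4
        # logistic-style SEs proportional to 1/sqrt(2maf(1-maf) v(1-v) n)
        v = 0.5
        se = 1.0 / np.sqrt(2 * t["MAF"] * (1 - t["MAF"]) * v * (1 - v) * t["N"])
        t["SE"] = se
        t["Z"] = t["BETA"] / t["SE"]
        out = standardize_effects(t, self._meta())
        ratio = out["BETA"] / t["BETA"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_missing_prevalence_is_error(self):
        with pytest.raises(ValueError):
            CohortMeta(trait_type="binary", n_cases=None, n_controls=None)


class TestSnpCov:
    def test_zero_beta(self):
        assert snp_cov(0.0, 0.3) == 0.0

    def test_snp_variance_values(self):
        assert snp_variance(0.5) == pytest.approx(0.5)
        assert snp_variance(0.305) == pytest.approx(0.42395)

    def test_maf_domain(self):
        with pytest.raises(ValueError):
            snp_variance(0.6)
        with pytest.raises(ValueError):
            snp_variance(0.0)


class TestEffectiveN:
    def test_balanced_cohort(self):
        c = CohortMeta(trait_type="binary", n_cases=500, n_controls=500)
        assert effective_n([c]) == pytest.approx(1000.0)

    def test_igap_like(self):
        c = CohortMeta(trait_type="binary", n_cases=21_982, n_controls=41_944)
        assert effective_n([c]) == pytest.approx(4 * 0.34386 * (1 - 0.34386) * 63_926, rel=1e-3)
        assert effective_n([c]) == pytest.approx(57_704, rel=2e-3)

    def test_two_cohorts(self):
        a = CohortMeta(trait_type="binary", n_cases=50, n_controls=50)
        b = CohortMeta(trait_type="binary", n_cases=10, n_controls=90)
        assert effective_n([a, b]) == pytest.approx(136.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 0.99))
    def test_maximized_at_half(self, v):
        c = CohortMeta(trait_type="binary", n_cases=int(v * 10_000), n_controls=int((1 - v) * 10_000))
        ref = CohortMeta(trait_type="binary", n_cases=5_000, n_controls=5_000)
        assert effective_n([c]) <= effective_n([ref]) + 1e-9
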