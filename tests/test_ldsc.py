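import numpy as np
import pandas as pd
import pytest

from proxymeta.ldsc import bivariate_ldsc, multivariate_ldsc, univariate_ldsc
from proxymeta.ldscore import LDScoreTable, load_ldscores, save_ldscores
from proxymeta.simulate import simulate_zstats, synth_ldscores


def _table_from_z(ld, z, n):
    return pd.DataFrame({"SNP": ld.df["SNP"], "Z": z, "N": float(n)})


def _simulate_univariate(ld, h2, n, a=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    l2 = ld.df["L2"].to_numpy()
    sd = np.sqrt(1.0 + a + n * h2 * l2 / ld.m)
    return _table_from_z(ld, rng.standard_normal(len(l2)) * sd, n)


class TestUnivariate:
    def test_null_recovers_zero_heritability_and_unit_intercept(self, ld20k):
        rng = np.random.default_rng(1)
        t = _table_from_z(ld20k, rng.standard_normal(len(ld20k.df)), 1e5)
        res = univariate_ldsc(t, ld20k)
        assert abs(res.h2_obs) < 3 * res.h2_se
        assert abs(res.intercept - 1.0) < 3 * res.intercept_se

    def test_recovers_simulated_heritability(self, ld20k):
        t = _simulate_univariate(ld20k, 0.5, 1e5, rng=np.random.default_rng(2))
        res = univariate_ldsc(t, ld20k)
        assert res.h2_obs == pytest.approx(0.5, abs=2 * res.h2_se)

    def test_duplicated_rows_leave_estimate_unchanged(self, ld20k):
        t = _simulate_univariate(ld20k, 0.3, 1e5, rng=np.random.default_rng(3))
        res1 = univariate_ldsc(t, ld20k)
        dup_ld = LDScoreTable(
            df=pd.concat([ld20k.df, ld20k.df.assign(SNP=ld20k.df["SNP"] + "b")],
                         ignore_index=True),
            m=ld20k.m,
        )
        t2 = pd.concat([t, t.assign(SNP=t["SNP"] + "b")], ignore_index=True)
        res2 = univariate_ldsc(t2, dup_ld)
        assert res2.h2_obs == pytest.approx(res1.h2_obs, rel=5e-2)

    def test_too_few_snps_for_blocks_is_error(self, ld20k):
        t = _simulate_univariate(ld20k, 0.3, 1e5).head(300)
        with pytest.raises(ValueError):
            univariate_ldsc(t, ld20k, n_blocks=200)

    def test_m_prefilter_scales_estimate_exactly(self, ld20k):
        t = _simulate_univariate(ld20k, 0.2, 1e5, rng=np.random.default_rng(4))
        res_post = univariate_ldsc(t, ld20k)
        ld_pre = LDScoreTable(df=ld20k.df, m=ld20k.m * 1.3)
        res_pre = univariate_ldsc(t, ld_pre)
        assert res_pre.h2_obs / res_post.h2_obs == pytest.approx(1.3, rel=1e-9)


class TestBivariate:
    def test_self_covariance_equals_h2(self, ld20k):
        t = _simulate_univariate(ld20k, 0.4, 1e5, rng=np.random.default_rng(5))
        uni = univariate_ldsc(t, ld20k)
        bi = bivariate_ldsc(t, t.copy(), ld20k)
        assert bi.gencov == pytest.approx(uni.h2_obs, rel=1e-6)
        assert bi.intercept == pytest.approx(1.0, abs=3 * bi.intercept_se)

    def test_independent_traits_have_zero_gencov_and_intercept(self, ld20k):
        rng = np.random.default_rng(6)
        t1 = _simulate_univariate(ld20k, 0.3, 1e5, rng=rng)
        t2 = _simulate_univariate(ld20k, 0.3, 1e5, rng=rng)
        bi = bivariate_ldsc(t1, t2, ld20k)
        assert abs(bi.gencov) < 2.5 * bi.gencov_se
        assert abs(bi.intercept) < 3 * bi.intercept_se

    def test_recovers_simulated_covariance(self, ld20k, registry):
        cond = registry["cond1"]
        tabs = simulate_zstats(cond, ld20k, seed=np.random.default_rng(7))
        bi = bivariate_ldsc(tabs[0], tabs[1], ld20k)
        truth = 0.5 * cond.h2_F
        assert bi.gencov == pytest.approx(truth, abs=2 * bi.gencov_se)

    def test_insufficient_overlap_is_error(self, ld20k):
        t1 = _simulate_univariate(ld20k, 0.3, 1e5).head(50)
        with pytest.raises(ValueError, match="shared"):
            bivariate_ldsc(t1, t1.copy(), ld20k)


class TestMultivariate:
    def test_k1_reduces_to_univariate(self, ld20k):
        t = _simulate_univariate(ld20k, 0.25, 1e5, rng=np.random.default_rng(8))
        uni = univariate_ldsc(t, ld20k)
        gcs = multivariate_ldsc([t], ld20k)
        assert gcs.S[0, 0] == pytest.approx(uni.h2_obs, rel=1e-12)
        assert np.sqrt(gcs.V[0, 0]) == pytest.approx(uni.h2_se, rel=1e-12)

    def test_independent_traits_have_near_zero_cross_intercepts(self, ld20k):
        rng = np.random.default_rng(9)
        tabs = [_simulate_univariate(ld20k, 0.1, 2e5, rng=rng) for _ in range(3)]
        gcs = multivariate_ldsc(tabs, ld20k)
        off = [(1, 0), (2, 0), (2, 1)]
        for i, j in off:
            assert abs(gcs.intercepts[i, j]) < 3 * gcs.intercept_ses[i, j]

    def test_v_diagonal_matches_pairwise_jackknife(self, ld20k, registry):
        tabs = simulate_zstats(registry["cond1"], ld20k, seed=np.random.default_rng(10))
        gcs = multivariate_ldsc(tabs, ld20k)
        bi = bivariate_ldsc(tabs[0], tabs[1], ld20k)
        # vech order (00,10,11,20,21,22): cross pair direct-maternal is index 1
        assert np.sqrt(gcs.V[1, 1]) == pytest.approx(bi.gencov_se, rel=1e-9)

    def test_liability_conversion_applied_per_trait(self, ld20k, registry):
        cond = registry["cond1_binary"]
        tabs = simulate_zstats(cond, ld20k, seed=np.random.default_rng(11))
        g_obs = multivariate_ldsc(tabs, ld20k)
        g_lia = multivariate_ldsc(tabs, ld20k, prevalences=cond.prevalences())
        f = cond.liability_factors()
        assert g_lia.S == pytest.approx(g_obs.S * np.outer(f, f), rel=1e-12)

class TestOptions:
    def test_chisq_max_drops_exactly_the_extreme_snps(self, ld20k):
        rng = np.random.default_rng(21)
        t = _table_from_z(ld20k, rng.standard_normal(len(ld20k.df)), 1e5)
        t.loc[0, "Z"] = 40.0  # one extreme statistic
        res_filt = multivariate_ldsc([t], ld20k, chisq_max=80.0)
        res_manual = multivariate_ldsc([t.iloc[1:]], ld20k)
        assert res_filt.S[0, 0] == pytest.approx(res_manual.S[0, 0], rel=1e-12)
        # a threshold above every statistic is a no-op
        res_noop = multivariate_ldsc([t], ld20k, chisq_max=1e9)
        res_all = multivariate_ldsc([t], ld20k)
        assert res_noop.S[0, 0] == pytest.approx(res_all.S[0, 0], rel=1e-12)

    def test_chisq_max_removing_everything_is_error(self, ld20k):
        t = _simulate_univariate(ld20k, 0.3, 1e5, rng=np.random.default_rng(22))
        with pytest.raises(ValueError, match="chisq_max"):
            multivariate_ldsc([t], ld20k, chisq_max=1e-6)

    def test_one_step_weights_agree_with_iterated(self, ld20k):
        # both weighting schemes are consistent; estimates differ only within
        # a few SEs on the same data
        t = _simulate_univariate(ld20k, 0.4, 1e5, rng=np.random.default_rng(23))
        one = multivariate_ldsc([t], ld20k, weight_iterations=1)
        two = multivariate_ldsc([t], ld20k, weight_iterations=2)
        assert one.S[0, 0] == pytest.approx(two.S[0, 0], abs=3 * np.sqrt(two.V[0, 0]))


class TestLdscoreIO:
    def test_roundtrip_with_m_file(self, tmp_path):
        ld = synth_ldscores(12_000, seed=5)
        ld.m = 15_000.0
        path = tmp_path / "scores.tsv"
        save_ldscores(ld, path)
        back = load_ldscores(path)
        assert back.m == 15_000.0
        assert back.m_post == float(len(ld.df))
        assert np.allclose(back.df["L2"], ld.df["L2"], atol=1e-4)
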