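import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from proxymeta.ldsc import multivariate_ldsc
from proxymeta.sem import fit_dwls
from proxymeta.simulate import (
    SimulationCondition,
    simulate_snp_effect,
    simulate_zstats,
    synth_ldscores,
)
from proxymeta.snpgwas import (
    estimate_gamma,
    expand_matrices,
    meta_neff,
    q_snp,
    run_multivariate_gwas,
)


LAMBDAS = np.array([1.0, 0.463, 0.366])


def _expanded(exact_gcs, betas, ses, maf=0.3):
    return expand_matrices(exact_gcs, list(zip(betas, ses)), maf)


class TestExpandMatrices:
    def test_zero_betas_give_zero_covariances(self, exact_gcs):
        S_full, _ = _expanded(exact_gcs, [0, 0, 0], [0.01, 0.01, 0.01])
        assert np.allclose(S_full[1:, 0], 0.0)

    def test_covariance_is_beta_times_snp_variance(self, exact_gcs):
        S_full, _ = _expanded(exact_gcs, [0.1, 0, 0], [0.01] * 3, maf=0.5)
        assert S_full[0, 0] == pytest.approx(0.5)
        assert S_full[1, 0] == pytest.approx(0.05)

    def test_zero_cross_intercepts_give_diagonal_snp_block(self, exact_gcs):
        _, V_full = _expanded(exact_gcs, [0.1, 0.05, 0.04], [0.01, 0.02, 0.03])
        # snp-trait elements sit at vech positions (1,0)=1, (2,0)=3, (3,0)=6
        snp_pos = [1, 3, 6]
        block = V_full[np.ix_(snp_pos, snp_pos)]
        assert np.allclose(block - np.diag(np.diag(block)), 0.0)


class TestEstimateGamma:
    def test_proportional_pattern_recovers_gamma(self, exact_gcs):
        gamma = 0.07
        betas = gamma * LAMBDAS
        S_full, V_full = _expanded(exact_gcs, betas, [0.01] * 3)
        g, se = estimate_gamma(S_full, V_full, (LAMBDAS, np.zeros(3)))
        assert g == pytest.approx(gamma, rel=1e-10)
        assert se > 0

    def test_uninformative_proxies_reduce_to_direct_beta(self, exact_gcs):
        betas = [0.05, 0.4, -0.3]
        S_full, V_full = _expanded(exact_gcs, betas, [0.01, 1e4, 1e4])
        g, _ = estimate_gamma(S_full, V_full, (LAMBDAS, np.zeros(3)))
        assert g == pytest.approx(0.05, abs=1e-6)

    def test_snp_effect_recovery_across_replicates(self, registry):
        # known per-allele effect on F; mean estimate within 2 MC-SEs
        cond = registry["cond3_binary"]
        gammas = []
        rng = np.random.default_rng(99)
        for _ in range(500):
            beta_obs, se, _ = simulate_snp_effect(cond, gamma=0.068, maf=0.305, seed=rng)
            w = LAMBDAS / se**2
            gammas.append(float((w * beta_obs).sum() / (w * LAMBDAS).sum()))
        gammas = np.array(gammas)
        mc_se = gammas.std(ddof=1) / np.sqrt(len(gammas))
        assert gammas.mean() == pytest.approx(0.068, abs=2 * mc_se)


class TestQSnp:
    def test_zero_under_exact_proportionality(self, exact_gcs):
        betas = 0.07 * LAMBDAS
        S_full, V_full = _expanded(exact_gcs, betas, [0.01] * 3)
        q, df, p = q_snp(S_full, V_full, (LAMBDAS, np.zeros(3)))
        assert q == pytest.approx(0.0, abs=1e-10)
        assert df == 2 and p == pytest.approx(1.0)

    def test_direct_only_signal_is_heterogeneous(self, exact_gcs):
        S_full, V_full = _expanded(exact_gcs, [0.1, 0.0, 0.0], [0.005] * 3)
        q, df, p = q_snp(S_full, V_full, (LAMBDAS, np.zeros(3)))
        assert p < 0.05

    def test_matches_brute_force_discrepancy_difference(self, exact_gcs):
        # Q as the explicit difference between common-pathway and saturated
        # GLS discrepancies, minimised numerically
        betas, ses = np.array([0.08, 0.01, 0.05]), np.array([0.01, 0.02, 0.015])
        S_full, V_full = _expanded(exact_gcs, betas, ses, maf=0.3)
        var = S_full[0, 0]
        s = S_full[1:, 0]
        Vb = np.diag((ses * var) ** 2)  # intercepts are zero here
        Vi = np.linalg.inv(Vb)
        u = LAMBDAS * var

        def disc(g):
            r = s - g[0] * u
            return float(r @ Vi @ r)

        res = optimize.minimize_scalar(lambda g: disc([g]))
        q, _, _ = q_snp(S_full, V_full, (LAMBDAS, np.zeros(3)))
        assert q == pytest.approx(res.fun, rel=1e-8)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.1, 10.0))
    def test_invariant_to_common_rescaling(self, scale):
        from proxymeta.ldsc import GenCovStructure
        from proxymeta.sem import implied_sigma

        S = implied_sigma([1.0, 0.463, 0.366], 0.073, [0.0, 0.0, 0.0])
        gcs = GenCovStructure(S=S, V=np.eye(6) * 1e-6, intercepts=np.eye(3),
                              labels=list("abc"))
        betas, ses = np.array([0.08, 0.01, 0.05]), np.array([0.01, 0.02, 0.015])
        a, Va = _expanded(gcs, betas, ses)
        b, Vb = _expanded(gcs, betas * scale, ses * scale)
        qa, _, _ = q_snp(a, Va, (LAMBDAS, np.zeros(3)))
        qb, _, _ = q_snp(b, Vb, (LAMBDAS, np.zeros(3)))
        assert qa == pytest.approx(qb, rel=1e-9)


class TestMetaNeff:
    def test_zero_proxy_loadings(self):
        assert meta_neff([100, 100, 100], [1, 0, 0]) == 100

    def test_standard_loadings(self):
        assert meta_neff([100, 100, 100], [1, 0.5, 0.5]) == pytest.approx(150.0)

    def test_empirical_cohort_plug_in(self, registry):
        neff = registry["cond3_binary"].effective_ns()
        out = meta_neff(neff, [1, 0.463, 0.366])
        assert out == pytest.approx(neff[0] + 0.463**2 * neff[1] + 0.366**2 * neff[2])
        assert out > neff[0]


class TestRunMultivariateGwas:
    def test_null_calibration_of_gamma_z(self, registry):
        # no genetic signal anywhere: z statistics should not be inflated
        cond = SimulationCondition(name="zero", lambdas=(1, 0.5, 0.5), h2_F=0.0,
                                   trait_type="binary", vs=(0.344, 0.096, 0.055))
        ld = synth_ldscores(20_000, seed=17)
        from scipy import stats
        lam_gcs = []
        for r in range(3):
            tabs = simulate_zstats(cond, ld, seed=np.random.default_rng([17, r]))
            gcs = multivariate_ldsc(tabs, ld, prevalences=cond.prevalences())
            out = run_multivariate_gwas(tabs, gcs, fit_dwls(gcs))
            lam_gcs.append(np.median(out["Z"] ** 2) / stats.chi2.ppf(0.5, 1))
        assert 0.95 <= np.mean(lam_gcs) <= 1.05

    def test_mean_q_near_df_under_homogeneity(self, ld20k, registry):
        cond = registry["cond1"]
        tabs = simulate_zstats(cond, ld20k, seed=np.random.default_rng(18))
        gcs = multivariate_ldsc(tabs, ld20k)
        out = run_multivariate_gwas(tabs, gcs, fit_dwls(gcs))
        assert out["Q_SNP"].mean() == pytest.approx(out["Q_DF"].iloc[0], rel=0.05)

    def test_snp_missing_from_one_trait_is_skipped(self, ld20k, registry):
        tabs = simulate_zstats(registry["cond1"], ld20k, seed=np.random.default_rng(19))
        tabs[1] = tabs[1].iloc[5:].reset_index(drop=True)
        gcs = multivariate_ldsc(tabs, ld20k)
        out = run_multivariate_gwas(tabs, gcs, fit_dwls(gcs))
        assert out.attrs["log"]["n_missing_any_trait"] == 5
        assert len(out) == len(ld20k.df) - 5

    def test_neff_constant_and_matches_formula(self, ld20k, registry):
        cond = registry["cond3_binary"]
        tabs = simulate_zstats(cond, ld20k, seed=np.random.default_rng(20))
        gcs = multivariate_ldsc(tabs, ld20k, prevalences=cond.prevalences())
        fit = fit_dwls(gcs)
        out = run_multivariate_gwas(tabs, gcs, fit)
        assert out["NEFF"].nunique() == 1
        assert out["NEFF"].iloc[0] == pytest.approx(
            meta_neff(cond.effective_ns(), fit.lambdas), rel=1e-6
        )
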