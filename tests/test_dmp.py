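"""DMP stage: M-transform, per-probe OLS, variance moderation,
empirical-null correction and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lifemeth.dmp import (
    adjust_fdr,
    beta_to_mvalue,
    build_design,
    compute_delta_beta,
    DesignError,
    estimate_empirical_null,
    fit_probe_models,
    moderate_statistics,
    run_dmp_ewas,
)


class TestBetaToMvalue:
    def test_half_maps_to_zero(self):
        assert beta_to_mvalue(0.5) == pytest.approx(0.0)

    def test_point_eight_maps_to_two(self):
        assert beta_to_mvalue(0.8) == pytest.approx(2.0)

    def test_boundary_clipped_to_finite(self):
        m = beta_to_mvalue(0.0, epsilon=1e-6)
        assert np.isfinite(m) and m < 0
        assert np.isfinite(beta_to_mvalue(1.0, epsilon=1e-6))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_mvalue(1.2)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.001, 0.999))
    def test_antisymmetry(self, b):
        assert beta_to_mvalue(b) == pytest.approx(-beta_to_mvalue(1 - b), abs=1e-9)


class TestProbeOLS:
    def test_exact_fit(self):
        X = pd.DataFrame({"intercept": [1.0] * 4, "cli_index": [0.0, 0, 1, 1]})
        M = np.array([[0.0, 0.0, 1.0, 1.0]])
        coef, se_unit, sigma2, df = fit_probe_models(M, X, "cli_index")
        assert coef[0] == pytest.approx(1.0)
        assert sigma2[0] == pytest.approx(0.0, abs=1e-20)

    def test_constant_probe(self):
        X = pd.DataFrame({"intercept": [1.0] * 4, "cli_index": [0.0, 0, 1, 1]})
        M = np.full((1, 4), 3.7)
        coef, _, sigma2, _ = fit_probe_models(M, X, "cli_index")
        assert coef[0] == pytest.approx(0.0, abs=1e-12)
        assert sigma2[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self):
        """50 random probes against the direct (XᵀX)⁻¹Xᵀy solution."""
        rng = np.random.default_rng(5)
        n, k, probes = 30, 4, 50
        X = pd.DataFrame(
            np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(size=(n, k - 2))]),
            columns=["intercept", "cli_index", "c1", "c2"],
        )
        M = rng.normal(size=(probes, n))
        coef, se_unit, sigma2, df = fit_probe_models(M, X, "cli_index")
        Xn = X.to_numpy()
        xtx_inv = np.linalg.inv(Xn.T @ Xn)
        assert df == n - k
        for g in range(probes):
            b = xtx_inv @ Xn.T @ M[g]
            assert coef[g] == pytest.approx(b[1], abs=1e-8)
            r = M[g] - Xn @ b
            assert sigma2[g] == pytest.approx(r @ r / (n - k), abs=1e-8)
        assert se_unit == pytest.approx(np.sqrt(xtx_inv[1, 1]), abs=1e-12)

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame(
            {"intercept": [1.0] * 5, "cli_index": [0.0, 1, 0, 1, 0],
             "dup": [0.0, 1, 0, 1, 0]}
        )
        with pytest.raises(DesignError, match="dup|cli_index"):
            fit_probe_models(np.zeros((2, 5)), X, "cli_index")


class TestModeration:
    def test_prior_parameters_recovered_from_simulated_variances(self):
        """sigma² ~ s0²·χ²_d0/d0 with d0=4, s0=2 refits inside the band."""
        rng = np.random.default_rng(11)
        d0, s0, df = 4.0, 2.0, 20
        n_probes = 5000
        true_var = s0**2 * d0 / rng.chisquare(d0, n_probes)  # inv-chi2 prior
        s2 = true_var * rng.chisquare(df, n_probes) / df
        coef = rng.normal(size=n_probes)
        _, df_total, d0_hat, s02_hat, _ = moderate_statistics(s2, df, coef, 1.0)
        assert 3.0 <= d0_hat <= 5.0
        assert 1.8 <= np.sqrt(s02_hat) <= 2.2
        assert df_total == pytest.approx(df + d0_hat)

    def test_posterior_variances_shrink_toward_prior(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(10, 2000) / 10
        coef = rng.normal(size=2000)
        _, _, d0, s02, s2_post = moderate_statistics(s2, 10, coef, 1.0)
        # moderation pulls extremes toward s0²
        assert s2_post.max() <= s2.max()
        assert s2_post.min() >= s2.min()
        lo = s2 < s02
        assert np.all(s2_post[lo] >= s2[lo])
        assert np.all(s2_post[~lo] <= s2[~lo])

    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 2.0)
        coef = np.ones(100)
        t, df_total, d0, s02, s2_post = moderate_statistics(s2, 15, coef, 1.0)
        assert np.isinf(d0)
        assert np.allclose(s2_post, s02)


class TestEmpiricalNull:
    def test_exact_null_grid(self):
        z = stats.norm.ppf((np.arange(1, 10001) - 0.5) / 10000)
        null = estimate_empirical_null(z)
        assert abs(null.bias_mu) < 0.02
        assert null.inflation_sigma == pytest.approx(1.0, abs=0.02)

    def test_inflation_recovered(self):
        rng = np.random.default_rng(3)
        null = estimate_empirical_null(rng.normal(0, 1.5, 20000))
        assert null.inflation_sigma == pytest.approx(1.5, rel=0.05)

    def test_bias_recovered(self):
        rng = np.random.default_rng(4)
        null = estimate_empirical_null(rng.normal(0.5, 1.0, 20000))
        assert null.bias_mu == pytest.approx(0.5, abs=0.05)

    def test_too_few_statistics_rejected(self):
        with pytest.raises(ValueError):
            estimate_empirical_null(np.zeros(10))


def brute_force_bh(p):
    """Quadratic-time BH oracle: q_i = min over p_j >= p_i of p_j*m/rank_j."""
    p = np.asarray(p, float)
    m = p.size
    ranks = np.argsort(np.argsort(p, kind="mergesort"), kind="mergesort") + 1
    # average-free: rank of p_j is its 1-based position in the sorted order
    order = np.argsort(p, kind="mergesort")
    rank_of = np.empty(m, int)
    rank_of[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        vals = [p[j] * m / rank_of[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(vals))
    return q


class TestFDR:
    def test_single_pvalue_unchanged(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_equally_spaced_example(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(adjust_fdr(np.ones(7)), 1.0)

    def test_empty(self):
        assert adjust_fdr([]).size == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [1, 5, 37, 100])
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.random(n)
        if seed % 2:  # exercise ties
            p = np.round(p, 1)
        assert np.allclose(adjust_fdr(p), brute_force_bh(p), atol=1e-12)


class TestDeltaBeta:
    def test_identical_groups_give_zero(self):
        b = np.tile(np.array([[0.3, 0.3, 0.3, 0.3]]), (2, 1))
        assert np.allclose(compute_delta_beta(b, [1, 1, 0, 0]), 0.0)

    def test_hand_computed_difference(self):
        b = np.array([[0.30, 0.30, 0.32, 0.32]])
        # high-risk (index 1) minus low-risk means
        assert compute_delta_beta(b, [1, 1, 0, 0])[0] == pytest.approx(-0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_delta_beta(np.zeros((1, 3)), [1, 1, 1])


class TestRunDMP:
    def test_probe_order_invariance(self, null_bundle):
        _, pheno, meth, _ = null_bundle
        res1 = run_dmp_ewas(meth, pheno)
        shuffled = meth.beta.sample(frac=1, random_state=1)
        from lifemeth.io import MethylationData

        meth2 = MethylationData(beta=shuffled, annotation=meth.annotation)
        res2 = run_dmp_ewas(meth2, pheno)
        merged = res1.set_index("probe_id").join(
            res2.set_index("probe_id"), rsuffix="_2"
        )
        assert np.allclose(merged["coef_m"], merged["coef_m_2"])
        assert np.allclose(merged["fdr"], merged["fdr_2"])

    def test_effect_signs_agree_across_scales(self, spiked_bundle):
        """M-scale coefficient and beta-scale delta share a sign at spiked
        probes (shift alternatives move both the same way)."""
        _, pheno, meth, truth = spiked_bundle
        res = run_dmp_ewas(meth, pheno).set_index("probe_id")
        hits = res.loc[truth.spiked_probe_ids]
        agree = np.sign(hits["coef_m"]) == np.sign(hits["delta_beta"])
        assert agree.mean() >= 0.99

    def test_spiked_probes_dominate_ranking(self, spiked_bundle):
        _, pheno, meth, truth = spiked_bundle
        res = run_dmp_ewas(meth, pheno)
        top = set(res["probe_id"].head(2 * len(truth.spiked_probe_ids)))
        assert set(truth.spiked_probe_ids) <= top
        byid = res.set_index("probe_id")
        assert (byid.loc[truth.spiked_probe_ids, "fdr"] < 0.05).all()

    def test_sample_mismatch_raises(self, null_bundle):
        _, pheno, meth, _ = null_bundle
        bad = pheno.rename(index={pheno.index[0]: "impostor"})
        with pytest.raises(Exception, match="impostor"):
            run_dmp_ewas(meth, bad)

    def test_bmi_model_adds_column(self, null_bundle):
        _, pheno, _, _ = null_bundle
        base = build_design(pheno, include_bmi=False)
        adj = build_design(pheno, include_bmi=True)
        assert "bmi" in adj.columns and "bmi" not in base.columns
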