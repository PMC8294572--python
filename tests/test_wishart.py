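import numpy as np
import pytest
from scipy import stats

from krpower.design import cluster_mean_recast
from krpower.wishart import (
    InverseWishartTerm,
    WishartMatchError,
    check_positive_definite_sum,
    contrast_wishart,
    match_single_inverse_wishart,
    mc_inverse_wishart_sum,
    selection_term,
    terms_from_design,
)

from conftest import oral_cancer_member_design, random_spd


def random_term(rng, p, K, n_blocks=2, df=None):
    df = df if df is not None else p + 4 + rng.integers(3, 30)
    blocks = tuple(
        (rng.standard_normal((p, K)), int(rng.integers(1, 4))) for _ in range(n_blocks)
    )
    return InverseWishartTerm(df=float(df), scale=random_spd(rng, p), blocks=blocks)


class TestTermMoments:
    def test_scalar_closed_form(self):
        # S ~ W_1(nu, v): S^-1 = 1/(v chi2_nu); mean 1/(v(nu-2)),
        # var 2/(v^2 (nu-2)^2 (nu-4))
        nu, v = 12.0, 2.5
        t = InverseWishartTerm(df=nu, scale=[[v]], blocks=((np.array([[1.0]]), 1),))
        assert np.isclose(t.mean()[0, 0], 1.0 / (v * (nu - 2.0)), rtol=1e-12)
        assert np.isclose(
            t.trace_variance(), 2.0 / (v**2 * (nu - 2.0) ** 2 * (nu - 4.0)), rtol=1e-12
        )

    def test_trace_identity_for_selection_weights(self, rng):
        # selection-type mapping: tr(X' S^-1 X) = tr(S^-1) for every draw
        term = selection_term(q=2, p=3, i=2, indices=(1, 3), df=12.0, scale=random_spd(rng, 2))
        X = term.blocks[0][0]
        draws = stats.wishart.rvs(df=term.df, scale=term.scale, size=200, random_state=rng)
        for S in draws:
            S_inv = np.linalg.inv(S)
            assert np.isclose(np.trace(X.T @ S_inv @ X), np.trace(S_inv), rtol=1e-12)

    @pytest.mark.parametrize("p,K", [(1, 1), (2, 2), (3, 2)])
    def test_moments_match_sampling_oracle(self, p, K, rng):
        term = random_term(rng, p, K)
        mc = mc_inverse_wishart_sum([term], draws=40_000, seed=rng)
        assert np.all(np.abs(mc["mean"] - term.mean()) <= 4.0 * mc["mean_se"] + 1e-12)
        assert abs(mc["trace_var"] - term.trace_variance()) <= 4.0 * mc["trace_var_se"]

    def test_df_too_small_rejected(self):
        with pytest.raises(WishartMatchError):
            InverseWishartTerm(df=4.0, scale=np.eye(2), blocks=((np.eye(2), 1),))


class TestMatch:
    def test_single_complete_term_is_fixed_point(self, rng):
        scale = random_spd(rng, 3)
        term = InverseWishartTerm(df=20.0, scale=scale, blocks=((np.eye(3), 2),))
        m = match_single_inverse_wishart([term])
        assert m.diagnostics["fixed_point"]
        assert m.df == 20.0
        assert np.allclose(m.sigma_star, scale / 2.0, rtol=1e-12)

    def test_scalar_sum_matches_inverse_chisquare_family(self, rng):
        # K = 1: the matched law is a scaled inverse chi-square whose first
        # two moments equal the analytic moments of the sum
        terms = [random_term(rng, 1, 1) for _ in range(3)]
        m = match_single_inverse_wishart(terms)
        mean = sum(t.mean()[0, 0] for t in terms)
        var = sum(t.trace_variance() for t in terms)
        nu = m.df
        v = m.sigma_star[0, 0]
        assert np.isclose(1.0 / (v * (nu - 2.0)), mean, rtol=1e-10)
        assert np.isclose(2.0 / (v**2 * (nu - 2.0) ** 2 * (nu - 4.0)), var, rtol=1e-8)

    def test_moment_match_consistency_random_instances(self, rng):
        for _ in range(10):
            K = int(rng.integers(1, 5))
            terms = [random_term(rng, int(rng.integers(1, K + 1)), K) for _ in range(3)]
            analytic_mean = sum(t.mean() for t in terms)
            try:
                np.linalg.cholesky(analytic_mean)
            except np.linalg.LinAlgError:
                continue
            m = match_single_inverse_wishart(terms)
            assert np.allclose(m.implied_mean(), analytic_mean, rtol=1e-10)
            v = sum(t.trace_variance() for t in terms)
            assert np.isclose(m.implied_trace_variance(), v, rtol=1e-8)
            assert m.diagnostics.get("fixed_point") or m.diagnostics["agree"]
            np.linalg.cholesky(m.psi_star)  # positive definiteness

    def test_match_agrees_with_sampling_oracle_two_selection_terms(self, rng):
        # two selection-type terms into a 2x2 sum
        t1 = selection_term(1, 2, 1, (1, 2), df=14.0, scale=random_spd(rng, 2))
        t2 = selection_term(1, 2, 1, (1,), df=10.0, scale=random_spd(rng, 1))
        m = match_single_inverse_wishart([t1, t2])
        mc = mc_inverse_wishart_sum([t1, t2], draws=50_000, seed=rng)
        assert np.all(np.abs(mc["mean"] - m.mean) <= 4.0 * mc["mean_se"] + 1e-12)
        assert abs(mc["trace_var"] - m.trace_var) <= 4.0 * mc["trace_var_se"]


class TestMonteCarloOracle:
    def test_deterministic_given_seed(self, rng):
        term = random_term(np.random.default_rng(5), 2, 2)
        a = mc_inverse_wishart_sum([term], draws=2000, seed=99)
        b = mc_inverse_wishart_sum([term], draws=2000, seed=99)
        assert np.array_equal(a["mean"], b["mean"])
        assert a["trace_var"] == b["trace_var"]

    def test_standard_error_shrinks_with_draws(self):
        term = random_term(np.random.default_rng(7), 2, 2)
        small = mc_inverse_wishart_sum([term], draws=4000, seed=1)
        big = mc_inverse_wishart_sum([term], draws=16000, seed=2)
        ratio = small["mean_se"].mean() / big["mean_se"].mean()
        assert 1.5 < ratio < 2.7  # ~2 expected for 4x draws

    def test_too_few_draws_rejected(self):
        term = random_term(np.random.default_rng(3), 1, 1)
        with pytest.raises(WishartMatchError):
            mc_inverse_wishart_sum([term], draws=10, seed=0)


class TestPositiveDefiniteCheck:
    def test_complete_terms_cover_all_blocks(self, rng):
        terms = [
            selection_term(2, 2, 1, (1, 2), 10.0, random_spd(rng, 2)),
            selection_term(2, 2, 2, (1, 2), 10.0, random_spd(rng, 2)),
        ]
        assert check_positive_definite_sum(terms, [(0, 2), (2, 2)])

    def test_subset_only_block_fails(self, rng):
        terms = [
            selection_term(2, 2, 1, (1, 2), 10.0, random_spd(rng, 2)),
            selection_term(2, 2, 2, (1,), 10.0, random_spd(rng, 1)),
        ]
        assert not check_positive_definite_sum(terms, [(0, 2), (2, 2)])

    def test_worksite_recast_terms_cover(self):
        design = cluster_mean_recast(oral_cancer_member_design())
        terms = terms_from_design(design)
        # cluster-mean form: every arm's scalar block receives a complete
        # (full-dimension) contribution, so the sufficient condition holds
        assert check_positive_definite_sum(terms, [(0, 1), (1, 1)])
        m = match_single_inverse_wishart(terms)
        np.linalg.cholesky(m.mean)


class TestTermsFromDesign:
    def test_worksite_recast_terms(self):
        design = cluster_mean_recast(oral_cancer_member_design())
        terms = terms_from_design(design)
        assert len(terms) == 2
        assert [t.p_m for t in terms] == [1, 1]
        assert [t.df for t in terms] == [48.0, 28.0]  # N_d - q
        assert np.isclose(terms[0].scale[0, 0], 1125.0 / 48.0)

    def test_expectation_matches_monte_carlo(self):
        design = cluster_mean_recast(oral_cancer_member_design())
        terms = terms_from_design(design)
        analytic = sum(t.mean() for t in terms)
        mc = mc_inverse_wishart_sum(terms, draws=60_000, seed=123)
        assert np.all(np.abs(mc["mean"] - analytic) <= 3.0 * mc["mean_se"] + 1e-12)

    def test_insufficient_df_raises(self):
        from dataclasses import replace

        design = cluster_mean_recast(oral_cancer_member_design())
        # q so large that N_d - q <= p_d + 3 for the smaller pattern
        bad = replace(design, q=26)
        with pytest.raises(WishartMatchError):
            terms_from_design(bad)


class TestContrastWishart:
    def test_identity_contrast(self, rng):
        term = InverseWishartTerm(df=20.0, scale=random_spd(rng, 3), blocks=((np.eye(3), 1),))
        m = match_single_inverse_wishart([term])
        cw = contrast_wishart(m, np.eye(3), 3)
        assert cw.df == m.df
        assert np.allclose(cw.scale, m.sigma_star)

    def test_single_row_contrast_is_positive_scalar(self, rng):
        term = InverseWishartTerm(df=20.0, scale=random_spd(rng, 3), blocks=((np.eye(3), 1),))
        m = match_single_inverse_wishart([term])
        c = rng.standard_normal((1, 3))
        cw = contrast_wishart(m, c, 3)
        assert cw.scale.shape == (1, 1) and cw.scale[0, 0] > 0

    def test_contrast_mean_matches_sampling(self, rng):
        # E(W-hat) = df * C Sigma* C' under the matched law
        term = InverseWishartTerm(df=25.0, scale=random_spd(rng, 2), blocks=((np.eye(2), 1),))
        m = match_single_inverse_wishart([term])
        C = np.array([[1.0, -1.0]])
        cw = contrast_wishart(m, C, 2)
        draws = stats.wishart.rvs(df=m.df, scale=m.sigma_star, size=40_000, random_state=rng)
        emp = np.mean([C @ S @ C.T for S in draws])
        assert np.isclose(emp, cw.df * cw.scale[0, 0], rtol=0.03)

    def test_small_df_rejected(self):
        from krpower.wishart import MatchedInverseWishart

        m = MatchedInverseWishart(
            df=2.5, sigma_star=np.eye(3), mean=np.eye(3), trace_var=1.0, diagnostics={}
        )
        with pytest.raises(WishartMatchError):
            contrast_wishart(m, np.eye(3)[:2], 3)  # df = 2.5 <= a + 1 = 3
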