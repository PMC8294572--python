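import numpy as np
import pytest
from scipy import stats

from krpower.design import (
    ObservationPattern,
    StudyDesign,
    UnitGroup,
    cluster_mean_recast,
    stack_design,
)
from krpower.wald import (
    QuadFormApprox,
    WaldApproxError,
    match_noncentral_chisq,
    wald_f_representation,
    wald_moments,
    wls_contrast_covariance,
)
from krpower.wishart import ContrastWishart

from conftest import oral_cancer_member_design, random_spd


class TestWlsContrastCovariance:
    def test_iid_mean_is_classical(self):
        # one group of N units, X_i = 1_p, sigma^2 I: var(mean) = sigma^2/(N p)
        N, p, s2 = 12, 4, 2.5
        d = StudyDesign(
            patterns=(ObservationPattern(1, tuple(range(1, p + 1))),),
            groups=(UnitGroup(1, np.ones((p, 1)), N),),
            sigma_max=s2 * np.eye(p),
            beta=[0.0],
            C=[[1.0]],
            theta0=[0.0],
            q=1,
        )
        cm = wls_contrast_covariance(d)
        assert np.isclose(cm.sigma_x[0, 0], s2 / (N * p), rtol=1e-12)

    def test_blockwise_equals_dense_oracle(self):
        # brute force on the full stacked matrices of the worksite design
        design = oral_cancer_member_design()
        cm = wls_contrast_covariance(design)
        sm = stack_design(design)
        dense = sm.dense_sigma()
        info = sm.X_s.T @ np.linalg.solve(dense, sm.X_s)
        sigma_x = design.C @ np.linalg.inv(info) @ design.C.T
        assert np.allclose(cm.sigma_x, sigma_x, rtol=1e-9)

    def test_information_additivity(self, oral_design):
        from dataclasses import replace

        doubled = replace(
            oral_design,
            groups=tuple(
                UnitGroup(g.pattern_id, g.design, 2 * g.count) for g in oral_design.groups
            ),
        )
        a = wls_contrast_covariance(oral_design).sigma_x
        b = wls_contrast_covariance(doubled).sigma_x
        assert np.allclose(b, a / 2.0, rtol=1e-12)

    def test_singular_information_names_directions(self):
        d = StudyDesign(
            patterns=(ObservationPattern(1, (1,)),),
            groups=(UnitGroup(1, [[1.0, 1.0]], 10),),
            sigma_max=[[1.0]],
            beta=[0.0, 0.0],
            C=[[1.0, 0.0]],
            theta0=[0.0],
            q=1,
        )
        with pytest.raises(WaldApproxError, match="deficient"):
            wls_contrast_covariance(d)


class TestNoncentralChisqMatch:
    def test_identity_covariances_are_exact(self, rng):
        a = 3
        mu = rng.standard_normal(a)
        lam, n, delta = match_noncentral_chisq(mu, np.eye(a), np.eye(a))
        assert np.isclose(lam, 1.0)
        assert np.isclose(n, a)
        assert np.isclose(delta, mu @ mu)

    def test_null_reduces_to_satterthwaite(self, rng):
        a = 3
        sx, sw = random_spd(rng, a), random_spd(rng, a)
        lam, n, delta = match_noncentral_chisq(np.zeros(a), sx, sw)
        A = np.linalg.inv(sw)
        AS = A @ sx
        t, t2 = np.trace(AS), np.trace(AS @ AS)
        assert delta == 0.0
        assert np.isclose(lam, t2 / t, rtol=1e-12)
        assert np.isclose(n, t * t / t2, rtol=1e-12)

    def test_three_moments_reproduced(self, rng):
        # matched parameters must carry the exact null mean, alternative mean
        # and alternative variance of U = x' A x
        for _ in range(20):
            a = int(rng.integers(1, 5))
            sx, sw = random_spd(rng, a), random_spd(rng, a)
            mu = rng.standard_normal(a)
            lam, n, delta = match_noncentral_chisq(mu, sx, sw)
            A = np.linalg.inv(sw)
            AS = A @ sx
            E0 = np.trace(AS)
            EA = E0 + mu @ A @ mu
            VA = 2.0 * np.trace(AS @ AS) + 4.0 * mu @ A @ sx @ A @ mu
            assert np.isclose(lam * n, E0, rtol=1e-12)
            assert np.isclose(lam * (n + delta), EA, rtol=1e-12)
            assert np.isclose(2.0 * lam**2 * (n + 2.0 * delta), VA, rtol=1e-12)

    def test_non_spd_sigma_w_rejected(self, rng):
        with pytest.raises(WaldApproxError):
            match_noncentral_chisq(np.ones(2), np.eye(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestWaldFRepresentation:
    def _rep(self, rng, a=2, df=40.0, mu=None):
        sx = random_spd(rng, a)
        sw = random_spd(rng, a)
        mu = rng.standard_normal(a) if mu is None else mu
        from krpower.wald import ContrastMean

        cm = ContrastMean(mu=mu, sigma_x=sx, information=np.eye(a))
        cw = ContrastWishart(df=df, scale=sw)
        return cm, cw, wald_f_representation(cm, cw)

    def test_scale_identity_lambda_n_equals_trq(self, rng):
        for _ in range(10):
            _, _, rep = self._rep(rng, a=int(rng.integers(1, 5)))
            assert np.isclose(rep.lambda_u * rep.n_u, rep.tr_Q, rtol=1e-12)

    def test_scalar_null_case_is_central_f(self, rng):
        cm, cw, rep = self._rep(rng, a=1, mu=np.zeros(1))
        assert rep.delta_u == 0.0
        assert np.isclose(rep.n_u, 1.0, rtol=1e-12)
        assert np.isclose(rep.scale, rep.tr_Q / (1 * rep.denom_df), rtol=1e-12)

    def test_empirical_cdf_close_to_approx_law(self, rng):
        # draw the exact (Gaussian, Wishart) construction and compare with
        # the scaled noncentral F law; the law is approximate, so only a
        # loose Kolmogorov distance is required.  The instance mimics the
        # pipeline's geometry, where the Wishart scale is (approximately)
        # the contrast covariance divided by its degrees of freedom.
        a, df = 2, 40.0
        sx = random_spd(rng, a)
        sw = (sx + random_spd(rng, a, 0.1)) / df
        mu = np.array([0.6, -0.3])
        from krpower.wald import ContrastMean

        cm = ContrastMean(mu=mu, sigma_x=sx, information=np.eye(a))
        cw = ContrastWishart(df=df, scale=sw)
        rep = wald_f_representation(cm, cw)
        n = 100_000
        x = rng.multivariate_normal(mu, sx, size=n)
        W = stats.wishart.rvs(df=df, scale=sw, size=n, random_state=rng)
        w = np.einsum("ni,nij,nj->n", x, np.linalg.inv(W), x) / a
        grid = np.quantile(w, np.linspace(0.01, 0.99, 99))
        emp = np.searchsorted(np.sort(w), grid, side="right") / n
        approx = stats.ncf.cdf(grid / rep.scale, rep.n_u, rep.denom_df, rep.delta_u)
        assert np.max(np.abs(emp - approx)) < 0.03

    def test_denominator_df_guard(self, rng):
        from krpower.wald import ContrastMean

        cm = ContrastMean(mu=np.ones(1), sigma_x=np.eye(1), information=np.eye(1))
        with pytest.raises(WaldApproxError):
            wald_f_representation(cm, ContrastWishart(df=3.0, scale=np.eye(1)))


class TestWaldMoments:
    def test_moments_match_independent_f_moments(self, rng):
        # scipy's noncentral-F moments are an independent oracle for the
        # scaled-F mean and variance used internally
        for _ in range(5):
            rep = QuadFormApprox(
                a=2,
                lambda_u=float(rng.uniform(0.5, 2.0)),
                n_u=float(rng.uniform(1.0, 5.0)),
                delta_u=float(rng.uniform(0.0, 10.0)),
                denom_df=float(rng.uniform(10.0, 60.0)),
                tr_Q=1.0,
                h=1.0,
            )
            mom = wald_moments(rep)
            m, v = stats.ncf.stats(rep.n_u, rep.denom_df, rep.delta_u, moments="mv")
            assert np.isclose(mom.EA, rep.scale * m, rtol=1e-9)
            assert np.isclose(mom.VA, rep.scale**2 * v, rtol=1e-6)

    def test_central_mean_matches_quadrature(self):
        rep = QuadFormApprox(
            a=1, lambda_u=2.0, n_u=1.5, delta_u=0.0, denom_df=30.0, tr_Q=3.0, h=0.0
        )
        mom = wald_moments(rep)
        from scipy import integrate

        scale = rep.tr_Q / (rep.a * rep.denom_df)
        f = lambda x: x * stats.f.pdf(x / scale, 1.5, 30.0) / scale
        val, _ = integrate.quad(f, 0, np.inf)
        assert np.isclose(mom.E0, val, rtol=1e-6)

    def test_null_noncentrality_gives_equal_means(self):
        rep = QuadFormApprox(
            a=2, lambda_u=1.3, n_u=2.0, delta_u=0.0, denom_df=25.0, tr_Q=2.6, h=0.0
        )
        mom = wald_moments(rep)
        assert np.isclose(mom.EA, mom.E0, rtol=1e-12)

    def test_alternative_mean_increases_with_noncentrality(self):
        base = dict(a=2, lambda_u=1.0, n_u=2.0, denom_df=25.0, tr_Q=2.0, h=1.0)
        means = [
            wald_moments(QuadFormApprox(delta_u=d, **base)).EA for d in (0.0, 1.0, 4.0, 9.0)
        ]
        assert np.all(np.diff(means) > 0)

    def test_scale_invariance_of_null_moments(self, oral_design):
        # multiplying sigma_max by c scales sigma_x and Sigma_W together,
        # leaving the null Wald moments unchanged
        from dataclasses import replace

        from krpower.wald import wls_contrast_covariance
        from krpower.wishart import contrast_wishart, match_single_inverse_wishart, terms_from_design

        def null_moments(design):
            d = cluster_mean_recast(design)
            cm = wls_contrast_covariance(d)
            cw = contrast_wishart(
                match_single_inverse_wishart(terms_from_design(d)), d.C, d.r
            )
            rep = wald_f_representation(cm, cw)
            return wald_moments(rep).E0

        scaled = replace(oral_design, sigma_max=3.7 * oral_design.sigma_max)
        assert np.isclose(null_moments(oral_design), null_moments(scaled), rtol=1e-10)
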