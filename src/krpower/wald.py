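"""Approximate alternative-hypothesis distribution of the unscaled Wald statistic.

The Wald statistic ``w = (theta_hat - theta0)' W_hat^-1 (theta_hat - theta0) / a``
combines a Gaussian contrast estimate (conditional on the true covariance)
with an approximately Wishart estimated contrast covariance.  Writing
``x ~ N_a(mu, Sigma_x)`` independent of ``W ~ W_a(n, Sigma_W)``, the quadratic
form ``U = x' Sigma_W^-1 x`` is a weighted sum of noncentral chi-squares; a
three-moment match collapses it to a single scaled noncentral chi-square
``lambda_u * chi2_{n_u}(delta_u)``, and dividing by the independent Wishart
denominator yields a scaled noncentral F law for ``w``:

``w  ~  tr(Q) / [a (n + a - 1)] * F(n_u, n + a - 1, delta_u)``

with ``Q = Sigma_W^-1 Sigma_x`` and the identity ``lambda_u n_u = tr(Q)``.
The module then reads off the null mean, alternative mean and alternative
variance of ``w`` from noncentral-F moment formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StudyDesign, require_admissible
from .wishart import ContrastWishart

__all__ = [
    "ContrastMean",
    "QuadFormApprox",
    "WaldMoments",
    "WaldApproxError",
    "wls_contrast_covariance",
    "match_noncentral_chisq",
    "wald_f_representation",
    "wald_moments",
    "scaled_f_mean",
    "scaled_f_variance",
]


class WaldApproxError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastMean:
    """Exact mean and covariance of the weighted-least-squares contrast estimate.

    ``mu = C beta - theta0`` and ``sigma_x = C (X_s' Sigma_s^-1 X_s)^-1 C'``,
    computed blockwise by pattern.
    """

    mu: np.ndarray
    sigma_x: np.ndarray
    information: np.ndarray  # X_s' Sigma_s^-1 X_s, kept for diagnostics


@dataclass(frozen=True)
class QuadFormApprox:
    """Scaled-noncentral-F representation of the unscaled Wald statistic."""

    a: int
    lambda_u: float
    n_u: float
    delta_u: float
    denom_df: float
    tr_Q: float
    h: float  # mu' Sigma_W^-1 mu

    @property
    def scale(self) -> float:
        """Multiplier of the F variate: ``tr(Q) / (a * denom_df)``."""
        return self.lambda_u * self.n_u / (self.a * self.denom_df)


@dataclass(frozen=True)
class WaldMoments:
    E0: float
    EA: float
    VA: float


def wls_contrast_covariance(design: StudyDesign) -> ContrastMean:
    """Exact WLS contrast mean and covariance, accumulated pattern block by
    pattern block (no dense n-by-n matrix is formed)."""
    require_admissible(design)
    r = design.r
    info = np.zeros((r, r))
    for pat in design.patterns:
        grps = design.pattern_groups(pat.id)
        if not grps:
            continue
        sig_inv = np.linalg.inv(design.pattern_sigma(pat.id))
        for g in grps:
            info += g.count * (g.design.T @ sig_inv @ g.design)
    info = 0.5 * (info + info.T)
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        eigvals, eigvecs = np.linalg.eigh(info)
        deficient = [
            f"column combination {np.round(eigvecs[:, k], 3).tolist()}"
            for k in range(r)
            if eigvals[k] <= eigvals[-1] * 1e-12
        ]
        raise WaldApproxError(
            "information matrix X_s' Sigma_s^-1 X_s is singular; deficient "
            "directions: " + "; ".join(deficient)
        )
    info_inv = np.linalg.inv(info)
    sigma_x = design.C @ info_inv @ design.C.T
    mu = design.C @ design.beta - design.theta0
    return ContrastMean(mu=mu, sigma_x=0.5 * (sigma_x + sigma_x.T), information=info)


def match_noncentral_chisq(
    mu: np.ndarray, sigma_x: np.ndarray, sigma_W: np.ndarray
) -> tuple[float, float, float]:
    """Three-moment match of ``U = x' Sigma_W^-1 x`` to ``lambda * chi2_n(delta)``.

    With ``A = Sigma_W^-1`` the matching conditions are::

        lambda n           = tr(A Sigma_x)                       (null mean)
        lambda (n + delta) = tr(A Sigma_x) + mu' A mu            (alt. mean)
        2 lambda^2 (n + 2 delta)
            = 2 tr(A Sigma_x A Sigma_x) + 4 mu' A Sigma_x A mu   (alt. variance)

    solved in ratio form.  ``mu = 0`` degenerates to the two-moment
    (Satterthwaite) match with ``delta = 0``.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    sigma_x = np.atleast_2d(sigma_x)
    sigma_W = np.atleast_2d(sigma_W)
    try:
        np.linalg.cholesky(sigma_W)
    except np.linalg.LinAlgError:
        raise WaldApproxError("sigma_W must be symmetric positive definite") from None
    A = np.linalg.inv(sigma_W)
    AS = A @ sigma_x
    t = float(np.trace(AS))
    t2 = float(np.trace(AS @ AS))
    h = float(mu @ A @ mu)
    cross = float(mu @ A @ sigma_x @ A @ mu)
    if h <= 0.0:
        lam = t2 / t
        return lam, t / lam, 0.0
    lam = (t2 + 2.0 * cross) / (t + 2.0 * h)
    return lam, t / lam, h / lam


def wald_f_representation(
    contrast_mean: ContrastMean, contrast_wishart: ContrastWishart, a: int | None = None
) -> QuadFormApprox:
    """Scaled noncentral-F law of the unscaled Wald statistic ``w``."""
    sigma_W = contrast_wishart.scale
    a = sigma_W.shape[0] if a is None else a
    if contrast_wishart.df <= a + 1:
        raise WaldApproxError(
            f"contrast Wishart df {contrast_wishart.df} must exceed a + 1 = {a + 1}"
        )
    denom_df = contrast_wishart.df + a - 1.0
    if denom_df <= 4.0:
        raise WaldApproxError(
            f"denominator df {denom_df} must exceed 4 for the Wald variance to exist"
        )
    lam, n_u, delta_u = match_noncentral_chisq(
        contrast_mean.mu, contrast_mean.sigma_x, sigma_W
    )
    A = np.linalg.inv(sigma_W)
    tr_Q = float(np.trace(A @ contrast_mean.sigma_x))
    h = float(contrast_mean.mu @ A @ contrast_mean.mu)
    return QuadFormApprox(
        a=a, lambda_u=lam, n_u=n_u, delta_u=delta_u, denom_df=denom_df, tr_Q=tr_Q, h=h
    )


def scaled_f_mean(scale: float, df1: float, df2: float, delta: float) -> float:
    """Mean of ``scale * F(df1, df2, delta)`` (df2 > 2)."""
    if df2 <= 2:
        raise WaldApproxError("mean of F requires denominator df > 2")
    return scale * df2 * (df1 + delta) / (df1 * (df2 - 2.0))


def scaled_f_variance(scale: float, df1: float, df2: float, delta: float) -> float:
    """Variance of ``scale * F(df1, df2, delta)`` (df2 > 4)."""
    if df2 <= 4:
        raise WaldApproxError("variance of F requires denominator df > 4")
    num = (df1 + delta) ** 2 + (df1 + 2.0 * delta) * (df2 - 2.0)
    return 2.0 * scale**2 * (df2 / df1) ** 2 * num / ((df2 - 2.0) ** 2 * (df2 - 4.0))


def wald_moments(rep: QuadFormApprox) -> WaldMoments:
    """Null mean, alternative mean and alternative variance of ``w``.

    The null mean re-runs the moment match at ``mu = 0``; because the product
    ``lambda_u n_u = tr(Q)`` is invariant under the match, the null mean
    reduces to ``tr(Q) / [a (denom_df - 2)]`` regardless of branch.
    """
    if rep.denom_df <= 4:
        raise WaldApproxError("denominator df too small for the Wald variance")
    # null branch: central representation with scale tr(Q)/(a * denom_df)
    null_scale = rep.tr_Q / (rep.a * rep.denom_df)
    E0 = scaled_f_mean(null_scale, 1.0, rep.denom_df, 0.0)  # df1 cancels for delta=0
    EA = scaled_f_mean(rep.scale, rep.n_u, rep.denom_df, rep.delta_u)
    VA = scaled_f_variance(rep.scale, rep.n_u, rep.denom_df, rep.delta_u)
    return WaldMoments(E0=float(E0), EA=float(EA), VA=float(VA))
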