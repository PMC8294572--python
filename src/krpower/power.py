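"""Kenward-Roger power: noncentral-F match for the scaled Wald statistic.

The Kenward-Roger test statistic is a scaled Wald statistic ``F_R = lambda w``
referred to ``F(a, nu)``.  For power, the distribution of ``F_R`` under the
alternative is approximated by ``F(a, nu, gamma)``, with ``lambda``, ``nu``
and ``gamma`` chosen so that the null mean, alternative mean, and alternative
variance of ``lambda w`` equal those of the target F law:

    gamma  = a (EA/E0 - 1)
    nu     = 4 + [2 (a + 2 gamma) + (a + gamma)^2] / (rho a^2 - a - 2 gamma)
    lambda = nu / [(nu - 2) E0]

where ``rho = VA / (2 E0^2)`` and ``E0, EA, VA`` are the approximate moments
of the unscaled Wald statistic.  At ``gamma = 0`` the denominator df reduces
to ``4 + (a + 2)/(a rho - 1)``, the same functional form as the
Kenward-Roger null reference distribution.  Power is then
``1 - F(f_crit; a, nu, gamma)`` at ``f_crit = F^-1(1 - alpha; a, nu)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import StudyDesign, require_admissible
from .wald import (
    WaldMoments,
    wald_f_representation,
    wald_moments,
    wls_contrast_covariance,
)
from .wishart import contrast_wishart, match_single_inverse_wishart, terms_from_design

__all__ = ["KRFApprox", "PowerResult", "PowerDomainError", "three_moment_match", "compute_power", "calibrate_effect_scale"]


class PowerDomainError(ValueError):
    """The design falls outside the domain of the moment approximation."""


@dataclass(frozen=True)
class KRFApprox:
    """Matched noncentral-F parameters for the scaled Wald statistic."""

    a: int
    nu: float
    gamma: float
    lam: float
    rho_m: float


@dataclass(frozen=True)
class PowerResult:
    power: float
    f_crit: float
    approx: KRFApprox
    diagnostics: dict

    def __str__(self) -> str:  # concise text report; full report in interface module
        ap = self.approx
        return (
            f"power={self.power:.4f} (a={ap.a}, nu={ap.nu:.2f}, "
            f"gamma={ap.gamma:.3f}, lambda={ap.lam:.4f}, f_crit={self.f_crit:.4f})"
        )


def three_moment_match(moments: WaldMoments, a: int) -> KRFApprox:
    """Match ``(E0, EA, VA)`` of ``lambda w`` to a noncentral F(a, nu, gamma).

    Refuses (rather than clamps) when the moments fall outside the domain
    where a noncentral F with ``nu > 4`` can carry them.
    """
    E0, EA, VA = moments.E0, moments.EA, moments.VA
    if E0 <= 0 or VA <= 0:
        raise PowerDomainError(f"need E0 > 0 and VA > 0, got E0={E0}, VA={VA}")
    if EA < E0 * (1.0 - 1e-12):
        raise PowerDomainError(
            f"alternative mean EA={EA} below null mean E0={E0}: negative "
            "noncentrality is outside the approximation's domain"
        )
    rho = VA / (2.0 * E0 * E0)
    gamma = a * (EA / E0 - 1.0)
    gamma = max(gamma, 0.0)
    denom = rho * a * a - a - 2.0 * gamma
    if denom <= 0.0:
        raise PowerDomainError(
            f"moment ratio denominator rho*a^2 - a - 2*gamma = {denom} is not "
            "positive; the design is too small or the effect too extreme for "
            "the noncentral-F match (nu would not exceed 4)"
        )
    nu = 4.0 + (2.0 * (a + 2.0 * gamma) + (a + gamma) ** 2) / denom
    lam = nu / ((nu - 2.0) * E0)
    return KRFApprox(a=a, nu=float(nu), gamma=float(gamma), lam=float(lam), rho_m=float(rho))


def _stage(name):
    import functools

    def deco(fn):
        @functools.wraps(fn)
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise type(err)(f"[stage: {name}] {err}") from err

        return wrapped

    return deco


def compute_power(design: StudyDesign) -> PowerResult:
    """Approximate Kenward-Roger power for the design's hypothesis test.

    Runs the full analytic chain: exact WLS contrast moments, single
    inverse-Wishart match for the information matrix, scaled-F representation
    of the unscaled Wald statistic, three-moment noncentral-F match, and the
    final critical-value/power computation.  Errors carry the failing stage.
    """
    require_admissible(design)
    a = design.a

    cm = _stage("wls contrast covariance")(wls_contrast_covariance)(design)
    terms = _stage("wishart terms")(terms_from_design)(design)
    match = _stage("wishart match")(match_single_inverse_wishart)(terms)
    cw = _stage("contrast wishart")(contrast_wishart)(match, design.C, design.r)
    rep = _stage("wald representation")(wald_f_representation)(cm, cw, a)
    mom = _stage("wald moments")(wald_moments)(rep)
    approx = _stage("three-moment match")(three_moment_match)(mom, a)

    f_crit = float(stats.f.ppf(1.0 - design.alpha, a, approx.nu))
    if approx.gamma == 0.0:
        power = design.alpha
    else:
        power = float(stats.ncf.sf(f_crit, a, approx.nu, approx.gamma))
    power = min(max(power, 0.0), 1.0)
    diagnostics = {
        "mu": cm.mu.tolist(),
        "sigma_x": cm.sigma_x.tolist(),
        "N_star": match.N_star,
        "contrast_df": cw.df,
        "lambda_u": rep.lambda_u,
        "n_u": rep.n_u,
        "delta_u": rep.delta_u,
        "tr_Q": rep.tr_Q,
        "denom_df": rep.denom_df,
        "E0": mom.E0,
        "EA": mom.EA,
        "VA": mom.VA,
        "label": design.label,
        "n_units": design.n_units,
        "n_obs": design.n_obs,
        "alpha": design.alpha,
    }
    return PowerResult(power=power, f_crit=f_crit, approx=approx, diagnostics=diagnostics)


def calibrate_effect_scale(
    design: StudyDesign,
    target_power: float,
    tol: float = 1e-6,
    b_max: float = 1e6,
) -> float:
    """Effect scale ``b`` such that the design with ``beta -> b * beta`` has
    approximately ``target_power``.

    Power is continuous and strictly increasing in ``b`` for a nonnull
    direction, equal to ``alpha`` at ``b = 0``; bisection on an expanding
    bracket solves for the target.
    """
    from scipy import optimize

    if not (0 < target_power < 1):
        raise PowerDomainError("target power must lie in (0, 1)")
    if target_power < design.alpha:
        raise PowerDomainError(
            f"target power {target_power} below alpha = {design.alpha} is unreachable"
        )
    if target_power == design.alpha:
        return 0.0

    def gap(b: float) -> float:
        return compute_power(design.scaled_effect(b)).power - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > b_max:
            raise PowerDomainError("effect scale bracket exceeded b_max")
    b = optimize.brentq(gap, 0.0, hi, xtol=tol, rtol=1e-12)
    return float(b)
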