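"""Single inverse-Wishart approximation to the estimated information matrix.

Under pattern-homoscedastic sampling, the REML-estimated information matrix
``X_s' Sigma_hat^-1 X_s`` is a sum, over observation patterns, of quadratic
forms in independent inverse-Wishart matrices (each pattern's covariance
estimate behaves like a multivariate-model residual covariance).  This module
approximates that sum by a *single* inverse central Wishart, matching

* the expectation of the sum, elementwise, and
* the variance of its trace (the terms are independent, so trace variances add).

Parameterization.  Every term is stored through the Wishart law of the
*un-inverted* matrix: ``S ~ W_p(df, scale)`` with ``E(S^-1) =
scale^-1/(df - p - 1)``.  Published treatments disagree on how many units to
add to an inverse-Wishart's degrees of freedom; tying everything to the
Wishart df removes the ambiguity, and the sampling oracle
(:func:`mc_inverse_wishart_sum`) pins the moment formulas empirically.  Where
a textbook-style inverse-Wishart df is exposed (``MatchedInverseWishart.N_star``)
it uses the ``df + dim + 1`` convention, so the contrast Wishart has
``N_star - r - 1 = df`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .design import StudyDesign, require_admissible

__all__ = [
    "InverseWishartTerm",
    "MatchedInverseWishart",
    "ContrastWishart",
    "WishartMatchError",
    "selection_term",
    "check_positive_definite_sum",
    "terms_from_design",
    "match_single_inverse_wishart",
    "mc_inverse_wishart_sum",
    "contrast_wishart",
]


class WishartMatchError(ValueError):
    """Raised when the inverse-Wishart approximation is undefined."""


@dataclass(frozen=True)
class InverseWishartTerm:
    """Quadratic forms ``X_j' S^-1 X_j`` in inverse-Wishart matrices.

    ``S ~ W_{p_m}(df, scale)``; ``blocks`` lists ``(X_j, c_j)`` with each
    ``X_j`` of shape ``(p_m, K)`` mapping the term into the K-by-K sum, and
    ``c_j`` counting identical contributions.  The selection-type terms of
    the underlying theory are the special case of one block with a 0/1
    row-selection matrix.

    ``shared`` controls the term's probability law:

    * ``shared=True`` — one draw of ``S`` feeds every block copy (the exact
      law of a pattern's aggregated contribution, where all units share the
      pattern covariance estimate);
    * ``shared=False`` — every one of the ``sum_j c_j`` block copies carries
      its *own independent* draw of ``S``.  This is the independence
      assumption of the moment-matching theory (the variance of the trace of
      the sum is the sum of per-summand trace variances), which the power
      pipeline adopts: each sampling unit's contribution is treated as an
      independent inverse Wishart even though units within a pattern share
      the covariance estimate.

    The expectation is identical under both laws; only second moments
    differ.
    """

    df: float
    scale: np.ndarray
    blocks: tuple[tuple[np.ndarray, int], ...]
    shared: bool = True

    def __post_init__(self):
        scale = np.atleast_2d(np.asarray(self.scale, dtype=float))
        object.__setattr__(self, "scale", scale)
        blocks = tuple(
            (np.atleast_2d(np.asarray(X, dtype=float)), int(c)) for X, c in self.blocks
        )
        object.__setattr__(self, "blocks", blocks)
        p = scale.shape[0]
        if scale.shape != (p, p):
            raise WishartMatchError(f"scale must be square, got {scale.shape}")
        for X, c in blocks:
            if X.shape[0] != p:
                raise WishartMatchError(
                    f"block has {X.shape[0]} rows, expected {p}"
                )
            if c < 1:
                raise WishartMatchError("block multiplicity must be >= 1")
        if self.df <= p + 3:
            raise WishartMatchError(
                f"Wishart df {self.df} too small for second moments (need > p + 3 = {p + 3})"
            )

    @property
    def p_m(self) -> int:
        return self.scale.shape[0]

    @property
    def K(self) -> int:
        return self.blocks[0][0].shape[1]

    @property
    def precision(self) -> np.ndarray:
        """``Psi = scale^-1``: the precision matrix of the inverse-Wishart factor."""
        return np.linalg.inv(self.scale)

    def weight(self) -> np.ndarray:
        """Aggregated quadratic-form weight ``M = sum_j c_j X_j X_j'`` (p_m x p_m).

        The trace of the term is ``tr(S^-1 M)`` exactly, for every draw.
        """
        M = np.zeros((self.p_m, self.p_m))
        for X, c in self.blocks:
            M += c * (X @ X.T)
        return M

    def mean(self) -> np.ndarray:
        """Exact expectation of the term (K x K)."""
        E_inv = self.precision / (self.df - self.p_m - 1.0)
        out = np.zeros((self.K, self.K))
        for X, c in self.blocks:
            out += c * (X.T @ E_inv @ X)
        return out

    @staticmethod
    def _single_trace_variance(psi: np.ndarray, M: np.ndarray, df: float, p: int) -> float:
        """``Var[tr(S^-1 M)]`` for one inverse-Wishart draw and weight ``M``.

        For ``S ~ W_p(df, V)`` with ``Psi = V^-1`` and symmetric ``M``:

        ``[2 tr(Psi M)^2 + 2 (df-p-1) tr(Psi M Psi M)] /
        [(df-p) (df-p-1)^2 (df-p-3)]``

        which reduces to the classical selection-type expression when
        ``M = I``.
        """
        d = df - p
        num = 2.0 * np.trace(psi @ M) ** 2 + 2.0 * (d - 1.0) * np.trace(psi @ M @ psi @ M)
        return float(num / (d * (d - 1.0) ** 2 * (d - 3.0)))

    def trace_variance(self) -> float:
        """Variance of the term's trace under its declared law.

        ``shared=True``: the exact variance of ``tr(S^-1 M)`` with the
        aggregated weight ``M = sum_j c_j X_j X_j'``.  ``shared=False``: the
        per-copy variances add (independent draws), so the result is
        ``sum_j c_j Var[tr(S^-1 X_j X_j')]``.
        """
        psi = self.precision
        if self.shared:
            return self._single_trace_variance(psi, self.weight(), self.df, self.p_m)
        total = 0.0
        for X, c in self.blocks:
            total += c * self._single_trace_variance(psi, X @ X.T, self.df, self.p_m)
        return total


def selection_term(
    q: int, p: int, i: int, indices: Sequence[int], df: float, scale: np.ndarray
) -> InverseWishartTerm:
    """Theorem-style selection term ``X = I_q({i}) (x) I_p(R)`` into a (qp x qp) sum.

    ``i`` and ``indices`` are 1-based.
    """
    from .design import deletion_matrix

    Dp = deletion_matrix(p, indices)
    ei = np.zeros((1, q))
    ei[0, i - 1] = 1.0
    X = np.kron(ei, Dp)
    return InverseWishartTerm(df=df, scale=scale, blocks=((X, 1),))


@dataclass(frozen=True)
class MatchedInverseWishart:
    """The single inverse-Wishart law matched to a sum of quadratic forms.

    ``S_star ~ W_K(df, sigma_star)`` and the matched approximation is
    ``sum ~ S_star^-1``.  ``mean`` is the exact expectation of the input sum
    (reproduced by construction); ``trace_var`` its exact trace variance.
    """

    df: float
    sigma_star: np.ndarray
    mean: np.ndarray
    trace_var: float
    diagnostics: dict

    @property
    def K(self) -> int:
        return self.sigma_star.shape[0]

    @property
    def N_star(self) -> float:
        """Inverse-Wishart df in the ``Wishart df + dim + 1`` convention."""
        return self.df + self.K + 1.0

    @property
    def psi_star(self) -> np.ndarray:
        """Precision matrix of the matched inverse Wishart: ``sigma_star^-1``."""
        return np.linalg.inv(self.sigma_star)

    def implied_mean(self) -> np.ndarray:
        return self.psi_star / (self.df - self.K - 1.0)

    def implied_trace_variance(self) -> float:
        psi = self.psi_star
        d = self.df - self.K
        num = 2.0 * np.trace(psi) ** 2 + 2.0 * (d - 1.0) * float(np.sum(psi * psi))
        return float(num / (d * (d - 1.0) ** 2 * (d - 3.0)))


@dataclass(frozen=True)
class ContrastWishart:
    """Approximate Wishart law of ``W_hat = C (X_s' Sigma_hat^-1 X_s)^-1 C'``."""

    df: float
    scale: np.ndarray

    @property
    def a(self) -> int:
        return self.scale.shape[0]


def check_positive_definite_sum(
    terms: Sequence[InverseWishartTerm], block_structure: Sequence[tuple[int, int]]
) -> bool:
    """Sufficient condition for the sum to be positive definite.

    ``block_structure`` lists ``(offset, size)`` diagonal blocks of the K-by-K
    sum.  The condition holds when every block receives at least one
    *complete* term: a single-block term whose mapping restricted to that
    block is the full identity (and zero elsewhere).
    """
    if not terms:
        raise WishartMatchError("no terms supplied")
    for off, size in block_structure:
        covered = False
        for t in terms:
            if t.p_m != size:
                continue
            for X, _ in t.blocks:
                inside = X[:, off : off + size]
                outside = np.delete(X, np.s_[off : off + size], axis=1)
                if np.array_equal(inside, np.eye(size)) and not outside.any():
                    covered = True
                    break
            if covered:
                break
        if not covered:
            return False
    return True


def terms_from_design(design: StudyDesign) -> list[InverseWishartTerm]:
    """One inverse-Wishart term per observation pattern.

    Pattern ``d`` contributes ``sum_{i in d} X_i' Sigma_hat_d^-1 X_i`` where
    the pattern covariance estimate follows
    ``W_{p_d}(N_d - q, Sigma_d / (N_d - q))`` — the residual covariance of the
    pattern's multivariate recast with between-design rank ``q``.

    The terms carry ``shared=False``: for second moments every unit's
    contribution is treated as an independent inverse Wishart, which is the
    moment-matching theory's independence assumption for the summands of the
    information matrix.  The expectation of the sum is exact either way.
    """
    require_admissible(design)
    terms = []
    for pat in design.patterns:
        grps = design.pattern_groups(pat.id)
        if not grps:
            continue
        n_d = design.pattern_units(pat.id)
        nu = n_d - design.q
        if nu <= pat.p_d + 3:
            raise WishartMatchError(
                f"pattern {pat.id}: N_d - q = {nu} must exceed p_d + 3 = "
                f"{pat.p_d + 3} for the trace variance to exist"
            )
        sigma_d = design.pattern_sigma(pat.id)
        blocks = tuple((g.design, g.count) for g in grps)
        terms.append(
            InverseWishartTerm(df=nu, scale=sigma_d / nu, blocks=blocks, shared=False)
        )
    return terms


def _solve_trace_df(t1: float, t2: float, v: float, K: int) -> tuple[float, dict]:
    """Solve the trace-variance matching equation for the matched Wishart df.

    With ``x = df - K``, the implied trace variance of the matched law
    constrained to have the correct mean is
    ``V(x) = [2 t1 + 2 (x - 1) t2] / [x (x - 3)]`` where ``t1 = tr(M)^2``,
    ``t2 = ||M||_F^2``.  ``V`` is continuous, decreasing on ``x > 3``, with
    range ``(0, inf)``, so a unique root of ``V(x) = v`` exists.  A bracketed
    root-finder is authoritative; the equivalent quadratic closed form
    (restored from the moment conditions) is evaluated as a cross-check.
    """

    def V(x: float) -> float:
        return (2.0 * t1 + 2.0 * (x - 1.0) * t2) / (x * (x - 3.0))

    # closed form: v x^2 - (3 v + 2 t2) x + 2 (t2 - t1) = 0, larger root
    b = 3.0 * v + 2.0 * t2
    disc = b * b - 8.0 * v * (t2 - t1)
    x_quad = (b + np.sqrt(disc)) / (2.0 * v)

    lo = 3.0 + 1e-9
    hi = max(2.0 * x_quad, 10.0)
    while V(hi) > v:
        hi *= 2.0
        if hi > 1e15:
            raise WishartMatchError("trace-variance equation has no admissible root")
    if V(lo) < v:
        raise WishartMatchError(
            "trace-variance equation has no root with df > K + 3; the design's "
            "pattern degrees of freedom are too small for the approximation"
        )
    x_root = optimize.brentq(lambda x: V(x) - v, lo, hi, xtol=1e-12, rtol=1e-14)
    diag = {"x_root": x_root, "x_quadratic": x_quad, "agree": abs(x_root - x_quad) < 1e-6 * max(1.0, x_quad)}
    return x_root, diag


def match_single_inverse_wishart(
    terms: Sequence[InverseWishartTerm],
) -> MatchedInverseWishart:
    """Match one inverse Wishart to an independent sum of quadratic forms.

    The matched law reproduces the exact mean of the sum elementwise and the
    exact variance of its trace.  A single full-dimension term with
    identity-proportional weight is its own fixed point and is returned
    exactly, bypassing root finding.
    """
    if not terms:
        raise WishartMatchError("no terms supplied")
    K = terms[0].K
    for t in terms:
        if t.K != K:
            raise WishartMatchError("terms map into sums of different dimensions")

    mean = np.zeros((K, K))
    v = 0.0
    for t in terms:
        mean += t.mean()
        v += t.trace_variance()
    mean = 0.5 * (mean + mean.T)
    try:
        np.linalg.cholesky(mean)
    except np.linalg.LinAlgError:
        raise WishartMatchError(
            "expected sum is not positive definite; check that some pattern "
            "observes every design column (block-coverage condition fails)"
        ) from None

    # fixed point: exactly one term, one draw, full dimension, weight
    # proportional to the identity (so the sum IS an inverse Wishart)
    single_draw = len(terms) == 1 and terms[0].p_m == K and (
        terms[0].shared or sum(c for _, c in terms[0].blocks) == 1
    )
    if single_draw:
        M_w = terms[0].weight()
        c = M_w[0, 0]
        if c > 0 and np.allclose(M_w, c * np.eye(K), rtol=1e-12, atol=1e-12):
            df = float(terms[0].df)
            sigma_star = terms[0].scale / c
            return MatchedInverseWishart(
                df=df,
                sigma_star=sigma_star,
                mean=mean,
                trace_var=v,
                diagnostics={"fixed_point": True},
            )

    t1 = float(np.trace(mean)) ** 2
    t2 = float(np.sum(mean * mean))
    x, diag = _solve_trace_df(t1, t2, v, K)
    df = x + K
    if df <= K + 3:
        raise WishartMatchError(f"matched df {df} not admissible (need > {K + 3})")
    psi_star = (df - K - 1.0) * mean
    sigma_star = np.linalg.inv(psi_star)
    diag.update(
        {
            "fixed_point": False,
            "t1": t1,
            "t2": t2,
            "trace_var_target": v,
            "df": df,
            "N_star": df + K + 1.0,
        }
    )
    return MatchedInverseWishart(
        df=float(df), sigma_star=sigma_star, mean=mean, trace_var=float(v), diagnostics=diag
    )


def _wishart_draws(df: float, scale: np.ndarray, n: int, rng) -> np.ndarray:
    p = scale.shape[0]
    if p == 1:
        # W_1(df, s) = s * chi2_df
        draws = scale[0, 0] * rng.chisquare(df, size=n)
        return draws.reshape(n, 1, 1)
    return stats.wishart.rvs(df=df, scale=scale, size=n, random_state=rng)


def mc_inverse_wishart_sum(
    terms: Sequence[InverseWishartTerm],
    draws: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Sampling oracle for the sum's moments.

    Returns the empirical mean matrix, the empirical trace variance, and
    Monte Carlo standard errors for both, computed from ``draws`` independent
    realizations of the sum.  Deterministic given ``seed``.
    """
    if draws < 1_000:
        raise WishartMatchError("use at least 1000 draws")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K = terms[0].K
    total = np.zeros((draws, K, K))
    resampled = 0

    def inv_draws(t, n):
        nonlocal resampled
        S = _wishart_draws(t.df, t.scale, n, rng)
        # guard against numerically singular draws (essentially impossible
        # for admissible df, but resample rather than crash)
        bad = np.linalg.matrix_rank(S) < t.p_m if t.p_m > 1 else (S[:, 0, 0] <= 0)
        bad = np.atleast_1d(bad)
        while bad.any():
            resampled += int(bad.sum())
            S[bad] = _wishart_draws(t.df, t.scale, int(bad.sum()), rng)
            bad_new = np.linalg.matrix_rank(S) < t.p_m if t.p_m > 1 else (S[:, 0, 0] <= 0)
            bad = np.atleast_1d(bad_new)
        return np.linalg.inv(S)

    for t in terms:
        if t.shared:
            S_inv = inv_draws(t, draws)
            for X, c in t.blocks:
                total += c * np.einsum("ik,nij,jl->nkl", X, S_inv, X, optimize=True)
        else:
            # every block copy gets its own independent draw, matching the
            # term's declared law
            for X, c in t.blocks:
                for _ in range(c):
                    S_inv = inv_draws(t, draws)
                    total += np.einsum("ik,nij,jl->nkl", X, S_inv, X, optimize=True)
    mean = total.mean(axis=0)
    mean_se = total.std(axis=0, ddof=1) / np.sqrt(draws)
    tr = np.trace(total, axis1=1, axis2=2)
    tvar = float(tr.var(ddof=1))
    centered = tr - tr.mean()
    m4 = float(np.mean(centered**4))
    tvar_se = float(np.sqrt(max(m4 - tvar**2, 0.0) / draws))
    return {
        "mean": mean,
        "mean_se": mean_se,
        "trace_var": tvar,
        "trace_var_se": tvar_se,
        "draws": draws,
        "resampled": resampled,
    }


def contrast_wishart(match: MatchedInverseWishart, C: np.ndarray, r: int) -> ContrastWishart:
    """Wishart law of the estimated contrast covariance ``C S_star C'``.

    The matched information matrix has paper-convention df ``N_star``; the
    contrast Wishart carries ``N_star - r - 1`` degrees of freedom, which in
    the internal parameterization is simply the matched Wishart df.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != match.K or match.K != r:
        raise WishartMatchError(
            f"contrast has {C.shape[1]} columns; matched dimension is {match.K}, r = {r}"
        )
    a = C.shape[0]
    df = match.df  # == N_star - r - 1
    if df <= a + 1:
        raise WishartMatchError(
            f"contrast Wishart df {df} must exceed a + 1 = {a + 1} for the "
            "Wald moments to exist"
        )
    scale = C @ match.sigma_star @ C.T
    return ContrastWishart(df=float(df), scale=0.5 * (scale + scale.T))
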