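"""Restricted maximum likelihood for pattern-blocked covariance models.

The models fitted here mirror the simulation truth: a single maximal
covariance matrix from a small parametric family (iid, compound symmetry,
AR(1), or unstructured), observed through fixed per-unit patterns.  The
restricted log-likelihood, the GLS coefficient estimate and the residual
quadratic form are all computed from per-group sufficient statistics
``(sum_i y_i y_i', sum_i y_i)``, so the cost of one likelihood evaluation is
independent of the number of sampling units.

Families are parameterized so that the covariance is *linear* in the
parameters wherever the standard software convention is linear (variance
components for compound symmetry), because the Kenward-Roger small-sample
adjustment is parameterization-dependent through its second-derivative term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .design import StudyDesign, require_admissible

__all__ = [
    "CovarianceFamily",
    "IidFamily",
    "CompoundSymmetryFamily",
    "AR1Family",
    "UnstructuredFamily",
    "get_family",
    "ModelStructure",
    "REMLFit",
    "reml_fit",
]


# ---------------------------------------------------------------------------
# covariance families
# ---------------------------------------------------------------------------
class CovarianceFamily:
    """Parametric family for the maximal covariance matrix."""

    name: str = "abstract"
    n_params: int = 0
    linear: bool = True  # Sigma linear in the parameters (second derivs vanish)

    def matrix(self, tau: np.ndarray, p: int) -> np.ndarray:
        raise NotImplementedError

    def derivs(self, tau: np.ndarray, p: int) -> list[np.ndarray]:
        raise NotImplementedError

    def second_derivs(self, tau: np.ndarray, p: int) -> list[list[np.ndarray]]:
        """Symmetric table of second derivative matrices (zero when linear)."""
        z = np.zeros((p, p))
        return [[z] * self.n_params for _ in range(self.n_params)]

    # unconstrained transform for optimization
    def to_unconstrained(self, tau: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def from_unconstrained(self, z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def start(self, sigma_mom: np.ndarray) -> np.ndarray:
        """Method-of-moments start from a pooled residual covariance estimate."""
        raise NotImplementedError


class IidFamily(CovarianceFamily):
    """Independent errors: ``Sigma = sigma2 * I``."""

    name = "iid"
    n_params = 1

    def matrix(self, tau, p):
        return tau[0] * np.eye(p)

    def derivs(self, tau, p):
        return [np.eye(p)]

    def to_unconstrained(self, tau):
        return np.array([np.log(tau[0])])

    def from_unconstrained(self, z):
        return np.array([np.exp(z[0])])

    def start(self, sigma_mom):
        return np.array([max(float(np.mean(np.diag(sigma_mom))), 1e-8)])


class CompoundSymmetryFamily(CovarianceFamily):
    """Exchangeable errors in variance-component form: ``Sigma = v_e I + v_b J``.

    ``v_b`` is the between-unit (intraclass) covariance and may be negative as
    long as every pattern block stays positive definite; the optimizer search
    space keeps ``v_e > 0`` and leaves ``v_b`` free, with non-positive-definite
    proposals rejected by an infinite objective.
    """

    name = "cs"
    n_params = 2

    def matrix(self, tau, p):
        return tau[0] * np.eye(p) + tau[1] * np.ones((p, p))

    def derivs(self, tau, p):
        return [np.eye(p), np.ones((p, p))]

    def to_unconstrained(self, tau):
        return np.array([np.log(tau[0]), tau[1]])

    def from_unconstrained(self, z):
        return np.array([np.exp(z[0]), z[1]])

    def start(self, sigma_mom):
        p = sigma_mom.shape[0]
        diag = float(np.mean(np.diag(sigma_mom)))
        if p > 1:
            off = float((sigma_mom.sum() - np.trace(sigma_mom)) / (p * (p - 1)))
        else:
            off = 0.0
        v_e = max(diag - off, 1e-8 + 0.05 * abs(diag))
        return np.array([v_e, off])

    @staticmethod
    def from_variance_icc(variance: float, icc: float) -> np.ndarray:
        return np.array([variance * (1.0 - icc), variance * icc])


class AR1Family(CovarianceFamily):
    """First-order autoregressive errors: ``Sigma_ij = sigma2 * rho^|i-j|``.

    Nonlinear in ``rho``; second derivatives are supplied analytically for the
    Kenward-Roger adjustment.
    """

    name = "ar1"
    n_params = 2
    linear = False

    @staticmethod
    def _lag(p):
        return np.abs(np.subtract.outer(np.arange(p), np.arange(p)))

    def matrix(self, tau, p):
        s2, rho = tau
        return s2 * rho ** self._lag(p)

    def derivs(self, tau, p):
        s2, rho = tau
        lag = self._lag(p)
        corr = rho ** lag
        with np.errstate(divide="ignore", invalid="ignore"):
            dcorr = np.where(lag > 0, lag * rho ** (lag - 1.0), 0.0)
        return [corr, s2 * dcorr]

    def second_derivs(self, tau, p):
        s2, rho = tau
        lag = self._lag(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            d1 = np.where(lag > 0, lag * rho ** (lag - 1.0), 0.0)
            d2 = np.where(lag > 1, lag * (lag - 1.0) * rho ** (lag - 2.0), 0.0)
        zero = np.zeros((p, p))
        return [[zero, d1], [d1, s2 * d2]]

    def to_unconstrained(self, tau):
        return np.array([np.log(tau[0]), np.arctanh(np.clip(tau[1], -0.999, 0.999))])

    def from_unconstrained(self, z):
        return np.array([np.exp(z[0]), np.tanh(z[1])])

    def start(self, sigma_mom):
        p = sigma_mom.shape[0]
        s2 = max(float(np.mean(np.diag(sigma_mom))), 1e-8)
        if p > 1:
            lag1 = float(np.mean(np.diag(sigma_mom, 1)))
            rho = np.clip(lag1 / s2, -0.95, 0.95)
        else:
            rho = 0.0
        return np.array([s2, rho])


class UnstructuredFamily(CovarianceFamily):
    """Fully parameterized symmetric covariance.

    The optimizer works in Cholesky coordinates (log-diagonal, free
    off-diagonal), while derivatives for the Kenward-Roger adjustment use the
    element basis — ``tau`` is the half-vectorization of ``Sigma`` and
    ``dSigma/dtau_k`` are the symmetric single-element basis matrices, a
    linear structure.
    """

    name = "unstructured"
    linear = True

    def __init__(self, p: int):
        self.p = p
        self.n_params = p * (p + 1) // 2
        self._pairs = [(i, j) for i in range(p) for j in range(i, p)]

    def matrix(self, tau, p):
        sig = np.zeros((p, p))
        for k, (i, j) in enumerate(self._pairs):
            sig[i, j] = sig[j, i] = tau[k]
        return sig

    def derivs(self, tau, p):
        out = []
        for i, j in self._pairs:
            E = np.zeros((p, p))
            E[i, j] = E[j, i] = 1.0
            out.append(E)
        return out

    def to_unconstrained(self, tau):
        sig = self.matrix(tau, self.p)
        L = np.linalg.cholesky(sig)
        z = []
        for i, j in self._pairs:
            # note (i, j) with i <= j indexes L[j, i] (lower triangle)
            z.append(np.log(L[i, i]) if i == j else L[j, i])
        return np.array(z)

    def from_unconstrained(self, z):
        L = np.zeros((self.p, self.p))
        for k, (i, j) in enumerate(self._pairs):
            if i == j:
                L[i, i] = np.exp(z[k])
            else:
                L[j, i] = z[k]
        sig = L @ L.T
        return np.array([sig[i, j] for i, j in self._pairs])

    def start(self, sigma_mom):
        sig = sigma_mom + 1e-8 * np.trace(sigma_mom) / self.p * np.eye(self.p)
        return np.array([sig[i, j] for i, j in self._pairs])


def get_family(name: str, p: int | None = None) -> CovarianceFamily:
    name = name.lower()
    if name == "iid":
        return IidFamily()
    if name == "cs":
        return CompoundSymmetryFamily()
    if name == "ar1":
        return AR1Family()
    if name in ("unstructured", "un"):
        if p is None:
            raise ValueError("unstructured family needs the dimension p")
        return UnstructuredFamily(p)
    raise ValueError(f"unknown covariance family {name!r}")


# ---------------------------------------------------------------------------
# model structure and restricted likelihood
# ---------------------------------------------------------------------------
@dataclass
class ModelStructure:
    """Design-side quantities that do not change across replicates."""

    design: StudyDesign
    family: CovarianceFamily
    # per group: (pattern 0-based indices, X_g, count); pattern-major order
    groups: list[tuple[np.ndarray, np.ndarray, int]] = field(default_factory=list)
    pattern_index: list[np.ndarray] = field(default_factory=list)  # unique patterns
    pattern_units: list[int] = field(default_factory=list)
    group_pattern: list[int] = field(default_factory=list)  # group -> pattern slot

    @classmethod
    def from_design(cls, design: StudyDesign, family: CovarianceFamily | str):
        require_admissible(design)
        if isinstance(family, str):
            family = get_family(family, design.p)
        self = cls(design=design, family=family)
        for slot, pat in enumerate(design.patterns):
            idx = np.asarray(pat.indices, dtype=int) - 1
            self.pattern_index.append(idx)
            self.pattern_units.append(design.pattern_units(pat.id))
            for g in design.pattern_groups(pat.id):
                self.groups.append((idx, g.design, g.count))
                self.group_pattern.append(slot)
        return self

    @property
    def r(self) -> int:
        return self.design.r

    def pattern_blocks(self, full: np.ndarray) -> list[np.ndarray]:
        return [full[np.ix_(idx, idx)] for idx in self.pattern_index]


def _restricted_deviance(structure: ModelStructure, tau, suffstats):
    """-2 restricted log-likelihood (up to an additive constant), or None if
    the proposal is not positive definite on every pattern block."""
    fam = structure.family
    p = structure.design.p
    sigma = fam.matrix(tau, p)
    blocks = structure.pattern_blocks(sigma)
    chols = []
    for B in blocks:
        try:
            chols.append(np.linalg.cholesky(B))
        except np.linalg.LinAlgError:
            return None, None
    r = structure.r
    info = np.zeros((r, r))
    xty = np.zeros(r)
    yty = 0.0
    logdet = 0.0
    sig_invs = [None] * len(blocks)
    for slot, (L, n_d) in enumerate(zip(chols, structure.pattern_units)):
        logdet += 2.0 * n_d * np.sum(np.log(np.diag(L)))
        inv = np.linalg.inv(blocks[slot])
        sig_invs[slot] = inv
    for k, (idx, X, c) in enumerate(structure.groups):
        inv = sig_invs[structure.group_pattern[k]]
        S, s = suffstats[k]
        info += c * (X.T @ inv @ X)
        xty += X.T @ inv @ s
        yty += float(np.sum(inv * S))
    sign, logdet_info = np.linalg.slogdet(info)
    if sign <= 0:
        return None, None
    beta = np.linalg.solve(info, xty)
    rss = yty - float(xty @ beta)
    dev = logdet + logdet_info + rss
    return dev, {"beta": beta, "info": info, "rss": rss}


@dataclass
class REMLFit:
    """Result of a restricted maximum likelihood fit."""

    tau: np.ndarray
    beta: np.ndarray
    info: np.ndarray  # X' Sigma_hat^-1 X at the fitted covariance
    deviance: float
    converged: bool
    n_eval: int
    structure: ModelStructure

    @property
    def sigma_max(self) -> np.ndarray:
        return self.structure.family.matrix(self.tau, self.structure.design.p)

    @property
    def covbeta(self) -> np.ndarray:
        """Conventional (unadjusted) covariance of beta-hat."""
        return np.linalg.inv(self.info)


def _fit_from_suffstats(
    structure: ModelStructure,
    suffstats,
    maxiter: int = 200,
    extra_starts: int = 1,
) -> REMLFit:
    fam = structure.family
    p = structure.design.p

    # method-of-moments pooled residual covariance for the start value:
    # OLS residual cross-products accumulated on the maximal grid
    r = structure.r
    info0 = np.zeros((r, r))
    xty0 = np.zeros(r)
    for k, (idx, X, c) in enumerate(structure.groups):
        S, s = suffstats[k]
        info0 += c * (X.T @ X)
        xty0 += X.T @ s
    beta0 = np.linalg.lstsq(info0, xty0, rcond=None)[0]
    acc = np.zeros((p, p))
    cnt = np.zeros((p, p))
    for k, (idx, X, c) in enumerate(structure.groups):
        S, s = suffstats[k]
        m = X @ beta0
        R = S - np.outer(s, m) - np.outer(m, s) + c * np.outer(m, m)
        acc[np.ix_(idx, idx)] += R
        cnt[np.ix_(idx, idx)] += c
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_mom = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    if not np.all(np.isfinite(sigma_mom)):
        sigma_mom = np.eye(p)

    evals = 0

    def objective(z):
        nonlocal evals
        evals += 1
        tau = fam.from_unconstrained(z)
        dev, _ = _restricted_deviance(structure, tau, suffstats)
        return np.inf if dev is None else dev

    starts = [fam.start(sigma_mom)]
    if extra_starts:
        # conservative fallback: diagonal start with no correlation
        diag = max(float(np.mean(np.diag(sigma_mom))), 1e-8)
        fallback = fam.start(diag * np.eye(p))
        starts.append(fallback)

    best = None
    for s0 in starts[: 1 + extra_starts]:
        try:
            z0 = fam.to_unconstrained(np.asarray(s0, dtype=float))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            continue
        res = optimize.minimize(
            objective,
            z0,
            method="Nelder-Mead",
            options={"maxiter": maxiter * max(1, fam.n_params), "xatol": 1e-8, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and best is res:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimization failed from every start value")
    tau_hat = fam.from_unconstrained(best.x)
    dev, aux = _restricted_deviance(structure, tau_hat, suffstats)
    if dev is None:
        raise RuntimeError("REML optimum is not positive definite")
    return REMLFit(
        tau=tau_hat,
        beta=aux["beta"],
        info=aux["info"],
        deviance=float(dev),
        converged=bool(best.success),
        n_eval=evals,
        structure=structure,
    )


def _suffstats_from_outcomes(structure: ModelStructure, y: np.ndarray):
    """Split a stacked outcome vector (stack_design order) into per-group
    sufficient statistics."""
    y = np.asarray(y, dtype=float).ravel()
    expected = sum(c * len(idx) for idx, X, c in structure.groups)
    if y.shape[0] != expected:
        raise ValueError(
            f"outcome vector has {y.shape[0]} elements, design implies {expected}"
        )
    out = []
    offset = 0
    for idx, X, c in structure.groups:
        p_d = len(idx)
        block = y[offset : offset + c * p_d].reshape(c, p_d)
        offset += c * p_d
        out.append((block.T @ block, block.sum(axis=0)))
    if offset != y.shape[0]:
        raise ValueError(
            f"outcome vector has {y.shape[0]} elements, design implies {offset}"
        )
    return out


def reml_fit(
    design: StudyDesign,
    y: np.ndarray,
    family: str | CovarianceFamily = "unstructured",
    maxiter: int = 200,
) -> REMLFit:
    """REML fit of a pattern-blocked covariance model to one stacked outcome.

    ``y`` must be ordered as produced by :func:`krpower.simulate.simulate_outcomes`
    (pattern-major, then group, then unit).  Returns the fitted covariance
    parameters, the GLS coefficient estimate at the fitted covariance, and a
    convergence flag; callers must check ``converged`` and are expected to
    exclude (and count) non-converged replicates rather than drop them
    silently.
    """
    structure = ModelStructure.from_design(design, family)
    suffstats = _suffstats_from_outcomes(structure, y)
    return _fit_from_suffstats(structure, suffstats, maxiter=maxiter)
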