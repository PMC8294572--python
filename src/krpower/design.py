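"""Study-design model for homoscedastic linear mixed models with fixed
observation patterns.

A *study design* describes a planned analysis before any data exist: every
independent sampling unit (participant or cluster) is assigned a fixed-effects
design matrix and an *observation pattern* — the known subset of the ``p``
possible observations that will be collected for it.  All units share a single
maximal covariance matrix ``sigma_max``; a unit with pattern ``R_d`` has
covariance equal to the principal submatrix of ``sigma_max`` at the observed
rows.  The hypothesis is the general linear hypothesis ``C @ beta = theta0``.

Indices in patterns are 1-based in the public API, matching the statistical
convention for row subsets ``R_d ⊆ {1..p}``.  Internally everything is
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ObservationPattern",
    "UnitGroup",
    "StudyDesign",
    "StackedModel",
    "DesignError",
    "deletion_matrix",
    "pattern_covariance",
    "compound_symmetry_cov",
    "ar1_cov",
    "stack_design",
    "validate_design",
    "cluster_mean_recast",
]


class DesignError(ValueError):
    """Raised for structurally invalid study designs."""


def _as_matrix(x, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.ndim != 2:
        raise DesignError(f"{name} must be a 2-d array, got shape {arr.shape}")
    return arr


def deletion_matrix(p: int, indices: Sequence[int]) -> np.ndarray:
    """Submatrix of ``I_p`` keeping the rows in ``indices`` (1-based).

    ``deletion_matrix(3, [1, 3])`` is ``[[1,0,0],[0,0,1]]``; applying it as
    ``D @ A @ D.T`` extracts the principal submatrix of ``A`` at those rows.
    """
    idx = list(indices)
    if len(idx) == 0:
        raise DesignError("pattern index set must be nonempty")
    if any(int(i) != i for i in idx):
        raise DesignError("pattern indices must be integers")
    idx = [int(i) for i in idx]
    if any(i < 1 or i > p for i in idx):
        raise DesignError(f"pattern indices must lie in 1..{p}, got {idx}")
    if len(set(idx)) != len(idx):
        raise DesignError(f"duplicate pattern indices: {idx}")
    if sorted(idx) != idx:
        raise DesignError(f"pattern indices must be strictly increasing: {idx}")
    D = np.zeros((len(idx), p))
    D[np.arange(len(idx)), np.array(idx) - 1] = 1.0
    return D


def pattern_covariance(sigma_max: np.ndarray, indices: Sequence[int]) -> np.ndarray:
    """Covariance of a pattern: ``D sigma_max D'`` at the observed rows."""
    sigma_max = _as_matrix(sigma_max, "sigma_max")
    D = deletion_matrix(sigma_max.shape[0], indices)
    return D @ sigma_max @ D.T


def compound_symmetry_cov(p: int, variance: float, icc: float) -> np.ndarray:
    """Exchangeable (compound-symmetry) covariance.

    ``variance * (J_p * icc + I_p * (1 - icc))`` — common variance with a
    single intraclass correlation.  ``icc`` must lie in ``[0, 1)`` so the
    matrix is positive definite for every ``p``.
    """
    if variance <= 0:
        raise DesignError(f"variance must be positive, got {variance}")
    if not (0 <= icc < 1):
        raise DesignError(f"icc must lie in [0, 1), got {icc}")
    return variance * (np.full((p, p), icc) + np.eye(p) * (1.0 - icc))


def ar1_cov(p: int, variance: float, rho: float) -> np.ndarray:
    """First-order autoregressive covariance: element (i,j) is ``variance * rho**|i-j|``."""
    if variance <= 0:
        raise DesignError(f"variance must be positive, got {variance}")
    if not (-1 < rho < 1):
        raise DesignError(f"ar1 correlation must lie in (-1, 1), got {rho}")
    lag = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    return variance * rho ** lag


@dataclass(frozen=True)
class ObservationPattern:
    """A fixed subset ``R_d`` of the ``p`` possible observation rows.

    ``indices`` are 1-based, strictly increasing.  ``n_units`` (``N_d``) is
    derived from the unit groups referencing this pattern.
    """

    id: int
    indices: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))

    @property
    def p_d(self) -> int:
        return len(self.indices)

    def deletion(self, p: int) -> np.ndarray:
        return deletion_matrix(p, self.indices)


@dataclass(frozen=True)
class UnitGroup:
    """``count`` identical sampling units sharing one pattern and one design matrix.

    ``design`` is the per-unit fixed-effects matrix ``X_i`` with one row per
    observed occasion (``p_d`` rows) and ``r`` columns.
    """

    pattern_id: int
    design: np.ndarray
    count: int

    def __post_init__(self):
        object.__setattr__(self, "design", _as_matrix(self.design, "design"))
        if self.count < 1:
            raise DesignError(f"group count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class StudyDesign:
    """Complete description of a planned mixed-model study.

    Parameters
    ----------
    patterns, groups : the observation patterns and the unit groups using them.
    sigma_max : (p, p) symmetric positive definite maximal covariance, in
        squared outcome units.
    beta : (r,) regression coefficients under the alternative.
    C : (a, r) full-row-rank contrast matrix.
    theta0 : (a,) null values for ``C @ beta``.
    alpha : Type I error rate.
    q : rank of the between-unit design in the multivariate recast used by the
        information-matrix approximation (the number of treatment conditions
        for the standard parallel-arm designs).
    """

    patterns: tuple[ObservationPattern, ...]
    groups: tuple[UnitGroup, ...]
    sigma_max: np.ndarray
    beta: np.ndarray
    C: np.ndarray
    theta0: np.ndarray
    alpha: float = 0.05
    q: int = 2
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "patterns", tuple(self.patterns))
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "sigma_max", _as_matrix(self.sigma_max, "sigma_max"))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float).ravel())
        object.__setattr__(self, "C", _as_matrix(self.C, "C"))
        object.__setattr__(self, "theta0", np.asarray(self.theta0, dtype=float).ravel())

    # -- derived dimensions -------------------------------------------------
    @property
    def p(self) -> int:
        return self.sigma_max.shape[0]

    @property
    def r(self) -> int:
        return self.groups[0].design.shape[1]

    @property
    def a(self) -> int:
        return self.C.shape[0]

    @property
    def n_units(self) -> int:
        return sum(g.count for g in self.groups)

    @property
    def n_obs(self) -> int:
        by_id = {pat.id: pat for pat in self.patterns}
        return sum(g.count * by_id[g.pattern_id].p_d for g in self.groups)

    def pattern(self, pattern_id: int) -> ObservationPattern:
        for pat in self.patterns:
            if pat.id == pattern_id:
                return pat
        raise DesignError(f"unknown pattern id {pattern_id}")

    def pattern_units(self, pattern_id: int) -> int:
        """``N_d``: number of sampling units observed with this pattern."""
        return sum(g.count for g in self.groups if g.pattern_id == pattern_id)

    def pattern_sigma(self, pattern_id: int) -> np.ndarray:
        return pattern_covariance(self.sigma_max, self.pattern(pattern_id).indices)

    def pattern_groups(self, pattern_id: int) -> tuple[UnitGroup, ...]:
        return tuple(g for g in self.groups if g.pattern_id == pattern_id)

    def with_beta(self, beta) -> "StudyDesign":
        return replace(self, beta=np.asarray(beta, dtype=float).ravel())

    def scaled_effect(self, b: float) -> "StudyDesign":
        """Design whose mean contrast is ``theta0 + b * (C beta - theta0)``.

        Used by effect-scale calibration; ``b = 0`` gives an exactly null
        design, ``b = 1`` returns the design's own alternative.
        """
        return self.with_beta(b * self.beta)


@dataclass(frozen=True)
class StackedModel:
    """Population-averaged form: ``y_s = X_s beta + e_s`` with block covariance.

    ``sigma_blocks`` stores the pattern-major block-diagonal structure of the
    stacked covariance as ``(block, multiplicity)`` pairs; the dense n-by-n
    matrix is never materialized here (``dense_sigma`` builds it on request for
    small oracles only).
    """

    X_s: np.ndarray
    sigma_blocks: tuple[tuple[np.ndarray, int], ...]
    n: int

    def dense_sigma(self) -> np.ndarray:
        from scipy.linalg import block_diag

        mats = []
        for block, count in self.sigma_blocks:
            mats.extend([block] * count)
        return block_diag(*mats)


def validate_design(design: StudyDesign) -> list[str]:
    """Return a list of human-readable invariant violations (empty = admissible).

    Checks structural conformance, positive definiteness of ``sigma_max``,
    contrast rank, and the Wishart admissibility rule ``N_d > q + p_d + 1``
    for every pattern.
    """
    problems: list[str] = []
    p = design.p

    if not design.patterns:
        return ["design has no observation patterns"]
    if not design.groups:
        return ["design has no unit groups"]

    seen_ids = [pat.id for pat in design.patterns]
    if len(set(seen_ids)) != len(seen_ids):
        problems.append(f"duplicate pattern ids: {seen_ids}")

    covered: set[int] = set()
    for pat in design.patterns:
        try:
            deletion_matrix(p, pat.indices)
        except DesignError as err:
            problems.append(f"pattern {pat.id}: {err}")
            continue
        covered.update(pat.indices)
    if covered != set(range(1, p + 1)):
        missing = sorted(set(range(1, p + 1)) - covered)
        problems.append(
            f"sigma_max rows {missing} are not observed under any pattern; "
            "sigma_max dimension should equal the maximal pattern coverage"
        )

    sig = design.sigma_max
    if sig.shape[0] != sig.shape[1]:
        problems.append(f"sigma_max is not square: {sig.shape}")
    elif not np.allclose(sig, sig.T, rtol=1e-10, atol=1e-12):
        problems.append("sigma_max is not symmetric")
    else:
        try:
            np.linalg.cholesky(sig)
        except np.linalg.LinAlgError:
            problems.append("sigma_max is not positive definite")

    r = design.groups[0].design.shape[1]
    by_id = {pat.id: pat for pat in design.patterns}
    used: set[int] = set()
    for k, g in enumerate(design.groups):
        if g.pattern_id not in by_id:
            problems.append(f"group {k}: unknown pattern id {g.pattern_id}")
            continue
        used.add(g.pattern_id)
        pat = by_id[g.pattern_id]
        if g.design.shape[0] != pat.p_d:
            problems.append(
                f"group {k}: design has {g.design.shape[0]} rows but pattern "
                f"{pat.id} observes {pat.p_d}"
            )
        if g.design.shape[1] != r:
            problems.append(
                f"group {k}: design has {g.design.shape[1]} columns, expected {r}"
            )
    unused = set(by_id) - used
    if unused:
        problems.append(f"patterns {sorted(unused)} have no sampling units")

    if design.C.shape[1] != r:
        problems.append(f"C has {design.C.shape[1]} columns but r = {r}")
    if design.beta.shape[0] != r:
        problems.append(f"beta has length {design.beta.shape[0]} but r = {r}")
    if design.theta0.shape[0] != design.C.shape[0]:
        problems.append("theta0 length does not match the number of contrast rows")
    if np.linalg.matrix_rank(design.C) != design.C.shape[0]:
        problems.append("C has linearly dependent rows (rank(C) < a)")
    if not (0 < design.alpha < 1):
        problems.append(f"alpha must lie in (0, 1), got {design.alpha}")
    if design.q < 1:
        problems.append(f"q must be a positive integer, got {design.q}")

    for pat in design.patterns:
        if pat.id not in used:
            continue
        n_d = design.pattern_units(pat.id)
        bound = design.q + pat.p_d + 1
        if not n_d > bound:
            problems.append(
                f"pattern {pat.id}: N_d = {n_d} does not exceed q + p_d + 1 = {bound}"
            )
    return problems


def require_admissible(design: StudyDesign) -> None:
    problems = validate_design(design)
    if problems:
        raise DesignError("inadmissible design:\n  - " + "\n  - ".join(problems))


def stack_design(design: StudyDesign) -> StackedModel:
    """Build the population-averaged model: stacked ``X_s`` and the
    pattern-major block structure of the stacked covariance."""
    require_admissible(design)
    rows = []
    blocks = []
    for pat in design.patterns:
        grps = design.pattern_groups(pat.id)
        if not grps:
            continue
        n_d = sum(g.count for g in grps)
        for g in grps:
            rows.extend([g.design] * g.count)
        blocks.append((design.pattern_sigma(pat.id), n_d))
    X_s = np.vstack(rows)
    return StackedModel(X_s=X_s, sigma_blocks=tuple(blocks), n=X_s.shape[0])


def cluster_mean_recast(design: StudyDesign) -> StudyDesign:
    """Collapse a cluster-randomized design to its model of cluster means.

    Each sampling unit (cluster) with ``p_d`` exchangeable members and
    within-cluster covariance ``Sigma_d`` is replaced by a single observation
    — the cluster mean — with variance ``1' Sigma_d 1 / p_d**2`` (for
    compound symmetry, ``sigma^2 [1 + (p_d - 1) rho] / p_d``).  Each distinct
    pattern becomes a one-dimensional pattern; the recast maximal covariance
    is the diagonal of cluster-mean variances.

    Requires every unit's design rows to be identical (covariates constant
    within a cluster), which the model already assumes.
    """
    require_admissible(design)
    variances = []
    new_patterns = []
    new_groups = []
    for k, pat in enumerate(design.patterns):
        sig_d = design.pattern_sigma(pat.id)
        ones = np.ones(pat.p_d)
        variances.append(float(ones @ sig_d @ ones) / pat.p_d**2)
        new_patterns.append(ObservationPattern(id=pat.id, indices=(k + 1,)))
        for g in design.pattern_groups(pat.id):
            row = g.design[0]
            if not np.allclose(g.design, row[None, :]):
                raise DesignError(
                    "cluster-mean recast requires covariates constant within a unit"
                )
            new_groups.append(UnitGroup(pattern_id=pat.id, design=row[None, :], count=g.count))
    return StudyDesign(
        patterns=tuple(new_patterns),
        groups=tuple(new_groups),
        sigma_max=np.diag(variances),
        beta=design.beta,
        C=design.C,
        theta0=design.theta0,
        alpha=design.alpha,
        q=design.q,
        label=design.label + ("+cluster-means" if design.label else "cluster-means"),
    )
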