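"""Gaussian outcome simulation for study designs.

Replicates are drawn from the population-averaged model: for each sampling
unit with pattern ``d``, ``y_i = X_i beta + e_i`` with
``e_i ~ N(0, Sigma_d)``, independently across units.  Sampling factors
through the Cholesky root of each pattern covariance, so no dense stacked
covariance is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StudyDesign, require_admissible

__all__ = ["ReplicateBatch", "simulate_outcomes", "simulate_sufficient_stats"]


@dataclass(frozen=True)
class ReplicateBatch:
    """Simulated stacked outcome vectors, one row per replicate.

    ``outcomes`` has shape ``(replicates, n)`` with columns ordered
    pattern-major then group then unit (the same ordering as
    :func:`krpower.design.stack_design`).
    """

    design: StudyDesign
    replicates: int
    seed: int
    outcomes: np.ndarray


def _group_layout(design: StudyDesign):
    """Pattern-major iteration order: (group, pattern, Sigma_d cholesky)."""
    layout = []
    for pat in design.patterns:
        sig = design.pattern_sigma(pat.id)
        chol = np.linalg.cholesky(sig)
        for g in design.pattern_groups(pat.id):
            layout.append((g, pat, chol))
    return layout


def simulate_outcomes(design: StudyDesign, replicates: int, seed: int) -> ReplicateBatch:
    """Draw ``replicates`` independent stacked outcome vectors.

    Deterministic given ``seed``; the batch is a pure function of
    ``(design, replicates, seed)``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    require_admissible(design)
    rng = np.random.default_rng(seed)
    cols = []
    for g, pat, chol in _group_layout(design):
        mean = g.design @ design.beta  # (p_d,)
        z = rng.standard_normal(size=(replicates, g.count, pat.p_d))
        y = z @ chol.T + mean  # (R, count, p_d)
        cols.append(y.reshape(replicates, -1))
    outcomes = np.concatenate(cols, axis=1)
    return ReplicateBatch(design=design, replicates=replicates, seed=seed, outcomes=outcomes)


def simulate_sufficient_stats(
    design: StudyDesign, replicates: int, rng: np.random.Generator
):
    """Per-group sufficient statistics for REML, for every replicate.

    Returns a list over groups (pattern-major order) of pairs
    ``(S, s)`` with ``S[rep] = sum_i y_i y_i'`` (shape ``(R, p_d, p_d)``) and
    ``s[rep] = sum_i y_i`` (shape ``(R, p_d)``).  Restricted likelihoods,
    GLS estimates and residual quadratic forms are all functions of these,
    so per-replicate model fitting never touches unit-level data again.
    """
    out = []
    for g, pat, chol in _group_layout(design):
        mean = g.design @ design.beta
        z = rng.standard_normal(size=(replicates, g.count, pat.p_d))
        y = z @ chol.T + mean
        S = np.einsum("rci,rcj->rij", y, y, optimize=True)
        s = y.sum(axis=1)
        out.append((S, s))
    return out
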