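"""Validation design grids: cluster-randomized and longitudinal studies.

These builders generate the two families of study designs used to validate
the power approximation against Monte Carlo simulation:

* *Cluster-randomized trials*: ``t`` parallel arms, ``n_per_arm`` clusters per
  arm, complete clusters of ``p_complete`` members and (optionally) incomplete
  clusters at a size ratio ``s``, exchangeable within-cluster correlation.
  Half the clusters are complete, half incomplete.  The analytic power
  pipeline consumes the cluster-mean recast of these designs; the simulation
  arm fits the member-level compound-symmetry model.
* *Longitudinal studies*: 5 planned repeated measures, 50 participants per
  arm, AR(1) within-participant correlation, with monotone (last two
  occasions missing) or non-monotone (2nd and 4th missing) dropout for a
  subset of participants; the hypothesis is the time-by-treatment
  interaction.

Effect sizes enter through a scale factor ``b`` multiplying a unit-effect
coefficient vector, calibrated by root finding so the *approximate* power
hits nominal targets (0.2, 0.5, 0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import (
    ObservationPattern,
    StudyDesign,
    UnitGroup,
    ar1_cov,
    cluster_mean_recast,
    compound_symmetry_cov,
    validate_design,
)
from .power import calibrate_effect_scale, compute_power

__all__ = [
    "GridDesign",
    "DeviationSummary",
    "cluster_randomized_design",
    "longitudinal_design",
    "build_cluster_grid",
    "build_longitudinal_grid",
    "analysis_design",
    "deviation_report",
]


@dataclass(frozen=True)
class GridDesign:
    """A grid entry: the member-level design plus its factor metadata."""

    design: StudyDesign
    meta: dict


def _arm_contrast(t: int) -> np.ndarray:
    """Rows ``e_1 - e_j`` for j = 2..t: no difference among the t arm means."""
    C = np.zeros((t - 1, t))
    C[:, 0] = 1.0
    C[np.arange(t - 1), np.arange(1, t)] = -1.0
    return C


def cluster_randomized_design(
    t: int,
    n_per_arm: int,
    p_complete: int,
    s: float,
    icc: float,
    effect: float = 0.0,
    sigma2: float = 2.0,
    alpha: float = 0.05,
    label: str = "",
) -> StudyDesign:
    """Member-level cluster-randomized design in cell-means coding.

    ``s`` is the ratio of the incomplete cluster size to ``p_complete``
    (``s = 1`` means every cluster is complete); for ``s < 1`` each arm has
    half complete and half incomplete clusters.  ``effect`` is the mean of
    arm 1 relative to all other arms (the coefficient vector is
    ``effect * e_1``).
    """
    p_inc = int(round(s * p_complete))
    if p_inc < 1 or p_inc > p_complete:
        raise ValueError(f"incomplete cluster size {p_inc} out of range")
    sigma_max = compound_symmetry_cov(p_complete, sigma2, icc)
    patterns = [ObservationPattern(1, tuple(range(1, p_complete + 1)))]
    groups = []
    arms = np.eye(t)
    if p_inc == p_complete:
        for arm in range(t):
            groups.append(
                UnitGroup(1, np.tile(arms[arm], (p_complete, 1)), n_per_arm)
            )
    else:
        if n_per_arm % 2:
            raise ValueError("n_per_arm must be even to split complete/incomplete")
        patterns.append(ObservationPattern(2, tuple(range(1, p_inc + 1))))
        half = n_per_arm // 2
        for arm in range(t):
            groups.append(UnitGroup(1, np.tile(arms[arm], (p_complete, 1)), half))
        for arm in range(t):
            groups.append(UnitGroup(2, np.tile(arms[arm], (p_inc, 1)), half))
    beta = np.zeros(t)
    beta[0] = effect
    return StudyDesign(
        patterns=tuple(patterns),
        groups=tuple(groups),
        sigma_max=sigma_max,
        beta=beta,
        C=_arm_contrast(t),
        theta0=np.zeros(t - 1),
        alpha=alpha,
        q=t,
        label=label or f"cluster(t={t},N={n_per_arm},p={p_complete},s={s},icc={icc})",
    )


def longitudinal_design(
    t: int,
    missing: str,
    n_incomplete: int,
    n_per_arm: int = 50,
    n_times: int = 5,
    rho: float = 0.4,
    sigma2: float = 1.0,
    effect: float = 0.0,
    alpha: float = 0.05,
    label: str = "",
) -> StudyDesign:
    """Longitudinal design with AR(1) errors and known dropout patterns.

    ``missing`` is ``"monotone"`` (4th and 5th occasions missing, observed
    rows {1,2,3}) or ``"nonmonotone"`` (2nd and 4th missing, observed rows
    {1,3,5}); ``n_incomplete`` participants per arm follow that pattern.
    Cell-means coding: one mean per arm-by-time cell, ``effect`` on arm 1 at
    time 1; the hypothesis is the time-by-treatment interaction.
    """
    if missing == "monotone":
        inc_rows = (1, 2, 3)
    elif missing == "nonmonotone":
        inc_rows = (1, 3, 5)
    else:
        raise ValueError("missing must be 'monotone' or 'nonmonotone'")
    if not 0 <= n_incomplete < n_per_arm:
        raise ValueError("n_incomplete must lie in [0, n_per_arm)")
    sigma_max = ar1_cov(n_times, sigma2, rho)
    full = tuple(range(1, n_times + 1))
    arms = np.eye(t)
    patterns = [ObservationPattern(1, full)]
    groups = []
    n_complete = n_per_arm - n_incomplete
    for arm in range(t):
        X_full = np.kron(arms[arm][None, :], np.eye(n_times))
        groups.append(UnitGroup(1, X_full, n_complete))
    if n_incomplete > 0:
        patterns.append(ObservationPattern(2, inc_rows))
        sel = np.array(inc_rows) - 1
        for arm in range(t):
            X_full = np.kron(arms[arm][None, :], np.eye(n_times))
            groups.append(UnitGroup(2, X_full[sel], n_incomplete))
    beta = np.zeros(t * n_times)
    beta[0] = effect
    C_time = np.hstack([np.eye(n_times - 1), -np.ones((n_times - 1, 1))])
    C = np.kron(_arm_contrast(t), C_time)
    return StudyDesign(
        patterns=tuple(patterns),
        groups=tuple(groups),
        sigma_max=sigma_max,
        beta=beta,
        C=C,
        theta0=np.zeros(C.shape[0]),
        alpha=alpha,
        q=t,
        label=label
        or f"longitudinal(t={t},{missing},N_inc={n_incomplete})",
    )


def analysis_design(grid_design: GridDesign) -> StudyDesign:
    """The representation fed to the analytic pipeline: cluster designs are
    recast to cluster means, longitudinal designs pass through unchanged."""
    if grid_design.meta.get("type") == "cluster":
        return cluster_mean_recast(grid_design.design)
    return grid_design.design


def build_cluster_grid(
    iccs: Sequence[float] = (0.04, 0.1, 0.2, 0.5),
    targets: Sequence[float] = (0.2, 0.5, 0.8),
    t_values: Sequence[int] = (2, 4),
    n_values: Sequence[int] = (10, 40),
    p_values: Sequence[int] = (5, 50),
    s_values: Sequence[float] = (0.6, 0.8, 1.0),
    calibrate: bool = True,
) -> list[GridDesign]:
    """Cluster-randomized validation grid.

    Crosses arms x clusters-per-arm x cluster size x incompleteness ratio,
    keeps the member-level-admissible combinations (``N_d > q + p_d + 1``
    for every pattern with ``q = t``), and expands each survivor over the
    intraclass correlations and target approximate powers.  With
    ``calibrate=True`` each entry carries the effect scale ``b`` solving
    ``approximate power = target`` for its recast design.
    """
    out = []
    for t in t_values:
        for n in n_values:
            for p in p_values:
                for s in s_values:
                    base = cluster_randomized_design(t, n, p, s, icc=iccs[0])
                    if validate_design(base):
                        continue  # inadmissible combination
                    for icc in iccs:
                        for target in targets:
                            d = cluster_randomized_design(t, n, p, s, icc=icc, effect=1.0)
                            meta = {
                                "type": "cluster",
                                "t": t,
                                "n_per_arm": n,
                                "p": p,
                                "s": s,
                                "icc": icc,
                                "target": target,
                                "b": None,
                            }
                            if calibrate:
                                b = calibrate_effect_scale(cluster_mean_recast(d), target)
                                d = d.scaled_effect(b)
                                meta["b"] = b
                            meta["id"] = (
                                f"cluster_t{t}_N{n}_p{p}_s{s}_icc{icc}_pw{target}"
                            )
                            out.append(GridDesign(design=d, meta=meta))
    return out


def build_longitudinal_grid(
    targets: Sequence[float] = (0.2, 0.5, 0.8),
    t_values: Sequence[int] = (2, 4),
    missing_values: Sequence[str] = ("monotone", "nonmonotone"),
    n_inc_values: Sequence[int] = (0, 10, 20),
    calibrate: bool = True,
) -> list[GridDesign]:
    """Longitudinal validation grid: 12 structural designs (arms x dropout
    pattern x number incomplete) expanded over the target powers."""
    out = []
    for t in t_values:
        for missing in missing_values:
            for n_inc in n_inc_values:
                for target in targets:
                    d = longitudinal_design(t, missing, n_inc, effect=1.0)
                    meta = {
                        "type": "longitudinal",
                        "t": t,
                        "missing": missing,
                        "n_incomplete": n_inc,
                        "target": target,
                        "b": None,
                    }
                    if calibrate:
                        b = calibrate_effect_scale(d, target)
                        d = d.scaled_effect(b)
                        meta["b"] = b
                    meta["id"] = f"longit_t{t}_{missing}_ninc{n_inc}_pw{target}"
                    out.append(GridDesign(design=d, meta=meta))
    return out


_STRATA = ["type", "t", "p", "s", "icc", "missing", "n_incomplete", "target"]


@dataclass(frozen=True)
class DeviationSummary:
    """Approximate-minus-empirical power deviations with stratified summaries."""

    table: pd.DataFrame
    overall: dict
    by_stratum: dict = field(default_factory=dict)

    def __str__(self) -> str:
        o = self.overall
        return (
            f"deviations over {len(self.table)} designs: median {o['median']:+.3f} "
            f"(min {o['min']:+.3f}, q1 {o['q1']:+.3f}, q3 {o['q3']:+.3f}, max {o['max']:+.3f})"
        )


def _summary(x: pd.Series) -> dict:
    return {
        "n": int(x.size),
        "min": float(x.min()),
        "q1": float(x.quantile(0.25)),
        "median": float(x.median()),
        "q3": float(x.quantile(0.75)),
        "max": float(x.max()),
    }


def deviation_report(records: Iterable[dict]) -> DeviationSummary:
    """Summarize approximate vs empirical power across grid designs.

    Each record needs ``id``, ``approx_power``, ``empirical_power``,
    ``mc_std_error`` and any factor columns; the deviation is
    ``approximate - empirical`` (positive = approximation optimistic).
    """
    df = pd.DataFrame(list(records))
    required = {"id", "approx_power", "empirical_power"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing fields: {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValueError("duplicate design ids in deviation report")
    df = df.copy()
    df["deviation"] = df["approx_power"] - df["empirical_power"]
    overall = _summary(df["deviation"])
    by = {}
    for col in _STRATA:
        if col in df.columns and df[col].notna().any():
            by[col] = {
                str(level): _summary(sub["deviation"])
                for level, sub in df.groupby(col, dropna=True)
            }
    return DeviationSummary(table=df, overall=overall, by_stratum=by)
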