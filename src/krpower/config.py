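"""JSON study-design configurations and packaged fixtures.

A design config is a plain JSON object (see ``docs/config_schema.md``)::

    {
      "schema_version": 1,
      "label": "worksite smoking-cessation trial",
      "covariance": {"family": "cs", "dimension": 30,
                     "variance": 15625.0, "icc": 0.04},
      "patterns": [{"id": 1, "indices": "1:30"},
                   {"id": 2, "indices": "1:20"}],
      "groups": [{"pattern": 1, "count": 25, "design": {"kron_ones": [1, 0]}},
                 ...],
      "beta": [25.0, 0.0],
      "C": [[1.0, -1.0]],
      "theta0": [0.0],
      "alpha": 0.05,
      "q": 2,
      "analysis": {"cluster_mean_recast": true}
    }

``design`` entries are either explicit row-major matrices or the factorial
shorthand ``{"kron_ones": row}`` meaning ``ones(p_d) (x) row`` (every
observed occasion of the unit carries the same covariate row).  Pattern
index sets accept either explicit lists or the span shorthand ``"a:b"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .design import (
    DesignError,
    ObservationPattern,
    StudyDesign,
    UnitGroup,
    ar1_cov,
    cluster_mean_recast,
    compound_symmetry_cov,
    require_admissible,
    validate_design,
)

__all__ = [
    "ConfigError",
    "DesignConfig",
    "load_design_config",
    "save_design_config",
    "fixture_path",
    "list_fixtures",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    """A loaded, validated design plus its analysis directives."""

    design: StudyDesign
    cluster_mean_recast: bool = False
    source: str = ""

    def analysis_design(self) -> StudyDesign:
        """Design in the representation the analytic pipeline consumes."""
        if self.cluster_mean_recast:
            return cluster_mean_recast(self.design)
        return self.design


def _parse_indices(spec) -> tuple[int, ...]:
    if isinstance(spec, str):
        try:
            lo, hi = spec.split(":")
            return tuple(range(int(lo), int(hi) + 1))
        except ValueError as err:
            raise ConfigError(f"bad index span {spec!r}: {err}") from None
    return tuple(int(i) for i in spec)


def _parse_design_matrix(spec, p_d: int) -> np.ndarray:
    if isinstance(spec, dict):
        if set(spec) != {"kron_ones"}:
            raise ConfigError(f"unknown design shorthand keys {sorted(spec)}")
        row = np.asarray(spec["kron_ones"], dtype=float).ravel()
        return np.tile(row, (p_d, 1))
    mat = np.asarray(spec, dtype=float)
    if mat.ndim == 1:
        mat = mat[None, :]
    if mat.shape[0] != p_d:
        raise ConfigError(
            f"design matrix has {mat.shape[0]} rows, pattern observes {p_d}"
        )
    return mat


def _parse_covariance(spec) -> np.ndarray:
    try:
        family = spec["family"]
    except (TypeError, KeyError):
        raise ConfigError("covariance must be an object with a 'family' key") from None
    if family == "explicit":
        return np.asarray(spec["matrix"], dtype=float)
    p = int(spec["dimension"])
    variance = float(spec["variance"])
    if family == "cs":
        return compound_symmetry_cov(p, variance, float(spec["icc"]))
    if family == "ar1":
        return ar1_cov(p, variance, float(spec["rho"]))
    raise ConfigError(f"unknown covariance family {family!r}")


def load_design_config(path: str | Path) -> DesignConfig:
    """Load, expand and validate a JSON design config.

    Raises :class:`ConfigError` with the offending field for schema problems
    and :class:`krpower.design.DesignError` naming the violated inequality
    for inadmissible designs.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ConfigError(f"{path}: not valid JSON: {err}") from None
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: schema_version {version!r} unsupported (expected {SCHEMA_VERSION}); "
            "refusing silent migration"
        )
    for key in ("covariance", "patterns", "groups", "beta", "C", "theta0"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required field {key!r}")
    sigma_max = _parse_covariance(raw["covariance"])
    patterns = []
    for entry in raw["patterns"]:
        patterns.append(
            ObservationPattern(id=int(entry["id"]), indices=_parse_indices(entry["indices"]))
        )
    by_id = {p.id: p for p in patterns}
    groups = []
    for k, entry in enumerate(raw["groups"]):
        pid = int(entry["pattern"])
        if pid not in by_id:
            raise ConfigError(f"groups[{k}]: unknown pattern id {pid}")
        design_mat = _parse_design_matrix(entry["design"], by_id[pid].p_d)
        groups.append(UnitGroup(pattern_id=pid, design=design_mat, count=int(entry["count"])))
    design = StudyDesign(
        patterns=tuple(patterns),
        groups=tuple(groups),
        sigma_max=sigma_max,
        beta=raw["beta"],
        C=raw["C"],
        theta0=raw["theta0"],
        alpha=float(raw.get("alpha", 0.05)),
        q=int(raw.get("q", 2)),
        label=str(raw.get("label", path.stem)),
    )
    require_admissible(design)
    analysis = raw.get("analysis", {})
    return DesignConfig(
        design=design,
        cluster_mean_recast=bool(analysis.get("cluster_mean_recast", False)),
        source=str(path),
    )


def save_design_config(
    config: DesignConfig, path: str | Path, description: str = ""
) -> None:
    """Serialize a design back to the JSON schema (explicit matrices)."""
    d = config.design
    raw = {
        "schema_version": SCHEMA_VERSION,
        "label": d.label,
        "covariance": {"family": "explicit", "matrix": d.sigma_max.tolist()},
        "patterns": [
            {"id": p.id, "indices": list(p.indices)} for p in d.patterns
        ],
        "groups": [
            {"pattern": g.pattern_id, "count": g.count, "design": g.design.tolist()}
            for g in d.groups
        ],
        "beta": d.beta.tolist(),
        "C": d.C.tolist(),
        "theta0": d.theta0.tolist(),
        "alpha": d.alpha,
        "q": d.q,
        "analysis": {"cluster_mean_recast": config.cluster_mean_recast},
    }
    if description:
        raw["description"] = description
    Path(path).write_text(json.dumps(raw, indent=1))


def list_fixtures() -> list[str]:
    root = resources.files("krpower") / "fixtures"
    return sorted(
        entry.name for entry in root.iterdir() if entry.name.endswith(".json")
    )


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture config."""
    if not name.endswith(".json"):
        name += ".json"
    root = resources.files("krpower") / "fixtures"
    path = root / name
    if not path.is_file():
        raise ConfigError(f"no packaged fixture {name!r}; available: {list_fixtures()}")
    return Path(str(path))
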