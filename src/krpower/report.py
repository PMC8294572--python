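"""Provenance manifests and result serialization."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .power import PowerResult

__all__ = ["RunManifest", "run_report"]


def _digest_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record embedded in every emitted result file."""

    tool: str
    version: str
    config_digest: str = ""
    seeds: tuple[int, ...] = ()
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    stages: dict = field(default_factory=dict)

    @classmethod
    def for_config(cls, config_path: str | Path | None, seeds=(), stages=None):
        from . import __version__

        return cls(
            tool="krpower",
            version=__version__,
            config_digest=_digest_file(config_path) if config_path else "",
            seeds=tuple(int(s) for s in seeds),
            stages=dict(stages or {}),
        )


def run_report(
    result: PowerResult,
    format: str = "text",
    manifest: RunManifest | None = None,
) -> str:
    """Serialize a power result (with manifest) as text, JSON or CSV.

    The text form prints the quantities of the final power step: numerator df
    ``a``, denominator df ``nu``, noncentrality ``gamma``, scale ``lambda``,
    the critical value and the power.
    """
    ap = result.approx
    record = {
        "power": result.power,
        "f_crit": result.f_crit,
        "a": ap.a,
        "nu": ap.nu,
        "gamma": ap.gamma,
        "lambda": ap.lam,
        "rho": ap.rho_m,
        "alpha": result.diagnostics.get("alpha"),
        "diagnostics": result.diagnostics,
    }
    if manifest is not None:
        record["manifest"] = asdict(manifest)
    if format == "json":
        return json.dumps(record, indent=1, default=str)
    if format == "csv":
        cols = ["power", "f_crit", "a", "nu", "gamma", "lambda", "rho", "alpha"]
        head = ",".join(cols)
        row = ",".join(repr(record[c]) for c in cols)
        return head + "\n" + row + "\n"
    if format == "text":
        lines = [
            f"design: {result.diagnostics.get('label') or '(unlabelled)'}",
            f"  sampling units: {result.diagnostics.get('n_units')}, "
            f"observations: {result.diagnostics.get('n_obs')}",
            f"  numerator df a      = {ap.a}",
            f"  denominator df nu   = {ap.nu:.4f}",
            f"  noncentrality gamma = {ap.gamma:.4f}",
            f"  scale lambda        = {ap.lam:.6f}",
            f"  critical value      = {result.f_crit:.4f}",
            f"  power               = {result.power:.4f}  (~{result.power:.2f})",
        ]
        if manifest is not None:
            lines.append(
                f"  manifest: {manifest.tool} {manifest.version} "
                f"config@{manifest.config_digest} seeds={list(manifest.seeds)}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unsupported format {format!r}")
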