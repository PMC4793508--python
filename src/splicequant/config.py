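"""Flat key-value run configuration shared by the command-line entry points.

The config file grammar is one ``key = value`` pair per line; ``#`` starts a
comment.  Unknown keys are rejected so silent typos cannot change an
analysis.  All defaults can be printed with ``splicequant --show-config``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["RunConfig", "load_config", "format_config"]


@dataclass(frozen=True)
class RunConfig:
    efficiency_method: str = "cq_slope"  # cq_slope | linreg | standard_curve
    takeoff_fraction: float = 0.2
    smooth_window: int = 5
    qc_tolerance_percent: float = 10.0
    melt_prominence_fraction: float = 0.05
    melt_tm_tolerance_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.efficiency_method not in ("cq_slope", "linreg", "standard_curve"):
            raise ValueError(
                f"efficiency_method must be cq_slope, linreg or standard_curve; "
                f"got {self.efficiency_method!r}"
            )
        if not (0.0 < self.takeoff_fraction < 1.0):
            raise ValueError("takeoff_fraction must lie in (0, 1)")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        if self.qc_tolerance_percent <= 0:
            raise ValueError("qc_tolerance_percent must be positive")


_TYPES = {f.name: f.type for f in fields(RunConfig)}


def load_config(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    base = base or RunConfig()
    updates = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _TYPES:
            raise ValueError(
                f"{path}:{lineno}: unknown config key {key!r}; "
                f"known keys: {sorted(_TYPES)}"
            )
        kind = _TYPES[key]
        if kind in ("int", int):
            updates[key] = int(value)
        elif kind in ("float", float):
            updates[key] = float(value)
        else:
            updates[key] = value
    return replace(base, **updates)


def format_config(config: RunConfig | None = None) -> str:
    config = config or RunConfig()
    lines = ["# splicequant run configuration (all keys with their values)"]
    for f in fields(RunConfig):
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    return "\n".join(lines) + "\n"
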