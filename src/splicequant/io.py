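"""Reading and writing of qPCR data tables.

All tables are plain CSV (comma separator, ``.`` decimal point, UTF-8,
mandatory header row).  Cycle numbering is 1-based throughout, matching
instrument displays.

Three inputs are understood:

* amplification tables — per-well fluorescence versus cycle, either *long*
  (columns ``well, cycle, fluorescence``) or *wide* (a ``cycle`` column plus
  one column per well);
* melt tables — long format ``well, temperature, fluorescence``;
* design sheets — the mapping from wells to samples and primer-pair targets
  (columns ``well_id, sample_id, target, replicate_index, role,
  log10_copies``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Target",
    "FluorescenceCurve",
    "MeltRamp",
    "DesignRow",
    "DesignSheet",
    "TableFormatError",
    "read_amplification_table",
    "read_melt_table",
    "read_design",
    "write_amplification_table",
    "write_melt_table",
    "write_design",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

#: minimum cycle count required for curve analysis downstream
MIN_CYCLES = 15


class TableFormatError(ValueError):
    """Raised when an input table violates the documented CSV dialect."""


class Target(str, enum.Enum):
    """Primer-pair target class.

    ``variant1``/``variant2`` are the two mutually exclusive splice isoforms;
    ``control1``/``control2`` are primer pairs annealing to sequence shared by
    both isoforms (control 2 flanks the spliced region and yields two
    size-distinguishable products).
    """

    VARIANT1 = "variant1"
    VARIANT2 = "variant2"
    CONTROL1 = "control1"
    CONTROL2 = "control2"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "Target":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            allowed = ", ".join(t.value for t in cls)
            raise TableFormatError(
                f"unknown target label {label!r}; allowed: {allowed}"
            ) from None


@dataclass(frozen=True)
class FluorescenceCurve:
    """One well's raw amplification signal over cycles."""

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    target: Target = Target.OTHER

    def __post_init__(self) -> None:
        cyc = np.asarray(self.cycles, dtype=float)
        flu = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", cyc)
        object.__setattr__(self, "fluorescence", flu)
        if cyc.ndim != 1 or flu.ndim != 1 or len(cyc) != len(flu):
            raise ValueError(
                f"well {self.well_id}: cycles and fluorescence must be "
                f"1-D sequences of equal length"
            )
        if len(cyc) > 1 and not np.all(np.diff(cyc) > 0):
            raise ValueError(f"well {self.well_id}: cycles must be strictly increasing")
        if not np.all(np.isfinite(flu)):
            bad = int(cyc[~np.isfinite(flu)][0])
            raise TableFormatError(
                f"well {self.well_id}: non-finite fluorescence at cycle {bad}"
            )

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class MeltRamp:
    """One well's fluorescence over a post-amplification temperature ramp."""

    well_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        tem = np.asarray(self.temperatures, dtype=float)
        flu = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", tem)
        object.__setattr__(self, "fluorescence", flu)
        if tem.ndim != 1 or flu.ndim != 1 or len(tem) != len(flu):
            raise ValueError(
                f"well {self.well_id}: temperatures and fluorescence must be "
                f"1-D sequences of equal length"
            )
        if len(tem) > 1 and not np.all(np.diff(tem) > 0):
            raise TableFormatError(
                f"well {self.well_id}: temperatures must be strictly increasing"
            )
        if len(tem) and tem[-1] - tem[0] < 10.0:
            raise TableFormatError(
                f"well {self.well_id}: melt ramp spans "
                f"{tem[-1] - tem[0]:.1f} degC; at least 10 degC required"
            )

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class DesignRow:
    well_id: str
    sample_id: str
    target: Target
    replicate_index: int = 1
    role: str = "unknown"  # "unknown" | "standard"
    log10_copies: float | None = None


@dataclass
class DesignSheet:
    """Validated experiment layout: one row per well."""

    rows: list[DesignRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.well_id in seen:
                raise TableFormatError(f"well {row.well_id} appears more than once")
            seen.add(row.well_id)
            if row.role not in ("unknown", "standard"):
                raise TableFormatError(
                    f"well {row.well_id}: role must be 'unknown' or 'standard', "
                    f"got {row.role!r}"
                )
            if row.role == "standard" and row.log10_copies is None:
                raise TableFormatError(
                    f"well {row.well_id}: standard wells must carry log10_copies"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def well(self, well_id: str) -> DesignRow:
        for row in self.rows:
            if row.well_id == well_id:
                return row
        raise KeyError(well_id)

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for row in self.rows:
            if row.role == "unknown" and row.sample_id not in out:
                out.append(row.sample_id)
        return out

    def wells_for(self, sample_id: str, target: Target) -> list[DesignRow]:
        return [
            r
            for r in self.rows
            if r.sample_id == sample_id and r.target is target and r.role == "unknown"
        ]

    def standards(self, target: Target | None = None) -> list[DesignRow]:
        return [
            r
            for r in self.rows
            if r.role == "standard" and (target is None or r.target is target)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": [r.well_id for r in self.rows],
                "sample_id": [r.sample_id for r in self.rows],
                "target": [r.target.value for r in self.rows],
                "replicate_index": [r.replicate_index for r in self.rows],
                "role": [r.role for r in self.rows],
                "log10_copies": [
                    "" if r.log10_copies is None else r.log10_copies for r in self.rows
                ],
            }
        )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def _targets_by_well(design: DesignSheet | None) -> dict[str, Target]:
    if design is None:
        return {}
    return {row.well_id: row.target for row in design.rows}


def read_amplification_table(
    path: str | Path,
    layout: str = "long",
    design: DesignSheet | None = None,
) -> list[FluorescenceCurve]:
    """Read per-well amplification curves from a CSV file.

    ``layout='long'`` expects columns ``well, cycle, fluorescence``;
    ``layout='wide'`` expects a ``cycle`` column plus one column per well.
    Wells are returned sorted by ``well_id``; a ``design`` sheet, when given,
    supplies the target label of each well.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    targets = _targets_by_well(design)
    curves: list[FluorescenceCurve] = []
    if layout == "long":
        _require_columns(df, ["well", "cycle", "fluorescence"], str(path))
        parsed = _parse_long(df, path, value_col="fluorescence", index_col="cycle")
        for well, (cyc, flu) in parsed.items():
            curves.append(
                FluorescenceCurve(
                    well_id=well,
                    cycles=cyc,
                    fluorescence=flu,
                    target=targets.get(well, Target.OTHER),
                )
            )
    else:
        _require_columns(df, ["cycle"], str(path))
        wells = [c for c in df.columns if c != "cycle"]
        cyc = _parse_numeric(df["cycle"], path, "cycle", "cycle")
        for well in wells:
            flu = np.empty(len(df))
            for i, raw in enumerate(df[well]):
                raw = raw.strip()
                if raw == "":
                    raise TableFormatError(
                        f"{path}: blank fluorescence for well {well} "
                        f"at cycle {int(cyc[i])}"
                    )
                try:
                    flu[i] = float(raw)
                except ValueError:
                    raise TableFormatError(
                        f"{path}: non-numeric fluorescence {raw!r} for well "
                        f"{well} at cycle {int(cyc[i])}"
                    ) from None
            order = np.argsort(cyc)
            curves.append(
                FluorescenceCurve(
                    well_id=well,
                    cycles=cyc[order],
                    fluorescence=flu[order],
                    target=targets.get(well, Target.OTHER),
                )
            )
    return sorted(curves, key=lambda c: c.well_id)


def _parse_numeric(col: pd.Series, path: Path, name: str, where: str) -> np.ndarray:
    out = np.empty(len(col))
    for i, raw in enumerate(col):
        raw = str(raw).strip()
        if raw == "":
            raise TableFormatError(f"{path}: blank {name} in row {i + 2}")
        try:
            out[i] = float(raw)
        except ValueError:
            raise TableFormatError(
                f"{path}: non-numeric {name} {raw!r} in row {i + 2}"
            ) from None
    return out


def _parse_long(
    df: pd.DataFrame, path: Path, value_col: str, index_col: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    wells: dict[str, tuple[list[float], list[float]]] = {}
    seen: set[tuple[str, float]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        well = str(getattr(row, "well")).strip()
        idx_raw = str(getattr(row, index_col)).strip()
        val_raw = str(getattr(row, value_col)).strip()
        if idx_raw == "" or val_raw == "":
            raise TableFormatError(
                f"{path}: blank cell for well {well} in row {i + 2}"
            )
        try:
            idx = float(idx_raw)
        except ValueError:
            raise TableFormatError(
                f"{path}: non-numeric {index_col} {idx_raw!r} for well {well}"
            ) from None
        try:
            val = float(val_raw)
        except ValueError:
            raise TableFormatError(
                f"{path}: non-numeric {value_col} {val_raw!r} for well {well} "
                f"at {index_col} {idx_raw}"
            ) from None
        key = (well, idx)
        if key in seen:
            raise TableFormatError(
                f"{path}: duplicate ({index_col}={idx_raw}) for well {well}"
            )
        seen.add(key)
        wells.setdefault(well, ([], []))[0].append(idx)
        wells[well][1].append(val)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for well, (idxs, vals) in wells.items():
        idx_arr = np.asarray(idxs)
        val_arr = np.asarray(vals)
        order = np.argsort(idx_arr)
        out[well] = (idx_arr[order], val_arr[order])
    return out


def read_melt_table(path: str | Path) -> list[MeltRamp]:
    """Read long-format melt ramps (``well, temperature, fluorescence``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["well", "temperature", "fluorescence"], str(path))
    parsed = _parse_long(df, path, value_col="fluorescence", index_col="temperature")
    ramps = [
        MeltRamp(well_id=w, temperatures=t, fluorescence=f)
        for w, (t, f) in parsed.items()
    ]
    return sorted(ramps, key=lambda r: r.well_id)


def read_design(path: str | Path) -> DesignSheet:
    """Read and validate a design sheet CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df, ["well_id", "sample_id", "target", "replicate_index", "role"], str(path)
    )
    rows = []
    for i, rec in df.iterrows():
        log10 = str(rec.get("log10_copies", "")).strip()
        rows.append(
            DesignRow(
                well_id=str(rec["well_id"]).strip(),
                sample_id=str(rec["sample_id"]).strip(),
                target=Target.parse(rec["target"]),
                replicate_index=int(float(rec["replicate_index"] or 1)),
                role=str(rec["role"]).strip() or "unknown",
                log10_copies=float(log10) if log10 else None,
            )
        )
    return DesignSheet(rows=rows)


def _format_float(x: float) -> str:
    if isinstance(x, str):
        return x
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def write_amplification_table(
    curves: Iterable[FluorescenceCurve], path: str | Path
) -> Path:
    """Write curves as a long-format CSV (canonical serialization)."""
    path = Path(path)
    lines = ["well,cycle,fluorescence"]
    for curve in sorted(curves, key=lambda c: c.well_id):
        for cyc, flu in zip(curve.cycles, curve.fluorescence):
            lines.append(f"{curve.well_id},{int(cyc)},{_format_float(flu)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_melt_table(ramps: Iterable[MeltRamp], path: str | Path) -> Path:
    path = Path(path)
    lines = ["well,temperature,fluorescence"]
    for ramp in sorted(ramps, key=lambda r: r.well_id):
        for tem, flu in zip(ramp.temperatures, ramp.fluorescence):
            lines.append(f"{ramp.well_id},{_format_float(tem)},{_format_float(flu)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_design(design: DesignSheet, path: str | Path) -> Path:
    path = Path(path)
    df = design.to_frame()
    lines = [",".join(df.columns)]
    for rec in df.itertuples(index=False):
        vals = [str(v) if not isinstance(v, float) else _format_float(v) for v in rec]
        lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


#: deterministic column order of the result table
RESULT_COLUMNS = [
    "sample",
    "target",
    "method",
    "Cq",
    "E",
    "CqE",
    "RIV_percent",
    "RIV_SE",
    "sum_percent",
    "deviation_D",
    "qc_pass",
]


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write the result table with deterministic column order and row sort.

    ``results`` must carry (a subset of) :data:`RESULT_COLUMNS`; missing
    columns are emitted empty so the header is always complete.  Re-writing a
    read-back file is byte-identical.
    """
    path = Path(path)
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[RESULT_COLUMNS]
    if len(df):
        df = df.sort_values(["sample", "target", "method"], kind="mergesort")
    lines = [",".join(RESULT_COLUMNS)]
    for rec in df.itertuples(index=False):
        vals = []
        for col, v in zip(RESULT_COLUMNS, rec):
            if col in ("sample", "target", "method"):
                vals.append(str(v))
            elif col == "qc_pass":
                vals.append("" if v == "" or v is None else str(bool(v)))
            else:
                vals.append(_format_float(v))
        lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, RESULT_COLUMNS, str(path))
    for col in RESULT_COLUMNS:
        if col in ("sample", "target", "method"):
            continue
        if col == "qc_pass":
            df[col] = df[col].map(lambda s: "" if s == "" else s == "True")
        else:
            df[col] = df[col].map(lambda s: "" if s == "" else float(s))
    return df
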