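"""Readers and writers for the tabular formats the pipeline consumes.

Axial-geometry tables and flow-waveform tables are accepted as CSV/TSV
(header row) or XLSX workbooks; group summary tables are written in the
wide six-cell layout (two implantation groups × three MRI time points)
and round-trip losslessly.

Column headers are mapped through a :class:`TableDialect`, so files with
arbitrary header strings can be read by supplying the mapping in a
config file instead of renaming columns by hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AxialGrid,
    AxialProfile,
    FlowWaveform,
    FormatError,
    ValidationError,
)

__all__ = [
    "TableDialect",
    "read_axial_profile",
    "read_flow_waveforms",
    "write_flow_waveforms",
    "write_axial_profile",
    "write_summary_table",
    "read_summary_table",
    "SUMMARY_CELL_ORDER",
]

log = logging.getLogger(__name__)

#: Canonical geometry column names.
_GEOM_COLS = ("z", "A_c", "A_d", "P_c", "P_d")
#: Canonical waveform column names (T optional).
_FLOW_COLS = ("level_z", "t", "Q")

#: Group/time-point cell order of the wide summary layout.
SUMMARY_CELL_ORDER = (
    ("PRE-2", "cervical"),
    ("PRE-2", "lumbar"),
    ("POST-1", "cervical"),
    ("POST-1", "lumbar"),
    ("POST-2", "cervical"),
    ("POST-2", "lumbar"),
)


@dataclass(frozen=True)
class TableDialect:
    """How to interpret one tabular source.

    Parameters
    ----------
    columns
        Mapping from canonical names (``z``, ``A_c`` … ``level_z``, ``t``,
        ``Q``, ``T``) to the header strings actually present. Unmapped
        canonical names are looked up verbatim.
    flip_sign
        Negate Q on read, for sources using the caudal-positive
        convention.
    sheet
        XLSX sheet name(s); ``None`` reads all sheets.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    flip_sign: bool = False
    sheet: str | Sequence[str] | None = None

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _read_table(path: str | Path, dialect: TableDialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        sheets = pd.read_excel(path, sheet_name=dialect.sheet)
        if isinstance(sheets, dict):
            frames = [df for df in sheets.values() if not df.empty]
            if not frames:
                raise FormatError(f"{path}: workbook contains no data")
            return pd.concat(frames, ignore_index=True)
        return sheets
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc


def _require_columns(df: pd.DataFrame, canonical: Iterable[str], dialect: TableDialect,
                     path: str | Path) -> dict[str, str]:
    mapping = {}
    for name in canonical:
        actual = dialect.resolve(name)
        if actual not in df.columns:
            raise FormatError(f"{path}: missing required column {actual!r} (for {name!r})")
        mapping[name] = actual
    return mapping


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise FormatError(f"{path}: non-numeric value in column {col!r} at row {row}")
    if values.isna().any():
        row = int(np.argmax(values.isna().to_numpy()))
        raise FormatError(f"{path}: missing value in column {col!r} at row {row}")
    return values.to_numpy(dtype=float)


def read_axial_profile(path: str | Path, dialect: TableDialect | None = None) -> AxialProfile:
    """Read a per-z geometry table into an :class:`AxialProfile`.

    The table must provide columns for z (mm), cord/dura areas (mm²) and
    cord/dura perimeters (mm). A non-uniform z grid is linearly resampled
    onto a uniform grid with the same span and median spacing (logged).
    """
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect)
    if df.empty:
        raise FormatError(f"{path}: table contains no rows")
    cols = _require_columns(df, _GEOM_COLS, dialect, path)
    z = _numeric(df, cols["z"], path)
    if np.any(np.diff(z) <= 0):
        raise ValidationError(f"{path}: z positions must be strictly increasing")
    fields = {name: _numeric(df, cols[name], path) for name in ("A_c", "A_d", "P_c", "P_d")}

    dz_all = np.diff(z)
    uniform = np.ptp(dz_all) <= 1e-9 * max(abs(z[-1] - z[0]), 1.0)
    if not uniform:
        dz = float(np.median(dz_all))
        n = int(round((z[-1] - z[0]) / dz))
        z_new = z[0] + np.arange(n + 1) * dz
        log.warning("%s: non-uniform axial grid; resampling to dz = %g mm", path, dz)
        fields = {k: np.interp(z_new, z, v) for k, v in fields.items()}
        z = z_new
    grid = AxialGrid(z - z[0]) if abs(z[0]) > 1e-12 else AxialGrid(z)
    return AxialProfile(grid=grid, **fields)


def write_axial_profile(profile: AxialProfile, path: str | Path) -> None:
    """Write an axial profile (including derived columns when present)."""
    data = {
        "z": profile.grid.z,
        "A_c": profile.A_c,
        "A_d": profile.A_d,
        "P_c": profile.P_c,
        "P_d": profile.P_d,
    }
    for name in ("A_sas", "P_sas", "D_h"):
        val = getattr(profile, name)
        if val is not None:
            data[name] = val
    pd.DataFrame(data).to_csv(path, index=False)


def read_flow_waveforms(path: str | Path, dialect: TableDialect | None = None
                        ) -> list[FlowWaveform]:
    """Read cardiac-gated waveforms, one block per axial level.

    Expects long-format columns ``level_z`` (mm), ``t`` (s), ``Q`` (mL/s)
    and optionally ``T`` (cardiac period, s; otherwise inferred as the
    t-range plus one sample step). Returns waveforms sorted rostral →
    caudal. At least two levels are required (a single level cannot
    support wave-speed estimation).
    """
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect)
    if df.empty:
        raise FormatError(f"{path}: table contains no rows")
    cols = _require_columns(df, _FLOW_COLS, dialect, path)
    level = _numeric(df, cols["level_z"], path)
    t_all = _numeric(df, cols["t"], path)
    q_all = _numeric(df, cols["Q"], path)
    if dialect.flip_sign:
        q_all = -q_all
    T_col = dialect.resolve("T")
    T_all = _numeric(df, T_col, path) if T_col in df.columns else None

    waveforms = []
    seen: set[float] = set()
    for lz in np.unique(level):
        if any(abs(lz - s) < 1e-9 for s in seen):
            raise ValidationError(f"{path}: duplicate waveform level z = {lz:g} mm")
        seen.add(float(lz))
        mask = level == lz
        t = t_all[mask]
        order = np.argsort(t)
        t, q = t[order], q_all[mask][order]
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{path}: duplicate time samples at level z = {lz:g} mm")
        if T_all is not None:
            T = float(T_all[mask][0])
        else:
            T = float(t[-1] - t[0] + np.median(np.diff(t)))
        waveforms.append(FlowWaveform(level_z=float(lz), t=t - t[0], Q=q, T=T))
    if len(waveforms) < 2:
        raise ValidationError(
            f"{path}: at least two axial levels are required, got {len(waveforms)}"
        )
    waveforms.sort(key=lambda w: w.level_z)
    return waveforms


def write_flow_waveforms(waveforms: Sequence[FlowWaveform], path: str | Path) -> None:
    """Write waveforms in the long format read_flow_waveforms accepts."""
    frames = [
        pd.DataFrame({"level_z": w.level_z, "t": w.t, "Q": w.Q, "T": w.T})
        for w in waveforms
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_summary_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write group mean ± SD summaries in the wide six-cell layout.

    ``records`` is long format with columns ``parameter``, ``unit``,
    ``group``, ``timepoint``, ``mean``, ``sd``. Cells are ordered PRE-2
    cervical/lumbar, POST-1 cervical/lumbar, POST-2 cervical/lumbar. A
    parameter appearing with two different unit strings is rejected.
    """
    required = {"parameter", "unit", "group", "timepoint", "mean", "sd"}
    missing = required - set(records.columns)
    if missing:
        raise FormatError(f"summary records missing columns: {sorted(missing)}")
    units = records.groupby("parameter")["unit"].nunique()
    mixed = units[units > 1]
    if not mixed.empty:
        raise ValidationError(
            f"mixed units for parameter(s): {', '.join(mixed.index)}"
        )
    order = {p: i for i, p in enumerate(dict.fromkeys(records["parameter"]))}
    rows = []
    for param, sub in records.groupby("parameter", sort=False):
        row: dict[str, object] = {"parameter": param, "unit": sub["unit"].iloc[0]}
        for tp, grp in SUMMARY_CELL_ORDER:
            cell = sub[(sub["timepoint"] == tp) & (sub["group"] == grp)]
            label = f"{tp} {grp}"
            row[f"{label} mean"] = cell["mean"].iloc[0] if not cell.empty else np.nan
            row[f"{label} sd"] = cell["sd"].iloc[0] if not cell.empty else np.nan
        rows.append(row)
    rows.sort(key=lambda r: order[r["parameter"]])
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    """Read a wide summary table back into long format (inverse of write)."""
    wide = pd.read_csv(path)
    records = []
    for _, row in wide.iterrows():
        for tp, grp in SUMMARY_CELL_ORDER:
            label = f"{tp} {grp}"
            if f"{label} mean" not in wide.columns:
                continue
            mean, sd = row[f"{label} mean"], row[f"{label} sd"]
            if pd.isna(mean) and pd.isna(sd):
                continue
            records.append(
                {
                    "parameter": row["parameter"],
                    "unit": row["unit"],
                    "group": grp,
                    "timepoint": tp,
                    "mean": mean,
                    "sd": sd,
                }
            )
    return pd.DataFrame(records)
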