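"""CSV readers/writers and the packaged equilibrium reference table.

File layouts
------------
``descriptors.csv``
    first column ``polymer_id``, remaining columns descriptor names.
``wu_timeseries.csv``
    columns ``polymer_id,time_days,wu_percent[,replicate_sd]``; a
    ``time_hours`` column is accepted instead of ``time_days``.
``wu_equilibrium.csv``
    columns ``polymer_id,wu_eq_percent,sd_percent``.

Numeric output uses Python's shortest round-trip float representation, so
write -> read reproduces values exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DescriptorTable,
    EquilibriumProperty,
    ModelingDataset,
    ParseError,
    PlateauConfig,
    PropertySeries,
    TargetKind,
)

__all__ = [
    "read_descriptor_table",
    "write_descriptor_table",
    "read_equilibrium_table",
    "write_equilibrium_table",
    "read_timeseries",
    "write_timeseries",
    "read_property_data",
    "write_predictions",
    "load_reference_equilibrium",
]


def _repr_float(v) -> str:
    # shortest round-trip representation (plain float, not np.float64 repr)
    return repr(float(v))


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"malformed CSV {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")
    return vals.to_numpy(dtype=float)


def read_descriptor_table(
    path: str | Path, drop_incomplete: bool = True
) -> DescriptorTable:
    """Load a descriptor CSV.

    Columns containing missing cells are dropped when ``drop_incomplete``
    (polymers are scarce, descriptors abundant); otherwise they raise.
    """
    df = _read_csv(path)
    if df.columns[0] != "polymer_id":
        raise ParseError(f"{path}: first column must be 'polymer_id'")
    ids = df["polymer_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicated polymer id(s) {dup}")
    names = [str(c) for c in df.columns[1:]]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"{path}: duplicated descriptor name(s) {dup}")
    cols, kept = [], []
    n_dropped = 0
    for name in names:
        vals = pd.to_numeric(df[name], errors="coerce")
        if vals.isna().any():
            if drop_incomplete:
                n_dropped += 1
                continue
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing/non-numeric cell in {name!r}, row {row}")
        kept.append(name)
        cols.append(vals.to_numpy(dtype=float))
    values = np.column_stack(cols) if cols else np.empty((len(ids), 0))
    table = DescriptorTable(tuple(ids), tuple(kept), values)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "read_descriptor_table: dropped %d incomplete descriptor column(s)", n_dropped
        )
    return table


def write_descriptor_table(path: str | Path, table: DescriptorTable) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_repr_float)


def read_equilibrium_table(path: str | Path) -> list[EquilibriumProperty]:
    df = _read_csv(path)
    _require_columns(df, ["polymer_id", "wu_eq_percent", "sd_percent"], path)
    ids = df["polymer_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicated polymer id(s) {dup}")
    wu = _numeric(df, "wu_eq_percent", path)
    sd = _numeric(df, "sd_percent", path)
    return [EquilibriumProperty(p, float(w), float(s)) for p, w, s in zip(ids, wu, sd)]


def write_equilibrium_table(
    path: str | Path, eqs: Iterable[EquilibriumProperty]
) -> None:
    rows = [(e.polymer_id, e.wu_eq, e.sd_exp) for e in eqs]
    pd.DataFrame(rows, columns=["polymer_id", "wu_eq_percent", "sd_percent"]).to_csv(
        path, index=False, float_format=_repr_float
    )


def read_timeseries(path: str | Path) -> list[PropertySeries]:
    """Load ``wu_timeseries.csv`` into one series per polymer.

    Time is stored internally in days; a ``time_hours`` column is converted
    (6 h -> 0.25 d).
    """
    df = _read_csv(path)
    if "time_days" in df.columns:
        t = _numeric(df, "time_days", path)
    elif "time_hours" in df.columns:
        t = _numeric(df, "time_hours", path) / 24.0
    else:
        raise ParseError(f"{path}: need a 'time_days' or 'time_hours' column")
    _require_columns(df, ["polymer_id", "wu_percent"], path)
    wu = _numeric(df, "wu_percent", path)
    rep = _numeric(df, "replicate_sd", path) if "replicate_sd" in df.columns else None
    out = []
    ids = df["polymer_id"].astype(str).to_numpy()
    for pid in dict.fromkeys(ids):  # preserve first-appearance order
        m = ids == pid
        order = np.argsort(t[m], kind="stable")
        out.append(
            PropertySeries(
                pid,
                t[m][order],
                wu[m][order],
                rep[m][order] if rep is not None else None,
            )
        )
    return out


def write_timeseries(path: str | Path, series: Iterable[PropertySeries]) -> None:
    rows = []
    for s in series:
        for i in range(len(s)):
            rows.append(
                (
                    s.polymer_id,
                    s.times[i],
                    s.wu_percent[i],
                    s.replicate_sd[i] if s.replicate_sd is not None else "",
                )
            )
    pd.DataFrame(
        rows, columns=["polymer_id", "time_days", "wu_percent", "replicate_sd"]
    ).to_csv(path, index=False, float_format=_repr_float)


def read_property_data(
    path: str | Path,
    descriptors: DescriptorTable,
    target_kind: TargetKind,
    plateau: PlateauConfig | None = None,
) -> ModelingDataset:
    """Join a property CSV with a descriptor table into a ModelingDataset.

    ``target_kind="equilibrium"`` accepts either an equilibrium CSV or a
    time-series CSV (consolidated through the plateau rule);
    ``"all_points"`` requires the time-series layout.
    """
    df = _read_csv(path)
    is_series = "time_days" in df.columns or "time_hours" in df.columns
    if target_kind == "all_points":
        if not is_series:
            raise ParseError(f"{path}: all_points target requires a time-series CSV")
        return ModelingDataset.from_series(descriptors, read_timeseries(path), plateau)
    if is_series:
        from .core import estimate_equilibrium

        eqs = [estimate_equilibrium(s, plateau) for s in read_timeseries(path)]
        return ModelingDataset.from_equilibrium(descriptors, eqs)
    return ModelingDataset.from_equilibrium(descriptors, read_equilibrium_table(path))


def write_predictions(path: str | Path, records: Iterable[Mapping]) -> None:
    """Write prediction records (mappings with identical keys) as CSV."""
    df = pd.DataFrame(list(records))
    df.to_csv(path, index=False, float_format=_repr_float)


def load_reference_equilibrium() -> list[EquilibriumProperty]:
    """Packaged reference table: measured equilibrium water uptake for 18
    L-tyrosine-derived polyarylates (mean +/- SD, percent of dry mass)."""
    ref = resources.files("polysorb.data") / "wu_equilibrium_reference.csv"
    with resources.as_file(ref) as p:
        return read_equilibrium_table(p)
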