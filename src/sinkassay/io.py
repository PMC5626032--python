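"""Readers and writers for plate-fluorometer kinetic exports and catalogs.

Two input formats are supported:

* the *canonical* dialect — a delimited table whose first column is elapsed
  time and whose remaining columns are wells (header ``time_min,A1,A2,...``;
  ``time_s`` marks seconds, and ``h:mm:ss`` strings are accepted);
* a best-effort ``softmax_block`` reader for SoftMax-style ``.txt``
  exports, which skips banner lines and locates the kinetic block by its
  "Time" column.

Times are normalized to elapsed minutes internally. A well catalog CSV
(columns ``well, species, growth_phase, replicate_group, plate_format``
plus optional ``strain, depth_mm``) maps wells to cultures.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import DEFAULT_DEPTH_MM

__all__ = [
    "PlateKinetics",
    "WellCatalog",
    "read_plate_export",
    "read_catalog",
    "write_kinetics",
    "write_results",
    "GROWTH_PHASES",
    "PLATE_GEOMETRY",
]

logger = logging.getLogger(__name__)

GROWTH_PHASES = frozenset({"exponential", "stationary"})

#: rows x columns for the supported plate formats
PLATE_GEOMETRY: Mapping[int, tuple[str, int]] = {96: ("ABCDEFGH", 12), 24: ("ABCD", 6)}

_WELL_RE = re.compile(r"^([A-Z])(\d{1,2})$")
_HMS_RE = re.compile(r"^\d{1,2}:\d{2}(:\d{2}(\.\d+)?)?$")


def valid_well(well_id: str, plate_format: int) -> bool:
    """True when ``well_id`` (e.g. ``A1``) exists on the given plate format."""
    m = _WELL_RE.match(well_id.strip().upper())
    if not m or plate_format not in PLATE_GEOMETRY:
        return False
    rows, ncol = PLATE_GEOMETRY[plate_format]
    return m.group(1) in rows and 1 <= int(m.group(2)) <= ncol


@dataclass
class PlateKinetics:
    """A kinetic read: elapsed minutes plus a well x time RFU matrix.

    ``rfu`` is a DataFrame with one row per well and one column per read
    (columns are the elapsed minutes). NaN cells mark dropped reads for
    that well only; fits drop them pairwise.
    """

    times: np.ndarray
    rfu: pd.DataFrame
    plate_format: int = 96
    depth_mm: float = DEFAULT_DEPTH_MM
    read_interval_min: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty time vector")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 2
            raise ValueError(f"times not strictly increasing at row {bad}")
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")
        if self.rfu.shape[1] != self.times.size:
            raise ValueError("rfu matrix width does not match the time vector")
        vals = self.rfu.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError("non-finite RFU values")
        if self.read_interval_min is None and self.times.size > 1:
            self.read_interval_min = float(np.median(np.diff(self.times)))

    @classmethod
    def from_traces(
        cls,
        times,
        traces: Mapping[str, np.ndarray],
        plate_format: int = 96,
        depth_mm: float = DEFAULT_DEPTH_MM,
    ) -> "PlateKinetics":
        times = np.asarray(times, dtype=float)
        rfu = pd.DataFrame(
            {w: np.asarray(v, dtype=float) for w, v in traces.items()}
        ).T
        rfu.columns = times
        return cls(times=times, rfu=rfu, plate_format=plate_format, depth_mm=depth_mm)

    @property
    def wells(self) -> list[str]:
        return list(self.rfu.index)

    def trace(self, well: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, rfu) for one well with NaN reads dropped pairwise."""
        if well not in self.rfu.index:
            raise KeyError(f"well {well} not present in the kinetic export")
        y = self.rfu.loc[well].to_numpy(dtype=float)
        keep = np.isfinite(y)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("well %s: dropped %d missing reads", well, dropped)
        return self.times[keep], y[keep]


@dataclass
class WellCatalog:
    """Per-well culture metadata backed by a DataFrame."""

    table: pd.DataFrame

    REQUIRED = ("well", "species", "growth_phase", "replicate_group", "plate_format")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"catalog missing required columns: {missing}")
        t = self.table.copy()
        blank = t["well"].isna() | (t["well"].astype(str).str.strip() == "")
        if blank.any():
            logger.warning("catalog: dropped %d rows with blank well id", int(blank.sum()))
            t = t[~blank]
        t["well"] = t["well"].astype(str).str.strip().str.upper()
        dup = t["well"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate well ids in catalog: {sorted(t['well'][dup].unique())}"
            )
        bad_phase = ~t["growth_phase"].isin(GROWTH_PHASES)
        if bad_phase.any():
            raise ValueError(
                f"unknown growth_phase values {sorted(t['growth_phase'][bad_phase].unique())}; "
                f"allowed: {sorted(GROWTH_PHASES)}"
            )
        t["plate_format"] = t["plate_format"].astype(int)
        for _, row in t.iterrows():
            if not valid_well(row["well"], row["plate_format"]):
                raise ValueError(
                    f"well {row['well']} is not valid for a {row['plate_format']}-well plate"
                )
        if "strain" not in t.columns:
            t["strain"] = ""
        if "depth_mm" not in t.columns:
            t["depth_mm"] = np.nan
        self.table = t.reset_index(drop=True)

    @property
    def wells(self) -> list[str]:
        return list(self.table["well"])

    def __len__(self) -> int:
        return len(self.table)

    def row(self, well: str) -> pd.Series:
        hit = self.table[self.table["well"] == well]
        if hit.empty:
            raise KeyError(f"well {well} not in catalog")
        return hit.iloc[0]

    def depth_mm(self, well: str, default: float = DEFAULT_DEPTH_MM) -> float:
        v = self.row(well).get("depth_mm", np.nan)
        return float(v) if v == v and v is not None else default  # NaN-safe


def _parse_time_token(tok: str, unit: str) -> float:
    """One time cell -> elapsed minutes. Accepts numbers and h:mm:ss."""
    tok = tok.strip()
    if _HMS_RE.match(tok):
        parts = [float(p) for p in tok.split(":")]
        if len(parts) == 2:  # mm:ss
            return parts[0] + parts[1] / 60.0
        h, m, s = parts
        return h * 60.0 + m + s / 60.0
    value = float(tok)
    if unit == "s":
        return value / 60.0
    if unit == "h":
        return value * 60.0
    return value


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_plate_export(
    path,
    dialect: str = "canonical",
    time_unit: str = "auto",
    plate_format: int = 96,
    depth_mm: float = DEFAULT_DEPTH_MM,
) -> PlateKinetics:
    """Read a kinetic export into a :class:`PlateKinetics`.

    Parameters
    ----------
    dialect : {"canonical", "softmax_block"}
        ``canonical``: delimited table, first column elapsed time, one
        column per well. ``softmax_block``: best-effort SoftMax-style
        ``.txt`` (banner lines skipped; kinetic block located by its
        "Time" header; a "Temperature" column, if present, is dropped).
    time_unit : {"auto", "min", "s", "h"}
        Unit of a numeric time column. ``auto`` infers from the header
        (``time_s``/``time_sec`` means seconds, ``time_h`` hours,
        otherwise minutes); ``h:mm:ss`` strings are always recognized.
    """
    path = Path(path)
    if dialect not in {"canonical", "softmax_block"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty kinetic export: {path}")
    lines = [ln for ln in text.splitlines() if ln.strip()]

    if dialect == "softmax_block":
        start = None
        for i, ln in enumerate(lines):
            first = re.split(r"[\t,]", ln.strip())[0].strip().strip('"').lower()
            if first.startswith("time"):
                start = i
                break
        if start is None:
            raise ValueError("softmax_block: no kinetic block with a 'Time' column found")
        lines = lines[start:]
        # block ends at the first structurally different line (e.g. '~End')
        body = [lines[0]]
        delim = _sniff_delimiter(lines[0])
        width = len(lines[0].split(delim))
        for ln in lines[1:]:
            if len(ln.split(delim)) < max(2, width - 1):
                break
            body.append(ln)
        lines = body

    delim = _sniff_delimiter(lines[0])
    header = [h.strip().strip('"') for h in lines[0].split(delim)]
    if len(header) < 2:
        raise ValueError("kinetic export needs a time column and at least one well")
    time_label = header[0].lower()
    if time_unit == "auto":
        if re.search(r"(_|\b)(s|sec|secs|seconds)\b", time_label):
            time_unit = "s"
        elif re.search(r"(_|\b)(h|hr|hours)\b", time_label):
            time_unit = "h"
        else:
            time_unit = "min"
    well_cols = header[1:]
    drop_cols = {
        j for j, name in enumerate(well_cols) if name.lower().startswith("temperature")
    }
    wells = [w.upper() for j, w in enumerate(well_cols) if j not in drop_cols]

    times: list[float] = []
    data: list[list[float]] = []
    for r, ln in enumerate(lines[1:], start=1):
        cells = [c.strip().strip('"') for c in ln.split(delim)]
        if len(cells) != len(header):
            raise ValueError(f"row {r}: expected {len(header)} columns, got {len(cells)}")
        try:
            tmin = _parse_time_token(cells[0], time_unit)
        except ValueError as exc:
            raise ValueError(f"row {r}: unparseable time {cells[0]!r}") from exc
        if times and tmin <= times[-1]:
            raise ValueError(
                f"times not strictly increasing at row {r} "
                f"(t={tmin:g} min after t={times[-1]:g} min)"
            )
        row_vals = []
        for j, cell in enumerate(cells[1:]):
            if j in drop_cols:
                continue
            if cell == "":
                row_vals.append(math.nan)
                continue
            try:
                row_vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"row {r}, well {well_cols[j]}: non-numeric RFU value {cell!r}"
                ) from None
        times.append(tmin)
        data.append(row_vals)
    if not times:
        raise ValueError(f"no data rows in kinetic export: {path}")
    arr = np.asarray(data, dtype=float).T  # well x time
    rfu = pd.DataFrame(arr, index=wells, columns=np.asarray(times))
    return PlateKinetics(
        times=np.asarray(times),
        rfu=rfu,
        plate_format=plate_format,
        depth_mm=depth_mm,
    )


def read_catalog(path) -> WellCatalog:
    """Read a well catalog CSV (see module docstring for the schema)."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"well": str}, skipinitialspace=True)
    table.columns = [c.strip().lower() for c in table.columns]
    return WellCatalog(table)


def write_kinetics(kinetics: PlateKinetics, path, delimiter: str = "\t") -> None:
    """Write a canonical kinetic file (``time_min`` + one column per well)."""
    path = Path(path)
    header = ["time_min", *kinetics.wells]
    mat = kinetics.rfu.to_numpy(dtype=float)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(header)
        for j, t in enumerate(kinetics.times):
            w.writerow([repr(float(t)), *(repr(float(v)) for v in mat[:, j])])


_RESULT_COLUMNS = [
    "well",
    "species",
    "growth_phase",
    "model",
    "npq_corrected",
    "breakpoint_min",
    "rate1_m_per_day",
    "rate2_m_per_day",
    "amplitude1",
    "amplitude2",
    "rss",
    "n_points",
]


def _se(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    if values.size == 1:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def write_results(results, csv_path, json_path=None, decimals: int | None = 3) -> None:
    """Write per-well results CSV plus a per-group JSON summary.

    ``results`` is an iterable of per-well mappings (or an object exposing
    ``.to_records()``, like :class:`sinkassay.pipeline.AssayResults`).
    Rates and amplitudes are rounded to ``decimals`` places in the CSV;
    the JSON carries full precision.
    """
    if hasattr(results, "to_records"):
        records = results.to_records()
    else:
        records = list(results)
    csv_path = Path(csv_path)
    df = pd.DataFrame.from_records(records)
    for col in _RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=float)
    extra = [c for c in df.columns if c not in _RESULT_COLUMNS]
    df = df[_RESULT_COLUMNS + extra]
    out = df.copy()
    if decimals is not None and len(out):
        for col in ("rate1_m_per_day", "rate2_m_per_day", "amplitude1", "amplitude2"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{decimals}f}"
            )
    out.to_csv(csv_path, index=False)

    if json_path is not None:
        groups: dict[str, dict] = {}
        if len(df) and "replicate_group" in df.columns:
            for name, sub in df.groupby("replicate_group", dropna=True):
                entry = {"n_wells": int(len(sub))}
                for col in (
                    "rate1_m_per_day",
                    "rate2_m_per_day",
                    "amplitude1",
                    "amplitude2",
                ):
                    vals = pd.to_numeric(sub[col], errors="coerce").to_numpy(dtype=float)
                    finite = vals[np.isfinite(vals)]
                    entry[col] = {
                        "mean": float(finite.mean()) if finite.size else None,
                        "se": _se(vals) if finite.size else None,
                        "n": int(finite.size),
                    }
                groups[str(name)] = entry
        Path(json_path).write_text(json.dumps(groups, indent=2, sort_keys=True))
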