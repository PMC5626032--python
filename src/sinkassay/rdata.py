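"""Reproduction helper: load `.RData` supplements via an R subprocess.

Published trace data for this assay is distributed as `.RData` files. This
module converts every data frame (and coercible matrix/vector) inside such
a file to CSV using a short ``Rscript`` one-liner, then loads the CSVs with
pandas — no Python RData parser is required, only an R installation on
PATH.

:func:`rdata_to_kinetics` additionally tries to interpret one of the loaded
frames as a kinetic table (a time column plus well columns) so that a
supplementary file can feed :func:`sinkassay.pipeline.run_assay` directly.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

from .io import PlateKinetics, read_plate_export
from .model import DEFAULT_DEPTH_MM

__all__ = ["load_rdata", "rdata_to_kinetics", "have_rscript"]

_R_DUMP = r"""
args <- commandArgs(trailingOnly = TRUE)
load(args[1])
outdir <- args[2]
for (name in ls()) {
  obj <- get(name)
  df <- tryCatch(as.data.frame(obj), error = function(e) NULL)
  if (!is.null(df)) {
    write.csv(df, file.path(outdir, paste0(name, ".csv")), row.names = FALSE)
  }
}
"""


def have_rscript() -> bool:
    return shutil.which("Rscript") is not None


def load_rdata(path) -> dict[str, pd.DataFrame]:
    """Load every data-frame-like object in an .RData file.

    Returns a mapping of R object name to DataFrame. Requires ``Rscript``
    on PATH; raises ``RuntimeError`` when it is missing or fails.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not have_rscript():
        raise RuntimeError("Rscript not found on PATH; cannot read .RData files")
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        script = tmpdir / "dump.R"
        script.write_text(_R_DUMP)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(path), str(tmpdir)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"Rscript failed reading {path.name}: {proc.stderr.strip()}")
        out = {}
        for csv in sorted(tmpdir.glob("*.csv")):
            out[csv.stem] = pd.read_csv(csv)
    if not out:
        raise RuntimeError(f"no data-frame-like objects found in {path.name}")
    return out


_TIME_COL = re.compile(r"^(elapsed[._ ]?)?time", re.IGNORECASE)
_WELL_COL = re.compile(r"^[A-Ha-h]\d{1,2}$")


def rdata_to_kinetics(
    path,
    object_name: str | None = None,
    plate_format: int = 96,
    depth_mm: float = DEFAULT_DEPTH_MM,
    time_unit: str = "min",
) -> PlateKinetics:
    """Interpret an .RData supplement as a kinetic table.

    Looks for (or is told) a data frame with a time column and well-named
    columns, writes it as a canonical TSV and reads it back through the
    standard reader, so all validation applies.
    """
    frames = load_rdata(path)
    candidates = [object_name] if object_name else list(frames)
    for name in candidates:
        df = frames.get(name)
        if df is None:
            continue
        cols = list(df.columns)
        time_cols = [c for c in cols if _TIME_COL.match(str(c))]
        well_cols = [c for c in cols if _WELL_COL.match(str(c))]
        if not time_cols or not well_cols:
            continue
        tidy = df[[time_cols[0], *well_cols]].copy()
        unit_suffix = {"min": "min", "s": "s", "h": "h"}[time_unit]
        tidy.columns = [f"time_{unit_suffix}", *[str(c).upper() for c in well_cols]]
        with tempfile.NamedTemporaryFile(
            "w", suffix=".tsv", delete=False
        ) as fh:
            tidy.to_csv(fh, sep="\t", index=False)
            tmp_path = fh.name
        try:
            return read_plate_export(
                tmp_path,
                dialect="canonical",
                plate_format=plate_format,
                depth_mm=depth_mm,
            )
        finally:
            Path(tmp_path).unlink(missing_ok=True)
    raise RuntimeError(
        f"no object in {Path(path).name} looks like a kinetic table "
        "(need a time column plus well-named columns like A1, B3)"
    )
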