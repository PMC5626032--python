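"""End-to-end sinking assay: read -> scale -> NPQ-correct -> fit -> rates.

:class:`SinkingAssay` is the modelling object: construct it from a
:class:`~sinkassay.io.PlateKinetics` and a
:class:`~sinkassay.io.WellCatalog`, call :meth:`~SinkingAssay.fit`, and get
an :class:`AssayResults` holding per-well fits, sinking rates and
replicate-group summaries. Per-well failures are quarantined — a plate
screen must not die on one bad well — and recorded on the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from . import io as pio
from .model import DEFAULT_DEPTH_MM, scale_rfu
from .segmented import (
    SegmentedFitResult,
    SegmentedLinearModel,
    SinkingRates,
    correct_npq_rise,
    extract_rates,
)

__all__ = ["AssayConfig", "WellResult", "AssayResults", "SinkingAssay", "run_assay", "plot_well"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayConfig:
    """Tunable knobs of the assay pipeline.

    ``intercept_mode`` picks which fit variant supplies the *primary*
    reported rates; the other variant is computed and reported alongside,
    since figure fits with free and depth-pinned intercepts nearly overlap
    on clean data. ``npq_correction``: ``auto`` corrects wells whose first
    fitted segment rises significantly, ``off`` never corrects, ``force``
    corrects any well whose first segment rises at all.
    """

    depth_mm: float = DEFAULT_DEPTH_MM
    alpha: float = 0.05
    min_seg: int = 3
    intercept_mode: Literal["free", "fixed"] = "free"
    npq_correction: Literal["auto", "off", "force"] = "auto"
    selection_criterion: Literal["ftest", "bic"] = "ftest"
    manual_breakpoints: Mapping[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class WellResult:
    """Everything the pipeline learned about one well."""

    well: str
    species: str
    growth_phase: str
    replicate_group: str
    fit: SegmentedFitResult
    rates: SinkingRates
    fit_fixed: SegmentedFitResult | None = None
    rates_fixed: SinkingRates | None = None
    early_min: bool = False
    depth_mm: float = DEFAULT_DEPTH_MM
    #: times / depth signal actually fitted (post NPQ excision)
    times: np.ndarray | None = None
    depth_signal: np.ndarray | None = None

    def to_record(self) -> dict:
        r, f = self.rates, self.fit
        rec = {
            "well": self.well,
            "species": self.species,
            "growth_phase": self.growth_phase,
            "replicate_group": self.replicate_group,
            "model": f.model,
            "npq_corrected": f.npq_corrected,
            "breakpoint_min": f.breakpoint_min,
            "rate1_m_per_day": r.rate1_m_per_day,
            "rate2_m_per_day": r.rate2_m_per_day,
            "amplitude1": r.amplitude1,
            "amplitude2": r.amplitude2,
            "rss": f.rss,
            "n_points": f.n_points,
            "rate1_se": r.rate1_se,
            "rate2_se": r.rate2_se,
            "intercept_mm": f.intercept_mm,
            "early_min": self.early_min,
            "rise_end_min": f.rise_end_min,
        }
        if self.rates_fixed is not None:
            rec["rate1_fixed_m_per_day"] = self.rates_fixed.rate1_m_per_day
            rec["rate2_fixed_m_per_day"] = self.rates_fixed.rate2_m_per_day
        return rec


class AssayResults:
    """Per-well results plus replicate-group means and standard errors."""

    def __init__(self, wells: list[WellResult], failures: dict[str, str], config: AssayConfig):
        self.wells = wells
        self.failures = failures
        self.config = config

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def ok(self) -> bool:
        return not self.failures

    def well(self, well_id: str) -> WellResult:
        for w in self.wells:
            if w.well == well_id:
                return w
        raise KeyError(well_id)

    def to_records(self) -> list[dict]:
        return [w.to_record() for w in self.wells]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.to_records())

    def group_summary(self) -> pd.DataFrame:
        """Mean ± SE of rates and amplitudes across wells per replicate group."""
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame()
        rows = []
        for name, sub in df.groupby("replicate_group"):
            row = {"replicate_group": name, "n_wells": len(sub)}
            for col in ("rate1_m_per_day", "rate2_m_per_day", "amplitude1", "amplitude2"):
                vals = pd.to_numeric(sub[col], errors="coerce").dropna().to_numpy()
                row[f"{col}_mean"] = vals.mean() if vals.size else np.nan
                row[f"{col}_se"] = (
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else (0.0 if vals.size else np.nan)
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir, stem: str = "sinking_results") -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        json_path = out_dir / f"{stem}_groups.json"
        pio.write_results(self, csv_path, json_path)
        return csv_path, json_path

    def summary(self) -> str:
        lines = [
            f"Sinking assay: {len(self.wells)} wells fitted, {len(self.failures)} failed"
        ]
        g = self.group_summary()
        for _, row in g.iterrows():
            lines.append(
                f"  {row['replicate_group']}: rate1 = "
                f"{row['rate1_m_per_day_mean']:.3f} +/- {row['rate1_m_per_day_se']:.3f} m/d"
                + (
                    f", rate2 = {row['rate2_m_per_day_mean']:.3f} m/d"
                    if np.isfinite(row["rate2_m_per_day_mean"])
                    else ""
                )
                + f"  (n={int(row['n_wells'])})"
            )
        for well, msg in self.failures.items():
            lines.append(f"  FAILED {well}: {msg}")
        return "\n".join(lines)


def _fit_one_well(
    times: np.ndarray,
    rfu: np.ndarray,
    depth_mm: float,
    config: AssayConfig,
    manual_psi: float | None,
):
    trace = scale_rfu(times, rfu, depth_mm=depth_mm)
    t, y = trace.times, trace.depth_signal
    npq_corrected = False
    rise_end = None
    if config.npq_correction != "off":
        corr = correct_npq_rise(
            t,
            y,
            depth_mm,
            min_seg=config.min_seg,
            force=config.npq_correction == "force",
        )
        t, y = corr.times, corr.depth_signal
        npq_corrected, rise_end = corr.npq_corrected, corr.rise_end_min

    def fit_variant(fixed: bool) -> SegmentedFitResult:
        model = SegmentedLinearModel(
            t,
            y,
            min_seg=config.min_seg,
            fixed_intercept=depth_mm if fixed else None,
        )
        res = model.fit(
            alpha=config.alpha,
            criterion=config.selection_criterion,
            breakpoint=manual_psi,
        )
        if npq_corrected:
            res = SegmentedFitResult(
                **{
                    **res.__dict__,
                    "npq_corrected": True,
                    "rise_end_min": rise_end,
                }
            )
        return res

    fit_free = fit_variant(fixed=False)
    fit_fixed = fit_variant(fixed=True)
    primary, secondary = (
        (fit_free, fit_fixed) if config.intercept_mode == "free" else (fit_fixed, fit_free)
    )
    rates = extract_rates(primary, depth_mm)
    try:
        rates_secondary = extract_rates(secondary, depth_mm)
    except ValueError:
        rates_secondary = None
    return trace, t, y, primary, rates, secondary, rates_secondary


def run_assay(
    kinetics: pio.PlateKinetics,
    catalog: pio.WellCatalog,
    config: AssayConfig | None = None,
) -> AssayResults:
    """Run the full pipeline over every cataloged well.

    Every cataloged well must be present in the kinetic export (the
    reverse is not required: un-cataloged wells are ignored). Failures of
    individual wells are recorded in ``results.failures`` and do not abort
    the run.
    """
    config = config or AssayConfig()
    missing = [w for w in catalog.wells if w not in kinetics.rfu.index]
    if missing:
        raise ValueError(
            f"wells in catalog but absent from kinetic export: {missing}"
        )
    wells: list[WellResult] = []
    failures: dict[str, str] = {}
    for well_id in catalog.wells:
        meta = catalog.row(well_id)
        depth = catalog.depth_mm(well_id, default=config.depth_mm)
        try:
            times, rfu = kinetics.trace(well_id)
            trace, t, y, fit, rates, fit2, rates2 = _fit_one_well(
                times,
                rfu,
                depth,
                config,
                config.manual_breakpoints.get(well_id),
            )
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            logger.warning("well %s failed: %s", well_id, exc)
            failures[well_id] = str(exc)
            continue
        wells.append(
            WellResult(
                well=well_id,
                species=str(meta["species"]),
                growth_phase=str(meta["growth_phase"]),
                replicate_group=str(meta["replicate_group"]),
                fit=fit,
                rates=rates,
                fit_fixed=fit2,
                rates_fixed=rates2,
                early_min=trace.early_min,
                depth_mm=depth,
                times=t,
                depth_signal=y,
            )
        )
    return AssayResults(wells, failures, config)


class SinkingAssay:
    """Modelling object for one plate: data in, :class:`AssayResults` out.

    Examples
    --------
    >>> from sinkassay import read_plate_export, read_catalog
    >>> assay = SinkingAssay(read_plate_export("plate.tsv"),
    ...                      read_catalog("catalog.csv"))       # doctest: +SKIP
    >>> results = assay.fit()                                   # doctest: +SKIP
    >>> print(results.summary())                                # doctest: +SKIP
    """

    def __init__(
        self,
        kinetics: pio.PlateKinetics,
        catalog: pio.WellCatalog,
        config: AssayConfig | None = None,
    ):
        self.kinetics = kinetics
        self.catalog = catalog
        self.config = config or AssayConfig()

    def fit(self) -> AssayResults:
        return run_assay(self.kinetics, self.catalog, self.config)


def plot_well(result: WellResult, path) -> Path:
    """Plot one well's depth signal with its fitted segment line(s).

    Shows the depth signal (mm) versus elapsed minutes, the fitted single
    or two-segment line, a marker at the breakpoint, and — when an NPQ
    rise was excised — a shaded band over the discarded interval.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fit = result.fit
    t, y = result.times, result.depth_signal
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t, y, "o", ms=4, color="0.3", label="depth signal")
    tt = np.linspace(t.min(), t.max(), 200)
    ax.plot(tt, fit.predict(tt), "-", color="tab:blue", label=f"{fit.model} fit")
    if fit.model == "segmented":
        ax.axvline(fit.breakpoint_min, ls="--", color="tab:red", lw=1)
        ax.plot(
            [fit.breakpoint_min],
            [fit.predict(fit.breakpoint_min)],
            "s",
            color="tab:red",
            label=f"breakpoint {fit.breakpoint_min:.1f} min",
        )
    if fit.npq_corrected and fit.rise_end_min is not None:
        ax.axvspan(0, fit.rise_end_min, color="tab:orange", alpha=0.15, label="NPQ rise (excised)")
    ax.set_xlabel("Elapsed time (min)")
    ax.set_ylabel(f"sqrt(scaled RFU) x {result.depth_mm:g} mm")
    ax.set_title(f"{result.well} — {result.species} ({result.growth_phase})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
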