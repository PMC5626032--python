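"""Single-line and one-breakpoint piecewise-linear fits of the depth signal.

The depth signal ``sqrt(scaled RFU) * depth_mm`` of a sinking culture
declines linearly while one subpopulation dominates; a second, slower
subpopulation shows up as a change of slope. The model fitted here is the
continuous two-segment line

    y(t) = a + b1 * t                      for t <= psi
    y(t) = a + b1 * psi + b2 * (t - psi)   for t >  psi

with the two segments forced to meet at the breakpoint ``psi``. For a
given ``psi`` the model is linear in (a, b1, b2), so ``psi`` is estimated
by profiling: every admissible midpoint between consecutive observed times
is tried, the conditionally linear least-squares problem is solved at each,
the minimum-RSS candidate wins, and the breakpoint is then refined by
bounded scalar minimization inside the winning inter-observation interval.
This is deterministic and directly checkable against an exhaustive grid.

An initial *rise* of fluorescence — slow relaxation of non-photochemical
quenching (NPQ) after the drop from growth light to the dark plate
chamber — can mask early sinking. :func:`correct_npq_rise` detects a
positive first segment, discards it, extrapolates the sinking segment back
to t = 0 and rescales so the extrapolated intercept is the culture depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .model import MIN_PER_DAY, MM_PER_M, slope_to_rate

__all__ = [
    "LineFit",
    "SegmentedFitResult",
    "SinkingRates",
    "NpqCorrection",
    "SegmentedLinearModel",
    "fit_line",
    "fit_segmented",
    "select_model",
    "correct_npq_rise",
    "amplitudes",
    "extract_rates",
]


@dataclass(frozen=True)
class LineFit:
    """Ordinary least-squares straight line ``y = intercept + slope * t``."""

    slope: float
    intercept: float
    rss: float
    n_points: int
    slope_se: float
    intercept_se: float
    fixed_intercept: bool = False

    @property
    def n_params(self) -> int:
        return 1 if self.fixed_intercept else 2

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class SegmentedFitResult:
    """A fitted piecewise-linear (or single-line) model of one trace.

    ``model`` records which structure this result represents; for
    ``"single"`` the second slope and breakpoint are None. Slope standard
    errors are conditional on the fitted breakpoint.
    """

    model: Literal["single", "segmented"]
    intercept_mm: float
    slope1_mm_per_min: float
    rss: float
    n_points: int
    slope1_se: float
    intercept_se: float
    slope2_mm_per_min: float | None = None
    breakpoint_min: float | None = None
    slope2_se: float | None = None
    fixed_intercept: bool = False
    npq_corrected: bool = False
    rise_end_min: float | None = None
    manual_breakpoint: bool = False

    @property
    def n_params(self) -> int:
        k = 2 if self.model == "single" else 4  # breakpoint counts as a parameter
        return k - (1 if self.fixed_intercept else 0)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        y = self.intercept_mm + self.slope1_mm_per_min * t
        if self.model == "segmented":
            psi = self.breakpoint_min
            after = t > psi
            y = np.where(
                after,
                self.intercept_mm
                + self.slope1_mm_per_min * psi
                + self.slope2_mm_per_min * (t - psi),
                y,
            )
        return y

    def summary(self) -> str:
        lines = [
            f"Piecewise-linear sinking fit ({self.model})",
            f"  n points          : {self.n_points}",
            f"  intercept (mm)    : {self.intercept_mm:.4f}"
            + ("  [fixed]" if self.fixed_intercept else f" +/- {self.intercept_se:.4f}"),
            f"  slope1 (mm/min)   : {self.slope1_mm_per_min:.5f} +/- {self.slope1_se:.5f}",
        ]
        if self.model == "segmented":
            lines += [
                f"  slope2 (mm/min)   : {self.slope2_mm_per_min:.5f} +/- {self.slope2_se:.5f}",
                f"  breakpoint (min)  : {self.breakpoint_min:.2f}"
                + ("  [manual]" if self.manual_breakpoint else ""),
            ]
        lines.append(f"  RSS               : {self.rss:.6g}")
        if self.npq_corrected:
            lines.append(f"  NPQ rise excised  : first {self.rise_end_min:.1f} min")
        return "\n".join(lines)


@dataclass(frozen=True)
class SinkingRates:
    """Per-well sinking velocities (m d^-1) and phase amplitudes.

    ``amplitude1`` is the fraction of the total fitted depth-signal drop
    attributed to the first (faster) sinking phase, interpreted as the
    relative abundance of the faster-sinking subpopulation; amplitudes sum
    to 1 and amplitude1 is 1 for single-phase wells.
    """

    rate1_m_per_day: float
    amplitude1: float
    rate1_se: float
    rate2_m_per_day: float | None = None
    amplitude2: float | None = None
    rate2_se: float | None = None
    breakpoint_min: float | None = None


@dataclass(frozen=True)
class NpqCorrection:
    """Outcome of NPQ-rise screening on one trace."""

    times: np.ndarray
    depth_signal: np.ndarray
    npq_corrected: bool
    rise_end_min: float | None = None


def fit_line(times, y, fixed_intercept: float | None = None) -> LineFit:
    """OLS straight-line fit, optionally with the intercept pinned.

    With a fixed intercept ``c`` only the slope is free:
    ``slope = sum t (y - c) / sum t^2``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 points for a line fit")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in time: cannot fit a line")
    if fixed_intercept is not None:
        c = float(fixed_intercept)
        st2 = float(np.sum(t * t))
        slope = float(np.sum(t * (y - c)) / st2)
        resid = y - c - slope * t
        rss = float(resid @ resid)
        dof = n - 1
        sigma2 = rss / dof if dof > 0 else np.nan
        return LineFit(
            slope=slope,
            intercept=c,
            rss=rss,
            n_points=n,
            slope_se=float(np.sqrt(sigma2 / st2)),
            intercept_se=0.0,
            fixed_intercept=True,
        )
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * tbar)
    resid = y - intercept - slope * t
    rss = float(resid @ resid)
    dof = n - 2
    sigma2 = rss / dof if dof > 0 else np.nan
    return LineFit(
        slope=slope,
        intercept=intercept,
        rss=rss,
        n_points=n,
        slope_se=float(np.sqrt(sigma2 / sxx)),
        intercept_se=float(np.sqrt(sigma2 * (1.0 / n + tbar**2 / sxx))),
    )


def _design(t: np.ndarray, psi: float, fixed_intercept: float | None):
    """Design matrix of the continuous two-segment model at breakpoint psi."""
    hinge = np.maximum(t - psi, 0.0)
    if fixed_intercept is None:
        return np.column_stack([np.ones_like(t), t, hinge])
    return np.column_stack([t, hinge])


def _solve_at_psi(t, y, psi, fixed_intercept):
    """Conditionally linear LS solve at a fixed breakpoint; returns (rss, beta)."""
    X = _design(t, psi, fixed_intercept)
    target = y if fixed_intercept is None else y - fixed_intercept
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ beta
    return float(resid @ resid), beta, X


def _result_at_psi(t, y, psi, fixed_intercept, **flags) -> SegmentedFitResult:
    rss, beta, X = _solve_at_psi(t, y, psi, fixed_intercept)
    n, p = X.shape
    dof = n - (p + 1)  # the breakpoint consumed one further df
    sigma2 = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    ses = np.sqrt(np.maximum(np.diag(XtX_inv), 0.0) * sigma2)
    if fixed_intercept is None:
        a, b1, d = beta
        se_a, se_b1, se_d = ses
    else:
        a, (b1, d) = float(fixed_intercept), beta
        se_a, (se_b1, se_d) = 0.0, ses
    return SegmentedFitResult(
        model="segmented",
        intercept_mm=float(a),
        slope1_mm_per_min=float(b1),
        slope2_mm_per_min=float(b1 + d),
        breakpoint_min=float(psi),
        rss=rss,
        n_points=n,
        slope1_se=float(se_b1),
        # var(b2) = var(b1 + d); from the covariance of (b1, d)
        slope2_se=float(
            np.sqrt(
                max(
                    sigma2
                    * (
                        XtX_inv[-2, -2]
                        + XtX_inv[-1, -1]
                        + 2.0 * XtX_inv[-2, -1]
                    ),
                    0.0,
                )
            )
        ),
        intercept_se=float(se_a),
        fixed_intercept=fixed_intercept is not None,
        **flags,
    )


def fit_segmented(
    times,
    y,
    min_seg: int = 3,
    fixed_intercept: float | None = None,
    breakpoint: float | None = None,
    refine: bool = True,
    psi_max: float | None = None,
) -> SegmentedFitResult:
    """Fit the continuous one-breakpoint model by RSS profiling.

    Candidate breakpoints are the midpoints between consecutive observed
    times that leave at least ``min_seg`` points on each side. The minimum
    RSS candidate (ties broken toward the earliest breakpoint) is refined
    by bounded minimization within its inter-observation interval, where
    segment membership is constant and the profile RSS is smooth.

    Parameters
    ----------
    breakpoint : float, optional
        Manual override: skip the search and fit at this breakpoint
        (used when the automatic search fails on a known two-phase well).
    psi_max : float, optional
        Restrict the search to breakpoints at or below this time — used by
        the NPQ-rise detector to isolate an early rise from later decay
        curvature.
    """
    t = np.asarray(times, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = t.size
    if breakpoint is not None:
        return _result_at_psi(t, yv, float(breakpoint), fixed_intercept, manual_breakpoint=True)
    if n < 2 * min_seg:
        raise ValueError(f"need at least {2 * min_seg} points for a segmented fit")
    order = np.argsort(t)
    t, yv = t[order], yv[order]
    # midpoint between t[i] and t[i+1] leaves i+1 points left, n-i-1 right
    idx = np.arange(min_seg - 1, n - min_seg)
    candidates = 0.5 * (t[idx] + t[idx + 1])
    if psi_max is not None:
        keep = candidates <= psi_max
        idx, candidates = idx[keep], candidates[keep]
    if candidates.size == 0:
        raise ValueError("no admissible breakpoint candidates")
    rsses = np.array([_solve_at_psi(t, yv, c, fixed_intercept)[0] for c in candidates])
    best = int(np.flatnonzero(rsses <= rsses.min() + 1e-12)[0])  # earliest tie wins
    psi, best_rss = float(candidates[best]), float(rsses[best])
    if refine:
        # the profile RSS can dip inside an interval whose midpoint is not
        # the best sample, so every admissible interval is refined
        for i in idx:
            lo, hi = t[i], t[i + 1]
            eps = 1e-9 * max(1.0, hi - lo)
            res = optimize.minimize_scalar(
                lambda p: _solve_at_psi(t, yv, p, fixed_intercept)[0],
                bounds=(lo + eps, hi - eps),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun < best_rss - 1e-15 or (
                res.fun <= best_rss + 1e-12 and res.x < psi
            ):
                psi, best_rss = float(res.x), float(res.fun)
    return _result_at_psi(t, yv, psi, fixed_intercept)


def _single_as_result(fit: LineFit, **flags) -> SegmentedFitResult:
    return SegmentedFitResult(
        model="single",
        intercept_mm=fit.intercept,
        slope1_mm_per_min=fit.slope,
        rss=fit.rss,
        n_points=fit.n_points,
        slope1_se=fit.slope_se,
        intercept_se=fit.intercept_se,
        fixed_intercept=fit.fixed_intercept,
        **flags,
    )


def select_model(
    single_fit: LineFit | SegmentedFitResult,
    segmented_fit: SegmentedFitResult,
    alpha: float = 0.05,
    criterion: Literal["ftest", "bic"] = "ftest",
) -> Literal["single", "segmented"]:
    """Choose between the single-line and segmented fits.

    The segmented model is accepted iff the extra-parameters F-test (2
    extra df: the second slope and the breakpoint) is significant at
    ``alpha`` *and* both fitted slopes are negative — a genuine two-phase
    sinking trace, not a fluorescence rise. A BIC comparison is available
    as an alternative criterion.
    """
    if segmented_fit.model != "segmented":
        return "single"
    n = segmented_fit.n_points
    rss_single = single_fit.rss
    rss_seg = segmented_fit.rss
    if not (
        segmented_fit.slope1_mm_per_min < 0 and segmented_fit.slope2_mm_per_min < 0
    ):
        return "single"
    if criterion == "bic":
        k_single = 2 - int(getattr(single_fit, "fixed_intercept", False))
        k_seg = 4 - int(segmented_fit.fixed_intercept)
        bic_single = n * np.log(max(rss_single, 1e-300) / n) + k_single * np.log(n)
        bic_seg = n * np.log(max(rss_seg, 1e-300) / n) + k_seg * np.log(n)
        return "segmented" if bic_seg < bic_single else "single"
    dof_seg = n - (4 - int(segmented_fit.fixed_intercept))
    if dof_seg <= 0:
        return "single"
    if rss_seg <= 0:
        # perfect segmented fit: significant unless the single fit is perfect too
        return "segmented" if rss_single > 1e-12 * max(1, n) else "single"
    f_stat = ((rss_single - rss_seg) / 2.0) / (rss_seg / dof_seg)
    p_value = float(stats.f.sf(max(f_stat, 0.0), 2, dof_seg))
    return "segmented" if p_value < alpha else "single"


def _second_difference_noise(y: np.ndarray) -> float:
    """Noise SD of a trace from second differences of its early portion.

    Second differences annihilate locally linear trends, so this estimates
    detector noise without detrending. The sqrt transform inflates noise
    near the terminal plateau (scaled values near zero), so the estimate
    uses the leading region where the signal is still above 30% of its
    maximum; var(d2) = 6 sigma^2 for iid noise.
    """
    y = np.asarray(y, dtype=float)
    lead = np.flatnonzero(y >= 0.3 * y.max())
    stop = int(lead.max()) + 1 if lead.size else y.size
    chunk = y[:stop] if stop >= 8 else y
    d2 = np.diff(chunk, 2)
    if d2.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(d2**2) / 6.0))


def correct_npq_rise(
    times,
    depth_signal,
    depth_mm: float,
    min_seg: int = 3,
    rise_alpha: float = 0.05,
    force: bool = False,
) -> NpqCorrection:
    """Detect and excise an initial NPQ-relaxation fluorescence rise.

    A segmented fit with a significantly positive first slope followed by a
    declining second segment marks a rise phase. The rise segment is
    discarded, the sinking segment's line is extrapolated back to t = 0,
    and the retained signal is rescaled so that extrapolated intercept
    equals ``depth_mm`` (scaled fluorescence of 1) — the state the well
    would have shown had quenching relaxed instantly.

    With ``force=True`` the one-sided significance guard on the rising
    slope is waived (the rise need only be positive).

    Raises
    ------
    ValueError
        If a rise is detected but no declining segment follows
        ("no sinking phase detected").
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(depth_signal, dtype=float)
    if t.size < 2 * min_seg:
        return NpqCorrection(t, y, False)

    # A rise phase, if present, ends at the trace maximum: test the slope
    # of the pre-peak prefix on its own points (a global segmented fit can
    # average a short rise away when the later decay is curved).
    idx_peak = int(np.argmax(y))
    if idx_peak == 0:
        return NpqCorrection(t, y, False)
    if not force:
        # One-sided guard: do not call a rise on noise alone. A short
        # prefix leaves almost no residual df, so the noise level is
        # estimated from second differences of the early trace (which
        # cancel any locally linear trend) instead of prefix residuals.
        sigma = _second_difference_noise(y)
        if not np.isfinite(sigma) or sigma <= 0:
            return NpqCorrection(t, y, False)
        if idx_peak >= 2:
            prefix = fit_line(t[: idx_peak + 1], y[: idx_peak + 1])
            if prefix.slope <= 0:
                return NpqCorrection(t, y, False)
            tp = t[: idx_peak + 1]
            sxx = float(np.sum((tp - tp.mean()) ** 2))
            z = prefix.slope / (sigma / np.sqrt(sxx))
        else:
            # a 1-read rise has no slope to regress; test its amplitude
            z = (y[idx_peak] - y[0]) / (sigma * np.sqrt(2.0))
        if float(stats.norm.sf(z)) >= rise_alpha:
            return NpqCorrection(t, y, False)
    elif idx_peak >= 2 and fit_line(t[: idx_peak + 1], y[: idx_peak + 1]).slope <= 0:
        return NpqCorrection(t, y, False)
    if idx_peak > t.size - 1 - min_seg:
        raise ValueError("no sinking phase detected after the fluorescence rise")
    psi = 0.5 * (t[idx_peak] + t[idx_peak + 1])
    keep = t > psi
    # fit the retained sinking data and extrapolate its first-phase line
    # back to t = 0; rescaling that intercept to depth_mm restores the
    # signal the well would have shown had quenching relaxed instantly
    sink_first = fit_line(t[keep], y[keep])
    if keep.sum() >= 2 * min_seg:
        try:
            seg = fit_segmented(t[keep], y[keep], min_seg=min_seg)
        except (ValueError, np.linalg.LinAlgError):
            seg = None
        if seg is not None and select_model(sink_first, seg) == "segmented":
            sink_first = LineFit(
                slope=seg.slope1_mm_per_min,
                intercept=seg.intercept_mm,
                rss=seg.rss,
                n_points=seg.n_points,
                slope_se=seg.slope1_se,
                intercept_se=seg.intercept_se,
            )
    if sink_first.slope >= 0:
        raise ValueError("no sinking phase detected after the fluorescence rise")
    y0 = sink_first.intercept
    if y0 <= 0:
        raise ValueError("rise correction produced a non-positive intercept")
    scale = depth_mm / y0
    return NpqCorrection(t[keep], y[keep] * scale, True, rise_end_min=float(psi))


def amplitudes(fit: SegmentedFitResult, depth_mm: float) -> tuple[float, float | None]:
    """Phase amplitudes: fractional depth-signal drop attributed to each phase.

    For a segmented fit ``amplitude1 = (y(0) - y(psi)) / y(0)`` on the
    fitted piecewise line, ``amplitude2 = 1 - amplitude1``; a single-line
    fit has amplitude 1 by definition (one population does all the
    sinking). Amplitudes estimate relative subpopulation abundances.
    """
    if fit.model == "single":
        return 1.0, None
    y0 = fit.intercept_mm
    if y0 <= 0:
        raise ValueError("non-positive fitted intercept: amplitudes undefined")
    y_psi = y0 + fit.slope1_mm_per_min * fit.breakpoint_min
    a1 = (y0 - y_psi) / y0
    return float(a1), float(1.0 - a1)


def extract_rates(fit: SegmentedFitResult, depth_mm: float) -> SinkingRates:
    """Convert a fitted (NPQ-corrected) model into sinking rates in m d^-1."""
    if fit.slope1_mm_per_min > 0 or (
        fit.model == "segmented" and fit.slope2_mm_per_min > 0
    ):
        raise ValueError(
            "positive (rising) slope reached rate extraction; "
            "apply NPQ correction or inspect the trace"
        )
    conv = MIN_PER_DAY / MM_PER_M
    a1, a2 = amplitudes(fit, depth_mm)
    rate1 = slope_to_rate(abs(fit.slope1_mm_per_min))
    if fit.model == "single":
        return SinkingRates(
            rate1_m_per_day=rate1,
            amplitude1=a1,
            rate1_se=fit.slope1_se * conv,
        )
    return SinkingRates(
        rate1_m_per_day=rate1,
        rate2_m_per_day=slope_to_rate(abs(fit.slope2_mm_per_min)),
        amplitude1=a1,
        amplitude2=a2,
        rate1_se=fit.slope1_se * conv,
        rate2_se=fit.slope2_se * conv,
        breakpoint_min=fit.breakpoint_min,
    )


class SegmentedLinearModel:
    """Piecewise-linear sinking model for one depth-signal trace.

    A thin statsmodels-style wrapper: construct from data, call
    :meth:`fit`, get a :class:`SegmentedFitResult` back. The functional
    API (:func:`fit_line`, :func:`fit_segmented`, :func:`select_model`)
    does the work.

    Examples
    --------
    >>> import numpy as np
    >>> t = np.arange(0, 60, 2.0)
    >>> y = np.where(t <= 20, 3.8 - 0.1 * t, 1.8 - 0.01 * (t - 20))
    >>> res = SegmentedLinearModel(t, y).fit()
    >>> res.model
    'segmented'
    """

    def __init__(
        self,
        times,
        depth_signal,
        min_seg: int = 3,
        fixed_intercept: float | None = None,
    ):
        self.times = np.asarray(times, dtype=float)
        self.depth_signal = np.asarray(depth_signal, dtype=float)
        self.min_seg = min_seg
        self.fixed_intercept = fixed_intercept

    def fit_single(self) -> SegmentedFitResult:
        return _single_as_result(
            fit_line(self.times, self.depth_signal, self.fixed_intercept)
        )

    def fit(
        self,
        alpha: float = 0.05,
        criterion: Literal["ftest", "bic"] = "ftest",
        breakpoint: float | None = None,
    ) -> SegmentedFitResult:
        """Fit both structures and return the selected one.

        A manual ``breakpoint`` bypasses both the search and the selection
        test (the analyst has asserted the well is two-phase).
        """
        single = fit_line(self.times, self.depth_signal, self.fixed_intercept)
        if breakpoint is not None:
            return fit_segmented(
                self.times,
                self.depth_signal,
                min_seg=self.min_seg,
                fixed_intercept=self.fixed_intercept,
                breakpoint=breakpoint,
            )
        try:
            seg = fit_segmented(
                self.times,
                self.depth_signal,
                min_seg=self.min_seg,
                fixed_intercept=self.fixed_intercept,
            )
        except ValueError:
            return _single_as_result(single)
        choice = select_model(single, seg, alpha=alpha, criterion=criterion)
        return seg if choice == "segmented" else _single_as_result(single)
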