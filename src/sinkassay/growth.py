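"""Gompertz growth-curve fits of daily culture fluorescence.

Daily relative fluorescence (RFU) of a batch culture is used as a proxy for
biomass. The modified Gompertz model (Zwietering parameterization) is
fitted to the log-scaled observable ``y(t) = ln(RFU_t / RFU_min)``:

    y(t) = A * exp(-exp(mu * e / A * (lam - t) + 1))

with ``A = ln(RFU_max / RFU_min)`` the log amplitude, ``mu`` (d^-1) the
maximum specific growth rate — the slope of y at the inflection — ``lam``
(d) the lag phase, and ``e`` Euler's number. The asymptotic maximum RFU is
back-calculated as ``exp(A) * RFU_min``.

Cultures are staged with :func:`detect_stationary`: stationary phase is
declared after a run of days with stable RFU (coefficient of variation at
or below a tolerance over a 3-day window by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GompertzParams",
    "GompertzModel",
    "GompertzResults",
    "gompertz_value",
    "fit_gompertz",
    "detect_stationary",
]

_E = float(np.e)


@dataclass(frozen=True)
class GompertzParams:
    """Fitted Gompertz parameters with standard errors.

    ``rfu_max_est = exp(A) * rfu_min`` is the back-calculated carrying
    capacity on the raw RFU scale.
    """

    A: float  # ln(RFU_max / RFU_min), dimensionless
    mu: float  # maximum specific growth rate, d^-1
    lam: float  # lag phase, d
    rfu_min: float
    A_se: float = float("nan")
    mu_se: float = float("nan")
    lam_se: float = float("nan")

    @property
    def rfu_max_est(self) -> float:
        return float(np.exp(self.A) * self.rfu_min)


def gompertz_value(t_days, A: float, mu: float, lam: float):
    """Modified Gompertz curve on the log scale, ``ln(RFU_t/RFU_min)``.

    Monotone nondecreasing in t for A, mu > 0; tends to A as t -> inf;
    equals ``A * exp(-e)`` at t = lam; its maximum slope is mu, attained
    at the inflection point.
    """
    t = np.asarray(t_days, dtype=float)
    return A * np.exp(-np.exp(mu * _E / A * (lam - t) + 1.0))


def _initial_guesses(days: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Multi-start initialization from the data's own shape."""
    A0 = max(float(y.max()), 1e-6)
    dy = np.diff(y) / np.diff(days)
    mu0 = max(float(dy.max()), 1e-3) if dy.size else 0.5
    # lag: last day still below 10% of the log range
    below = days[y < 0.1 * A0]
    lam0 = float(below.max()) if below.size else 0.0
    starts = [(A0, mu0, lam0)]
    starts.append((1.2 * A0, mu0, max(lam0 - 0.5, 0.0)))
    starts.append((A0, 0.5 * mu0, 0.0))
    starts.append((A0, 2.0 * mu0, lam0))
    return starts


def _log_rfu_model(t, A, mu, lam, log_baseline):
    return log_baseline + gompertz_value(t, A, mu, lam)


def fit_gompertz(days, rfu) -> GompertzParams:
    """Nonlinear least-squares Gompertz fit to a daily RFU series.

    The fit is on the log scale, ``ln(rfu_t) = ln(rfu_min) + y(t)``, with
    the log baseline a free parameter alongside (A, mu, lam): the curve
    only reaches its floor asymptotically, so pinning the baseline at the
    observed minimum would bias A by the (small, positive) value of y at
    the first observed day. The fitted baseline estimates RFU_min.
    Initialization is multi-start (amplitude from the observed log range,
    growth rate from the steepest log difference, lag from the last
    below-threshold day); the best converged start by RSS wins.

    Raises
    ------
    ValueError
        On fewer than 5 points, non-positive RFU, or non-convergence from
        every start (e.g. a flat series with no growth signal).
    """
    days = np.asarray(days, dtype=float)
    rfu = np.asarray(rfu, dtype=float)
    if days.size < 5:
        raise ValueError("need at least 5 daily points to fit a growth curve")
    if np.any(rfu <= 0):
        raise ValueError("RFU values must be positive for the log-scale fit")
    obs_min = float(rfu.min())
    log_rfu = np.log(rfu)
    y = log_rfu - np.log(obs_min)
    if float(y.max()) < 1e-3:
        raise ValueError(
            "no growth detected: log fluorescence range is essentially zero"
        )
    best = None
    diagnostics: list[str] = []
    c0 = float(np.log(obs_min))
    bounds = (
        [1e-9, 1e-9, 0.0, c0 - 2.0],
        [np.inf, np.inf, float(days.max()), c0 + 2.0],
    )
    for A0, mu0, lam0 in _initial_guesses(days, y):
        p0 = (
            min(max(A0, bounds[0][0]), 50.0),
            max(mu0, bounds[0][1]),
            min(max(lam0, 0.0), bounds[1][2]),
            c0,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _log_rfu_model,
                    days,
                    log_rfu,
                    p0=p0,
                    bounds=bounds,
                    maxfev=20000,
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
        except (RuntimeError, ValueError) as exc:
            diagnostics.append(f"start {p0}: {exc}")
            continue
        rss = float(np.sum((log_rfu - _log_rfu_model(days, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise ValueError(
            "Gompertz fit failed to converge from all starts:\n" + "\n".join(diagnostics)
        )
    _, popt, pcov = best
    ses = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return GompertzParams(
        A=float(popt[0]),
        mu=float(popt[1]),
        lam=float(popt[2]),
        rfu_min=float(np.exp(popt[3])),
        A_se=float(ses[0]),
        mu_se=float(ses[1]),
        lam_se=float(ses[2]),
    )


def detect_stationary(days, rfu, window: int = 3, tol: float = 0.05):
    """First day at which the culture has shown ``window`` days of stable RFU.

    Stability means the coefficient of variation of RFU over the trailing
    window is at most ``tol`` (so ``tol=0`` demands an exactly constant
    tail). Returns the day value, or None if the series never stabilizes
    or is shorter than the window (with a warning).
    """
    days = np.asarray(days, dtype=float)
    rfu = np.asarray(rfu, dtype=float)
    if days.size < window:
        warnings.warn("series shorter than the stationary window", stacklevel=2)
        return None
    for end in range(window - 1, days.size):
        chunk = rfu[end - window + 1 : end + 1]
        mean = chunk.mean()
        if mean == 0:
            continue
        cv = chunk.std(ddof=1) / abs(mean)
        if cv <= tol:
            return float(days[end])
    return None


class GompertzModel:
    """Gompertz growth model for one daily RFU series.

    Examples
    --------
    >>> import numpy as np
    >>> days = np.arange(15.0)
    >>> y = gompertz_value(days, 3.0, 1.2, 1.5)
    >>> res = GompertzModel(days, 100 * np.exp(y)).fit()
    >>> round(res.params.mu, 3)
    1.2
    """

    def __init__(self, days, rfu):
        self.days = np.asarray(days, dtype=float)
        self.rfu = np.asarray(rfu, dtype=float)

    def fit(self) -> "GompertzResults":
        return GompertzResults(self, fit_gompertz(self.days, self.rfu))


class GompertzResults:
    """Fitted growth curve: parameters, predictions, staging, summary."""

    def __init__(self, model: GompertzModel, params: GompertzParams):
        self.model = model
        self.params = params

    @property
    def rfu_max_est(self) -> float:
        return self.params.rfu_max_est

    def predict(self, days=None):
        """Predicted RFU on the raw scale."""
        t = self.model.days if days is None else np.asarray(days, dtype=float)
        p = self.params
        return p.rfu_min * np.exp(gompertz_value(t, p.A, p.mu, p.lam))

    def stationary_day(self, window: int = 3, tol: float = 0.05):
        return detect_stationary(self.model.days, self.model.rfu, window, tol)

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                "Gompertz growth fit (log-RFU scale)",
                f"  A   (ln RFUmax/RFUmin) : {p.A:.4f} +/- {p.A_se:.4f}",
                f"  mu  (d^-1)             : {p.mu:.4f} +/- {p.mu_se:.4f}",
                f"  lam (d)                : {p.lam:.4f} +/- {p.lam_se:.4f}",
                f"  RFU_min                : {p.rfu_min:.4g}",
                f"  RFU_max (back-calc)    : {p.rfu_max_est:.4g}",
            ]
        )
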