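"""Physical and optical model of the top-view sinking assay.

A microtitre well is read from above by a fluorescence detector. Cells are
initially suspended evenly through the culture depth (3.8 mm by default);
as they sink away from the detector the received chlorophyll-a fluorescence
falls off following the inverse-square law for an isotropic emitter:

    scaled_rfu(t) = 1 / (1 + s * t)**2

where ``s`` (min^-1) is the scaled sinking rate. Taking a square root
linearizes the decline, ``sqrt(scaled) = 1/(1 + s t) ~ 1 - s t``, so the
early decline of ``sqrt(scaled) * depth_mm`` is a straight line whose slope
(mm min^-1) converts directly to a sinking velocity in m d^-1.

This module houses the trace scaling, the depth transform, the forward
decay kernel, the slope-to-velocity conversion and a Stokes-law reference
utility. The regression machinery lives in :mod:`sinkassay.segmented`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScaledTrace",
    "StokesParams",
    "scale_rfu",
    "depth_transform",
    "forward_scaled",
    "slope_to_rate",
    "stokes_velocity",
    "MIN_PER_DAY",
    "MM_PER_M",
]

#: minutes in a day / millimetres in a metre — the slope conversion constants
MIN_PER_DAY = 1440.0
MM_PER_M = 1000.0

#: default culture depth in well plates (mm); identical for the 96- and
#: 24-well formats, which differ in well diameter, not depth.
DEFAULT_DEPTH_MM = 3.8


@dataclass(frozen=True)
class ScaledTrace:
    """A fluorescence trace scaled to [0, 1] and mapped to a depth signal.

    Attributes
    ----------
    times : ndarray
        Elapsed minutes, strictly increasing, first element 0.
    scaled : ndarray
        ``(rfu - min) / (max - min)``; exactly 1 at the trace maximum and
        0 at the minimum.
    depth_signal : ndarray
        ``sqrt(scaled) * depth_mm`` in mm — the signal the piecewise-linear
        fits operate on; its intercept has the physical value ``depth_mm``.
    rfu_min, rfu_max : float
        The scaling bounds actually used.
    depth_mm : float
        Culture depth.
    early_min : bool
        True when the trace minimum occurs before the final 10% of reads —
        a hint that the global minimum may not be the settled plateau.
    """

    times: np.ndarray
    scaled: np.ndarray
    depth_signal: np.ndarray
    rfu_min: float
    rfu_max: float
    depth_mm: float = DEFAULT_DEPTH_MM
    early_min: bool = False


@dataclass(frozen=True)
class StokesParams:
    """Parameters of Stokes' settling law for a small sphere.

    ``phi`` is the form resistance: how much more slowly the particle sinks
    than the sphere of equal volume (>= 1 for non-spheres by convention).
    """

    r: float  # particle radius, m
    rho_particle: float  # kg m^-3
    rho_water: float  # kg m^-3
    eta: float  # dynamic viscosity, kg m^-1 s^-1
    phi: float = 1.0  # form resistance, dimensionless
    g: float = 9.8  # m s^-2

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("particle radius must be positive")
        if self.eta <= 0:
            raise ValueError("viscosity must be positive")
        if self.phi <= 0:
            raise ValueError("form resistance must be positive")


def scale_rfu(
    times: np.ndarray,
    rfu: np.ndarray,
    depth_mm: float = DEFAULT_DEPTH_MM,
) -> ScaledTrace:
    """Scale a raw RFU trace to [0, 1] and attach its depth signal.

    The bounds are the global minimum and maximum of the observed trace, so
    the initial even suspension maps to a scaled value of 1 and the settled
    plateau to 0. Scaling removes arbitrary between-well differences in
    starting cell density.

    Raises
    ------
    ValueError
        On fewer than 4 finite points or a constant trace
        ("no fluorescence decline detected").
    """
    times = np.asarray(times, dtype=float)
    rfu = np.asarray(rfu, dtype=float)
    if times.shape != rfu.shape:
        raise ValueError("times and rfu must have the same length")
    finite = np.isfinite(rfu) & np.isfinite(times)
    times, rfu = times[finite], rfu[finite]
    if times.size < 4:
        raise ValueError("need at least 4 finite points to scale a trace")
    rfu_min = float(rfu.min())
    rfu_max = float(rfu.max())
    if rfu_max <= rfu_min:
        raise ValueError("no fluorescence decline detected (constant trace)")
    scaled = (rfu - rfu_min) / (rfu_max - rfu_min)
    # global min landing well before the end suggests the plateau was noisy
    idx_min = int(np.argmin(rfu))
    early_min = idx_min < int(np.ceil(0.9 * rfu.size)) - 1
    return ScaledTrace(
        times=times,
        scaled=scaled,
        depth_signal=depth_transform(scaled, depth_mm),
        rfu_min=rfu_min,
        rfu_max=rfu_max,
        depth_mm=float(depth_mm),
        early_min=early_min,
    )


def depth_transform(scaled: np.ndarray, depth_mm: float = DEFAULT_DEPTH_MM) -> np.ndarray:
    """Map a scaled trace to the depth signal ``sqrt(scaled) * depth_mm`` (mm).

    The square root inverts the inverse-square emission kernel, so a
    constant sinking velocity appears as a linear decline of this signal.
    """
    scaled = np.asarray(scaled, dtype=float)
    if depth_mm <= 0:
        raise ValueError("depth_mm must be positive")
    if np.any(scaled < 0):
        raise ValueError("scaled values must be nonnegative")
    return np.sqrt(scaled) * depth_mm


def forward_scaled(t_min, s_per_min):
    """Noise-free scaled fluorescence of a uniformly sinking population.

    ``1 / (1 + s t)**2`` — equal to 1 at t = 0 and strictly decreasing for
    s > 0. This is the generative counterpart of the linearized fits and
    the kernel of the synthetic trace simulator.
    """
    t = np.asarray(t_min, dtype=float)
    return 1.0 / (1.0 + t * s_per_min) ** 2


def slope_to_rate(slope, depth_mm: float | None = None) -> float:
    """Convert a fitted decline slope to a sinking rate in m d^-1.

    Parameters
    ----------
    slope : float
        Magnitude of the fitted decline. When ``depth_mm`` is None the fit
        was performed on the depth signal and the slope is already in
        mm min^-1; otherwise the slope is in scaled (dimensionless) units
        per minute and is first multiplied by the culture depth — the
        actual distance travelled.

    Returns
    -------
    float
        ``slope_mm_per_min * 1440 / 1000`` (m d^-1), nonnegative.
    """
    slope = float(slope)
    if slope < 0:
        raise ValueError("slope must be given as a nonnegative magnitude")
    slope_mm = slope * depth_mm if depth_mm is not None else slope
    return slope_mm * MIN_PER_DAY / MM_PER_M


def stokes_velocity(params: StokesParams) -> float:
    """Stokes settling velocity ``2 g r^2 (rho' - rho) / (9 eta phi)`` in m s^-1.

    A negative value means the particle is positively buoyant (floats).
    Informational only — used as a prior for simulations, never in rate
    estimation, which is purely empirical.
    """
    p = params
    return 2.0 * p.g * p.r**2 * (p.rho_particle - p.rho_water) / (9.0 * p.eta * p.phi)
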