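"""Seeded synthetic plate-kinetics traces with the assay's assumed structure.

Each simulated well mixes one or two sinking subpopulations whose scaled
fluorescence decays by the inverse-square kernel, multiplies in an optional
transient NPQ-relaxation rise, adds a settled-cell baseline plateau and
Gaussian detector noise:

    rfu(t) = [baseline + f0 * sum_i w_i / (1 + s_i t)^2]
             * [1 - npq_amp * exp(-t / npq_tau)] + eps_t

with ``eps_t ~ Normal(0, noise_sd)`` drawn from a seeded generator. The
defaults emulate a two-phase well read 40 times over 200 minutes — a fast
minority population at 0.05 min^-1 over a slow majority at 0.005 min^-1 —
with detector noise at 1% of the initial amplitude.

What this emulates (and what it does not) is documented in
``docs/methods.md``: there is no radiative-transfer optics, no convection,
and the NPQ rise is a single exponential, so a pass here validates the
estimation machinery, not the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import PlateKinetics, WellCatalog, GROWTH_PHASES
from .model import DEFAULT_DEPTH_MM

__all__ = ["SyntheticSpec", "WellGroup", "simulate_trace", "simulate_plate"]


def _default_times() -> np.ndarray:
    return np.linspace(0.0, 200.0, 40)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one simulated sinking trace.

    ``weights`` are subpopulation fractions (one or two entries summing to
    1); ``s_values`` the matching scaled sinking rates in min^-1.
    ``npq_amp`` is the fractional initial fluorescence suppression that
    relaxes with time constant ``npq_tau`` (minutes). ``baseline`` is the
    additive settled-cell floor (cells on the well bottom still fluoresce,
    producing the terminal plateau).
    """

    times: np.ndarray = field(default_factory=_default_times)
    f0: float = 1000.0
    weights: tuple[float, ...] = (0.3, 0.7)
    s_values: tuple[float, ...] = (0.05, 0.005)
    npq_amp: float = 0.0
    npq_tau: float = 10.0
    baseline: float = 100.0
    noise_sd: float = 10.0
    seed: int | None = 0
    depth_mm: float = DEFAULT_DEPTH_MM

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.s_values):
            raise ValueError("weights and s_values must have equal length")
        if len(self.weights) not in (1, 2):
            raise ValueError("one or two subpopulations are supported")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("subpopulation weights must sum to 1")
        if any(s < 0 for s in self.s_values):
            raise ValueError("sinking rates must be nonnegative")
        if not 0.0 <= self.npq_amp < 1.0:
            raise ValueError("npq_amp must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_trace(spec: SyntheticSpec, rng: np.random.Generator | None = None):
    """Simulate one (times, rfu) trace; deterministic for a fixed seed."""
    t = np.asarray(spec.times, dtype=float)
    decay = sum(
        w / (1.0 + s * t) ** 2 for w, s in zip(spec.weights, spec.s_values)
    )
    clean = (spec.baseline + spec.f0 * decay) * (
        1.0 - spec.npq_amp * np.exp(-t / spec.npq_tau)
    )
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sd, size=t.size)
    return t, clean


@dataclass(frozen=True)
class WellGroup:
    """A replicate group on a simulated plate: wells sharing one SyntheticSpec."""

    name: str
    species: str
    growth_phase: str
    wells: tuple[str, ...]
    spec: SyntheticSpec
    strain: str = ""

    def __post_init__(self) -> None:
        if self.growth_phase not in GROWTH_PHASES:
            raise ValueError(
                f"growth_phase must be one of {sorted(GROWTH_PHASES)}"
            )


def simulate_plate(
    groups: Sequence[WellGroup],
    jitter: float = 0.0,
    seed: int | None = 0,
    plate_format: int = 96,
) -> tuple[PlateKinetics, WellCatalog]:
    """Simulate a plate: one trace per well plus the matching catalog.

    Within a group, each well's sinking rates are perturbed by a
    multiplicative factor ``1 + jitter * z`` (z standard normal, clipped at
    ±3 sd) to emulate biological replicate scatter; noise seeds are spawned
    per well from ``seed`` so replicates share expectation but not noise.

    Raises
    ------
    ValueError
        If a well is assigned to more than one group, or groups use
        different time vectors.
    """
    if not groups:
        raise ValueError("at least one well group is required")
    seen: dict[str, str] = {}
    for g in groups:
        for w in g.wells:
            if w in seen:
                raise ValueError(
                    f"well {w} assigned to both group {seen[w]!r} and {g.name!r}"
                )
            seen[w] = g.name
    times = np.asarray(groups[0].spec.times, dtype=float)
    for g in groups[1:]:
        if not np.array_equal(np.asarray(g.spec.times, dtype=float), times):
            raise ValueError("all groups on a plate must share one read schedule")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(sum(len(g.wells) for g in groups))
    traces: dict[str, np.ndarray] = {}
    rows = []
    k = 0
    for g in groups:
        for w in g.wells:
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            spec = g.spec
            if jitter > 0:
                factors = 1.0 + jitter * np.clip(
                    rng.standard_normal(len(spec.s_values)), -3.0, 3.0
                )
                spec = replace(
                    spec,
                    s_values=tuple(
                        max(s * f, 0.0) for s, f in zip(spec.s_values, factors)
                    ),
                )
            _, rfu = simulate_trace(spec, rng=rng)
            traces[w] = rfu
            rows.append(
                {
                    "well": w,
                    "species": g.species,
                    "strain": g.strain,
                    "growth_phase": g.growth_phase,
                    "replicate_group": g.name,
                    "plate_format": plate_format,
                    "depth_mm": g.spec.depth_mm,
                }
            )
    import pandas as pd

    kinetics = PlateKinetics.from_traces(
        times,
        traces,
        plate_format=plate_format,
        depth_mm=groups[0].spec.depth_mm,
    )
    catalog = WellCatalog(pd.DataFrame(rows))
    return kinetics, catalog
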