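"""Fiber recruitment: titration curves, diameter rescaling, threshold jitter.

A recruitment curve R*(I) is generated by titrating a population of fibers
of uniform reference diameter d0 (4 μm myelinated, 0.8 μm unmyelinated):
R*(I) is the fraction of per-fiber thresholds at or below the stimulus
current I. Because stimulus thresholds scale as 1/d, the same curve recast
as a function of diameter at fixed current is R(d) = R*(d · I / d0) — small
fibers see an effectively reduced current. A sharp recruitment cutoff in
diameter, d_cut = d0 · T / I, is what breaks the cancellation of smoothly
varying fiber populations and drives the large partial-recruitment
deflections in the compound signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RecruitmentCurve",
    "titration_curve",
    "rescale_to_diameter",
    "jitter_thresholds",
    "D0_MYELINATED",
    "D0_UNMYELINATED",
]

#: Reference titration diameter for myelinated fibers, m.
D0_MYELINATED = 4e-6
#: Reference titration diameter for unmyelinated fibers, m.
D0_UNMYELINATED = 0.8e-6

#: Number of current samples a stored recruitment curve keeps.
CURVE_SAMPLES = 256


@dataclass
class RecruitmentCurve:
    """Fraction recruited vs stimulus current at reference diameter d0."""

    current: np.ndarray  # A, increasing
    fraction: np.ndarray  # in [0, 1], non-decreasing
    d0: float  # m

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.current.shape != self.fraction.shape or self.current.ndim != 1:
            raise ValueError("current and fraction must be matching 1-D arrays")
        if np.any(np.diff(self.current) <= 0):
            raise ValueError("current grid must be strictly increasing")
        if np.any(np.diff(self.fraction) < -1e-12):
            raise ValueError("recruitment must be non-decreasing in current")
        if np.any(self.fraction < 0) or np.any(self.fraction > 1):
            raise ValueError("recruitment fraction must lie in [0, 1]")
        if self.d0 <= 0:
            raise ValueError("reference diameter must be positive")

    def at_current(self, current):
        """R*(I) by piecewise-linear interpolation (0 below, capped above)."""
        i = np.asarray(current, dtype=float)
        out = np.interp(i, self.current, self.fraction, left=0.0, right=self.fraction[-1])
        return float(out) if out.ndim == 0 else out

    def at_diameter(self, d, current):
        return rescale_to_diameter(self, d, current)


def titration_curve(thresholds, current_grid=None, d0: float = D0_MYELINATED) -> RecruitmentCurve:
    """Empirical recruitment curve from per-fiber titration thresholds.

    R*(I) is the fraction of thresholds <= I (the empirical CDF). With no
    grid supplied, the curve is tabulated at CURVE_SAMPLES currents from 0 to
    just past the largest threshold; a step is resolved by bracketing each
    threshold with the grid.
    """
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("at least one threshold is required")
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be positive")
    if current_grid is None:
        current_grid = np.linspace(0.0, 1.05 * thresholds[-1], CURVE_SAMPLES)
    current_grid = np.asarray(current_grid, dtype=float)
    frac = np.searchsorted(thresholds, current_grid, side="right") / thresholds.size
    return RecruitmentCurve(current_grid, frac, d0)


def rescale_to_diameter(curve: RecruitmentCurve, d, current):
    """Fraction of diameter-``d`` fibers recruited at stimulus ``current``.

    Thresholds scale as 1/d, so a fiber of diameter d behaves like a
    reference fiber driven with current d*I/d0: R(d) = R*(d * I / d0).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    return curve.at_current(d * current / curve.d0)


def jitter_thresholds(thresholds, sigma_jitter: float, seed, floor: float = 1e-12):
    """Add independent zero-mean Gaussian jitter to titration thresholds.

    Jitter smooths the recruitment curve (the empirical CDF is convolved
    with the Gaussian), which in turn smooths the compound signal. Results
    are clipped below at ``floor`` and reproducible under ``seed``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if sigma_jitter < 0:
        raise ValueError("jitter width must be non-negative")
    if sigma_jitter == 0.0:
        return thresholds.copy()
    rng = np.random.default_rng(seed)
    out = thresholds + rng.normal(0.0, sigma_jitter, size=thresholds.shape)
    return np.maximum(out, floor)
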