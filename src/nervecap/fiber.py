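"""Fiber-level electrophysiology: conduction laws, AP waveforms, thresholds.

All quantities are SI internally (meters, seconds, volts, amperes, S/m).
Micrometer/millisecond values are accepted only at I/O boundaries with
explicit conversion.

The default constants are fits to multicompartment fiber models:

* myelinated conduction: ``v = a * d`` with ``a = 4.3e6 1/s``
* unmyelinated conduction: ``v = b * sqrt(d)`` with ``b = 470 m^0.5/s``
* Gaussian AP width ``w_V``: 5e-5 s (myelinated), 2e-4 s (unmyelinated)
* stimulus threshold: ``T(d) = T0 * d0 / d`` (inverse-diameter law)

The axial conductivity ``sigma_tau`` is never printed by the fiber models we
emulate; it is a pure amplitude scale and defaults to 1 S/m. Absolute signal
amplitudes therefore carry an arbitrary overall scale; shapes and scalings
with diameter do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "FiberKind",
    "ConductionLaw",
    "APWaveform",
    "FiberElectrical",
    "ThresholdLaw",
    "MYELINATED_VELOCITY_COEFF",
    "UNMYELINATED_VELOCITY_COEFF",
    "MYELINATED_AP_WIDTH",
    "UNMYELINATED_AP_WIDTH",
    "DEFAULT_AP_PEAK",
    "DEFAULT_AXIAL_CONDUCTIVITY",
    "conduction_velocity",
    "axial_prefactor",
    "gaussian_ap",
    "second_time_derivative",
    "critical_diameter",
    "stimulus_threshold",
]

#: Proportionality constant of the myelinated linear conduction law, 1/s.
MYELINATED_VELOCITY_COEFF = 4.3e6
#: Proportionality constant of the unmyelinated square-root law, m^0.5/s.
UNMYELINATED_VELOCITY_COEFF = 470.0
#: Gaussian sigma of the myelinated AP waveform, s.
MYELINATED_AP_WIDTH = 5e-5
#: Gaussian sigma of the unmyelinated AP waveform, s.
UNMYELINATED_AP_WIDTH = 2e-4
#: Default AP peak excursion, V (typical transmembrane swing; amplitude
#: scale only — shape analyses use ratios).
DEFAULT_AP_PEAK = 0.1
#: Default intracellular axial conductivity, S/m (amplitude scale only).
DEFAULT_AXIAL_CONDUCTIVITY = 1.0


class FiberKind(str, Enum):
    MYELINATED = "myelinated"
    UNMYELINATED = "unmyelinated"


@dataclass(frozen=True)
class ConductionLaw:
    """Diameter-to-velocity law: ``a*d`` (myelinated) or ``b*sqrt(d)``.

    ``coefficient`` is ``a`` in 1/s for myelinated fibers and ``b`` in
    m^0.5/s for unmyelinated fibers; it must be positive so that velocity
    is strictly increasing with ``v(0) = 0``.
    """

    kind: FiberKind
    coefficient: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("conduction coefficient must be positive")

    @classmethod
    def myelinated(cls, coefficient: float = MYELINATED_VELOCITY_COEFF) -> "ConductionLaw":
        return cls(FiberKind.MYELINATED, coefficient)

    @classmethod
    def unmyelinated(cls, coefficient: float = UNMYELINATED_VELOCITY_COEFF) -> "ConductionLaw":
        return cls(FiberKind.UNMYELINATED, coefficient)

    def velocity(self, d):
        return conduction_velocity(self, d)


def conduction_velocity(law: ConductionLaw, d):
    """Conduction velocity in m/s for diameter ``d`` in meters.

    Accepts scalars or arrays; raises for negative diameters.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    if law.kind is FiberKind.MYELINATED:
        v = law.coefficient * d
    else:
        v = law.coefficient * np.sqrt(d)
    return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class FiberElectrical:
    """Electrical description of a single fiber: diameter and axial conductivity."""

    diameter: float  # m
    axial_conductivity: float = DEFAULT_AXIAL_CONDUCTIVITY  # S/m

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("diameter must be non-negative")
        if self.axial_conductivity <= 0:
            raise ValueError("axial conductivity must be positive")

    @property
    def eta(self) -> float:
        return axial_prefactor(self)


def axial_prefactor(elec: FiberElectrical | None = None, *, d=None, sigma=DEFAULT_AXIAL_CONDUCTIVITY):
    """Axial current prefactor ``eta = pi d^2 sigma / 4`` in S*m.

    Relates transmembrane current per unit length to the second spatial
    derivative of the membrane potential, ``i = eta * d2V/dl2``. Either a
    :class:`FiberElectrical` or keyword ``d`` (and optional ``sigma``) may
    be given; the keyword form is vectorized over ``d``.
    """
    if elec is not None:
        return math.pi * elec.diameter**2 * elec.axial_conductivity / 4.0
    d = np.asarray(d, dtype=float)
    eta = np.pi * d**2 * sigma / 4.0
    return float(eta) if eta.ndim == 0 else eta


@dataclass
class APWaveform:
    """Transmembrane AP profile V_t(t) on a uniform time grid, peak at t = 0.

    ``peak`` / ``width`` hold the parametric Gaussian description when the
    waveform was built with :func:`gaussian_ap`; they enable exact analytic
    differentiation in downstream convolutions.
    """

    time: np.ndarray  # s, uniform
    values: np.ndarray  # V
    peak: float | None = None  # V_p, if parametric Gaussian
    width: float | None = None  # w_V (Gaussian sigma), if parametric

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.size < 5:
            raise ValueError("time grid needs at least 5 samples")
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have matching shapes")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def is_gaussian(self) -> bool:
        return self.peak is not None and self.width is not None

    def recentered(self) -> "APWaveform":
        """Shift the grid so the waveform maximum sits at t = 0."""
        t_peak = self.time[int(np.argmax(self.values))]
        return APWaveform(self.time - t_peak, self.values.copy(), self.peak, self.width)


def gaussian_ap(
    peak: float = DEFAULT_AP_PEAK,
    width: float = MYELINATED_AP_WIDTH,
    time_grid: np.ndarray | None = None,
    *,
    n_sigma: float = 6.0,
    dt: float | None = None,
) -> APWaveform:
    """Parametric Gaussian AP ``V_t(t) = V_p exp(-t^2 / 2 w_V^2)``.

    If no grid is supplied, a symmetric grid spanning ``±n_sigma*width`` at
    step ``width/50`` is built. A supplied grid must span at least ±5 widths
    so that the pulse is contained.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if time_grid is None:
        step = dt if dt is not None else width / 50.0
        half = n_sigma * width
        n = int(round(half / step))
        time_grid = np.arange(-n, n + 1) * step
    else:
        time_grid = np.asarray(time_grid, dtype=float)
        if time_grid[0] > -5 * width or time_grid[-1] < 5 * width:
            raise ValueError("time grid must span at least ±5 widths of the pulse")
    values = peak * np.exp(-(time_grid**2) / (2.0 * width**2))
    return APWaveform(time_grid, values, peak=peak, width=width)


def second_time_derivative(ap: APWaveform) -> np.ndarray:
    """d²V_t/dt² on the waveform's grid, in V/s².

    Uses the exact closed form for parametric Gaussians and a central
    finite difference otherwise (one-sided at the two boundary samples,
    which sit at baseline for any admissible waveform).
    """
    if ap.is_gaussian:
        t, w = ap.time, ap.width
        return ap.peak / w**2 * (t**2 / w**2 - 1.0) * np.exp(-(t**2) / (2 * w**2))
    d2 = np.empty_like(ap.values)
    v, dt = ap.values, ap.dt
    d2[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2]) / dt**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def critical_diameter(law: ConductionLaw, w_phi: float, w_v: float) -> float:
    """Diameter d* at which the AP's spatial extent matches the electrode's.

    Solves ``v(d*) = w_phi / w_v``: fibers with ``d << d*`` are in the
    electrode-dominated regime, ``d >> d*`` in the AP-dominated regime.
    """
    if w_phi <= 0 or w_v <= 0:
        raise ValueError("widths must be positive")
    target = w_phi / w_v
    if law.kind is FiberKind.MYELINATED:
        return target / law.coefficient
    return (target / law.coefficient) ** 2


@dataclass(frozen=True)
class ThresholdLaw:
    """Inverse-diameter stimulus threshold law ``T(d) = T0 * d0 / d``."""

    d0: float  # reference diameter, m
    t0: float  # threshold at d0, A

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.t0 <= 0:
            raise ValueError("reference diameter and threshold must be positive")

    def threshold(self, d):
        return stimulus_threshold(self, d)


def stimulus_threshold(thr: ThresholdLaw, d):
    """Stimulus threshold current (A) at diameter ``d`` (m); d must be > 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    t = thr.t0 * thr.d0 / d
    return float(t) if t.ndim == 0 else t
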