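"""Sensitivity functions (lead fields) along a fiber path.

The sensitivity function Φ(l) is the potential, per unit applied current,
generated along the fiber path when a virtual current is driven through the
recording terminals. By reciprocity it weights the fiber's membrane currents
in the recorded signal. This module builds Φ for Gaussian surrogate contacts
and for point electrodes in a homogeneous medium, post-processes profiles so
they vanish at the ends (making the recorded signal gauge-unambiguous on a
finite window), and reparameterizes Φ(l) into the time domain Φ(l_init + v·t)
for a propagating AP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SensitivityProfile",
    "GaussianContact",
    "PointElectrodeConfig",
    "gaussian_profile",
    "point_electrode_profile",
    "taper_ends",
    "time_reparameterize",
    "DEFAULT_RECORDING_OFFSET",
]

log = logging.getLogger(__name__)

#: Default arclength of the recording site relative to the AP initiation
#: plane (l = 0): 6 cm, the stimulus-to-cuff distance of the emulated setup.
DEFAULT_RECORDING_OFFSET = 0.06


@dataclass
class SensitivityProfile:
    """Lead field Φ(l) per unit current on a uniform arclength grid."""

    arclength: np.ndarray  # m, uniform
    values: np.ndarray  # V/A
    label: str = ""
    tapered: bool = False

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.arclength.ndim != 1 or self.arclength.size < 3:
            raise ValueError("arclength grid needs at least 3 samples")
        if self.arclength.shape != self.values.shape:
            raise ValueError("arclength and values must have matching shapes")
        steps = np.diff(self.arclength)
        if np.any(steps <= 0):
            raise ValueError("arclength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            raise ValueError("arclength grid must be uniform")
        if self.tapered and (self.values[0] != 0.0 or self.values[-1] != 0.0):
            raise ValueError("tapered profile must vanish at both ends")

    @property
    def dl(self) -> float:
        return float(self.arclength[1] - self.arclength[0])

    def with_offset(self, phi0: float) -> "SensitivityProfile":
        return SensitivityProfile(self.arclength, self.values + phi0, self.label, tapered=False)


@dataclass(frozen=True)
class GaussianContact:
    """Gaussian surrogate of a monopolar contact's lead field along the fiber.

    ``Φ(x) = polarity * peak * exp(-(x - center)^2 / (2 width^2))``
    """

    peak: float  # Φ_p, V/A
    width: float  # w_φ, m
    center: float  # x_c, m
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("contact width must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be ±1")


@dataclass(frozen=True)
class PointElectrodeConfig:
    """One or two point recording terminals in an infinite homogeneous medium.

    ``terminals`` are 3-D positions (m); ``polarities`` default to (+1,) for a
    monopolar terminal or (+1, -1) for a differential pair. ``sigma`` is the
    medium conductivity (S/m).
    """

    terminals: tuple  # of 3-vectors
    sigma: float = 1.0
    polarities: tuple | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("medium conductivity must be positive")
        terms = tuple(np.asarray(t, dtype=float) for t in self.terminals)
        object.__setattr__(self, "terminals", terms)
        if self.polarities is None:
            pol = (1,) if len(terms) == 1 else (1, -1)
            object.__setattr__(self, "polarities", pol)
        if len(self.polarities) != len(self.terminals):
            raise ValueError("one polarity per terminal required")


def gaussian_profile(contacts, grid) -> SensitivityProfile:
    """Sum of signed Gaussian contact profiles evaluated on ``grid``."""
    contacts = list(contacts)
    if not contacts:
        raise ValueError("at least one contact required")
    grid = np.asarray(grid, dtype=float)
    phi = np.zeros_like(grid)
    for c in contacts:
        phi += c.polarity * c.peak * np.exp(-((grid - c.center) ** 2) / (2 * c.width**2))
    return SensitivityProfile(grid, phi, label=f"gaussian:{len(contacts)}")


def point_source_potential(cfg: PointElectrodeConfig, points) -> np.ndarray:
    """Potential of unit current through the terminals at 3-D ``points``.

    The kernel is ``sum_e polarity_e / (4 pi sigma |r - r_e|)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    phi = np.zeros(points.shape[0])
    for pol, r_e in zip(cfg.polarities, cfg.terminals):
        dist = np.linalg.norm(points - r_e[None, :], axis=1)
        if np.any(dist == 0.0):
            raise ValueError("evaluation point coincides with an electrode")
        phi += pol / (4.0 * np.pi * cfg.sigma * dist)
    return phi


def fiber_path_points(start, direction, arclength) -> np.ndarray:
    """3-D points of a straight fiber path sampled at ``arclength`` values."""
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return start[None, :] + np.asarray(arclength, dtype=float)[:, None] * direction[None, :]


def point_electrode_profile(cfg: PointElectrodeConfig, fiber_path, grid) -> SensitivityProfile:
    """Lead field of point electrodes along a fiber path.

    ``fiber_path`` maps arclength values to 3-D points; a tuple
    ``(start, direction)`` describes a straight path. ``grid`` is the uniform
    arclength grid (m).
    """
    grid = np.asarray(grid, dtype=float)
    if callable(fiber_path):
        pts = np.asarray(fiber_path(grid), dtype=float)
    else:
        start, direction = fiber_path
        pts = fiber_path_points(start, direction, grid)
    phi = point_source_potential(cfg, pts)
    return SensitivityProfile(grid, phi, label="point-electrode")


def _taper_one_end(l, phi, min_slope, from_left: bool, margin_frac: float):
    """Linearize one end of the profile down to zero; returns modified values."""
    n = phi.size
    # pivot search confined to this end's half of the profile
    idx = range(1, n // 2) if from_left else range(n - 2, n // 2, -1)
    dl = l[1] - l[0]
    pivot = None
    for i in idx:
        slope = (phi[i + 1] - phi[i - 1]) / (2 * dl)
        if abs(slope) >= min_slope:
            pivot, s = i, slope
            break
    out = phi.copy()
    if pivot is None:
        # degenerate flat profile: linear ramp from the end value to zero
        m = max(2, int(margin_frac * n))
        log.warning("taper_ends: no point reaches min_slope; ramping over %d samples", m)
        if from_left:
            out[:m] = phi[m - 1] * np.arange(m) / (m - 1)
        else:
            out[-m:] = phi[-m] * np.arange(m - 1, -1, -1) / (m - 1)
        return out
    # tangent from the pivot outward until it crosses zero, zero beyond
    if from_left:
        seg = np.arange(0, pivot)
        line = phi[pivot] + s * (l[seg] - l[pivot])
    else:
        seg = np.arange(pivot + 1, n)
        line = phi[pivot] + s * (l[seg] - l[pivot])
    same_sign = line * np.sign(phi[pivot] if phi[pivot] != 0 else 1.0) > 0
    line = np.where(same_sign, line, 0.0)
    out[seg] = line
    # guarantee the invariant even when the tangent never crosses zero
    out[0 if from_left else -1] = 0.0
    return out


def taper_ends(profile: SensitivityProfile, min_slope: float | None = None, *, margin_frac: float = 0.05) -> SensitivityProfile:
    """Post-process Φ so it reaches exactly zero at both grid ends.

    From each end inward, the first point whose local slope magnitude reaches
    ``min_slope`` is found; the curve outward of it is replaced by the tangent
    line until the zero crossing, and set to zero beyond. The default
    ``min_slope`` is 1% of max|Φ| divided by the profile half-length. If no
    point reaches the slope, the end is linearly ramped to zero over a margin
    (logged).
    """
    l, phi = profile.arclength, profile.values
    if min_slope is None:
        half_len = (l[-1] - l[0]) / 2.0
        min_slope = 0.01 * np.max(np.abs(phi)) / half_len if np.max(np.abs(phi)) > 0 else 0.0
    if np.max(np.abs(phi)) == 0.0 or (phi[0] == 0.0 and phi[-1] == 0.0):
        out = phi.copy()
        out[0] = out[-1] = 0.0
        return SensitivityProfile(l, out, profile.label, tapered=True)
    out = _taper_one_end(l, phi, min_slope, True, margin_frac)
    out = _taper_one_end(l, out, min_slope, False, margin_frac)
    return SensitivityProfile(l, out, profile.label, tapered=True)


def time_reparameterize(profile: SensitivityProfile, v: float, l_init: float = 0.0, time_grid=None) -> tuple:
    """Evaluate Φ at ``l = l_init + v t``: the lead field seen by an AP front.

    Returns ``(time_grid, values)``. Interpolation is cubic inside the
    tabulated support and exactly zero outside. If no ``time_grid`` is given,
    the natural grid ``(l - l_init)/v`` of the profile samples is used.
    """
    if v <= 0:
        raise ValueError("velocity must be positive")
    l, phi = profile.arclength, profile.values
    if time_grid is None:
        time_grid = (l - l_init) / v
        return time_grid, phi.copy()
    time_grid = np.asarray(time_grid, dtype=float)
    pos = l_init + v * time_grid
    spline = CubicSpline(l, phi, extrapolate=False)
    vals = spline(pos)
    vals = np.where(np.isnan(vals), 0.0, vals)
    return time_grid, vals
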