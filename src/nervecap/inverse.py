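"""Inverse recovery of fiber-diameter-distribution parameters from an eCAP.

A reference compound signal constrains the gamma diameter distribution
(shape k, scale θ) of one fiber subpopulation — here the myelinated
afferents, with all other populations held fixed. The misfit is the L1 norm
Σ_i |V_i − V̂_i| over time samples, minimized by a derivative-free,
bound-constrained pattern search with mesh halving (deterministic), with a
Nelder–Mead simplex fallback.

Because only the diameter density p(d) depends on the fitted parameters,
the forward model precomputes everything else once — per-fascicle lead-field
matrices Φ_i(d, t), recruitment/amplitude weights, and the contributions of
the fixed populations — so each forward evaluation is a weighted matrix
product plus one convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .ecap import (
    DiameterGrid,
    FiberType,
    _second_derivative_on,
    compute_ecap,
    CONDUCTION_LAWS,
    scaling_function,
)
from .fiber import axial_prefactor, conduction_velocity
from .recruitment import rescale_to_diameter
from .sfap import Signal

__all__ = ["ECAPForwardModel", "FitProblem", "FitResult", "l1_objective", "fit_diameter_distribution"]


def l1_objective(sim: Signal, ref: Signal) -> float:
    """L1 mismatch Σ_i |V_i − V̂_i| between two signals on a shared grid."""
    if sim.time.shape != ref.time.shape or not np.allclose(sim.time, ref.time):
        raise ValueError("signals must share one time grid")
    return float(np.abs(sim.values - ref.values).sum())


class ECAPForwardModel:
    """eCAP as a function of one population's gamma (shape, scale).

    All nerve parameters except the target population's diameter density are
    frozen at construction; :meth:`simulate` then costs one matrix product
    and one convolution.
    """

    def __init__(
        self,
        fascicles,
        ap_waveforms: dict,
        current: float,
        target_type: FiberType = FiberType.MYELINATED_AFFERENT,
        *,
        dt: float = 1e-5,
        t_max: float = 25e-3,
        grid: DiameterGrid | None = None,
        l_init: float = 0.0,
    ) -> None:
        from scipy.interpolate import CubicSpline

        self.grid = grid or DiameterGrid()
        self.target_type = target_type
        self.current = current
        self._t_x = dt * np.arange(int(np.ceil(t_max / dt)) + 1)
        ap = ap_waveforms.get(target_type, ap_waveforms.get(target_type.kind))
        self._t_ap, self._d2v = _second_derivative_on(ap, dt)
        self._dt = dt

        d = self.grid.diameters
        law = CONDUCTION_LAWS[target_type.kind]
        v = conduction_velocity(law, d)

        # fixed contributions: every other (fascicle, type) pair
        fixed_nerve = []
        for fasc in fascicles:
            others = {ft: p for ft, p in fasc.populations.items() if ft is not target_type}
            if others:
                fixed_nerve.append(
                    type(fasc)(fasc.id, fasc.centroid, fasc.area, others, fasc.sensitivity, fasc.recruitment)
                )
        if fixed_nerve:
            res = compute_ecap(fixed_nerve, ap_waveforms, current, dt=dt, t_max=t_max, grid=self.grid, l_init=l_init)
            self._fixed_time = res.time
            self._fixed_total = res.total
        else:
            self._fixed_time = None
            self._fixed_total = 0.0

        # per-fascicle lead-field matrices restricted to recruited diameters
        self._blocks = []  # (base_weights_without_p, row_idx, phi_matrix)
        for fasc in fascicles:
            pop = fasc.populations.get(target_type)
            if pop is None:
                continue
            curve = fasc.recruitment[target_type]
            r = rescale_to_diameter(curve, d, current) if current > 0 else np.zeros_like(d)
            eta = axial_prefactor(d=d, sigma=pop.axial_conductivity)
            base = r * pop.count * self.grid.delta * eta / v
            rows = np.nonzero(base > 0)[0]
            if rows.size == 0:
                continue
            spline = CubicSpline(fasc.sensitivity.arclength, fasc.sensitivity.values, extrapolate=False)
            pos = l_init + v[rows, None] * self._t_x[None, :]
            phi = spline(pos)
            phi = np.where(np.isnan(phi), 0.0, phi)
            self._blocks.append((base[rows], rows, phi))

        self.n_evaluations = 0

    def _density(self, shape: float, scale: float) -> np.ndarray:
        pdf = gamma_dist.pdf(self.grid.diameters, a=shape, scale=scale)
        norm = pdf.sum() * self.grid.delta
        if norm <= 0:
            raise ValueError("gamma density has no mass on the diameter grid")
        return pdf / norm

    def simulate(self, shape: float, scale: float) -> Signal:
        """eCAP with the target population's gamma parameters set to (shape, scale)."""
        p = self._density(shape, scale)
        x = np.zeros_like(self._t_x)
        for base, rows, phi in self._blocks:
            x += (base * p[rows]) @ phi
        conv = np.convolve(self._d2v, x) * self._dt
        t0 = self._t_ap[0] + self._t_x[0]
        if self._fixed_time is None:
            self.n_evaluations += 1
            return Signal(t0 + self._dt * np.arange(conv.size), conv)
        # embed both parts on the union grid (grid offsets are multiples of dt)
        t_start = min(t0, self._fixed_time[0])
        t_end = max(t0 + self._dt * (conv.size - 1), self._fixed_time[-1])
        n = int(round((t_end - t_start) / self._dt)) + 1
        vals = np.zeros(n)
        off = int(round((t0 - t_start) / self._dt))
        vals[off : off + conv.size] += conv
        off_f = int(round((self._fixed_time[0] - t_start) / self._dt))
        vals[off_f : off_f + self._fixed_total.size] += self._fixed_total
        self.n_evaluations += 1
        return Signal(t_start + self._dt * np.arange(n), vals)


@dataclass
class FitProblem:
    """Bound-constrained 2-parameter fit of a diameter distribution."""

    forward: ECAPForwardModel
    reference: Signal
    x0: tuple  # initial (shape, scale)
    bounds: tuple  # ((k_lo, k_hi), (theta_lo, theta_hi))
    max_evals: int = 500
    mesh_tol: float = 1e-6  # stop when the normalized mesh is this small
    seed: int = 0

    def __post_init__(self) -> None:
        (klo, khi), (tlo, thi) = self.bounds
        k0, t0 = self.x0
        if not (klo <= k0 <= khi and tlo <= t0 <= thi):
            raise ValueError("initial point must lie inside the bounds")

    def objective(self, x) -> float:
        sim = self.forward.simulate(float(x[0]), float(x[1]))
        return l1_objective(sim, self.reference)


@dataclass
class FitResult:
    shape: float
    scale: float
    objective: float
    history: np.ndarray  # best-so-far objective after each evaluation
    n_evals: int
    converged: bool


# poll directions in the normalized unit box: axes plus diagonals
_DIRECTIONS = np.array(
    [[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float
)
_DIRECTIONS[4:] /= np.sqrt(2.0)


def fit_diameter_distribution(problem: FitProblem, method: str = "pattern") -> FitResult:
    """Minimize the L1 eCAP mismatch over (shape, scale).

    ``method="pattern"`` (default) runs a coordinate-plus-diagonal pattern
    search with mesh halving on the normalized parameter box: poll the eight
    directions at the current mesh size, move to the best improving point
    (doubling the mesh, capped), otherwise halve the mesh; stop when the
    mesh falls below ``mesh_tol`` or the evaluation budget is exhausted.
    The best-so-far history is monotone non-increasing by construction.

    ``method="nelder-mead"`` is a simplex fallback (evaluations clipped to
    the bounds).
    """
    lb = np.array([problem.bounds[0][0], problem.bounds[1][0]], dtype=float)
    ub = np.array([problem.bounds[0][1], problem.bounds[1][1]], dtype=float)
    span = ub - lb
    history: list = []

    def f_of(xn) -> float:
        x = lb + np.clip(xn, 0.0, 1.0) * span
        val = problem.objective(x)
        best = min(val, history[-1]) if history else val
        history.append(best)
        return val

    u = (np.asarray(problem.x0, dtype=float) - lb) / span

    if method == "nelder-mead":
        res = minimize(
            f_of,
            u,
            method="Nelder-Mead",
            options={"maxfev": problem.max_evals, "xatol": problem.mesh_tol, "fatol": 0.0},
        )
        xb = lb + np.clip(res.x, 0.0, 1.0) * span
        return FitResult(float(xb[0]), float(xb[1]), float(res.fun), np.asarray(history), len(history), bool(res.success))
    if method != "pattern":
        raise ValueError(f"unknown method {method!r}")

    f_best = f_of(u)
    mesh = 0.25
    converged = False
    while len(history) < problem.max_evals:
        if mesh < problem.mesh_tol:
            converged = True
            break
        improved = False
        best_cand, best_val = None, f_best
        for dvec in _DIRECTIONS:
            if len(history) >= problem.max_evals:
                break
            cand = np.clip(u + mesh * dvec, 0.0, 1.0)
            if np.allclose(cand, u):
                continue
            val = f_of(cand)
            if val < best_val:
                best_cand, best_val = cand, val
                improved = True
        if improved:
            u, f_best = best_cand, best_val
            mesh = min(mesh * 2.0, 0.25)
        else:
            mesh *= 0.5
    x = lb + u * span
    return FitResult(float(x[0]), float(x[1]), float(f_best), np.asarray(history), len(history), converged)
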