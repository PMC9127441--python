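"""Deterministic diffusion engine: backward Kolmogorov solver.

For the reduced (reference-size) Wright-Fisher diffusion with effective
selection ``g = gamma*kappa``,

    du/dt = g*y*(1-y)*du/dy + (1/2)*y*(1-y)*d2u/dy2,   u(y, 0) = f(y),

with absorbing (Dirichlet) boundaries ``u(0,t) = f(0)``, ``u(1,t) = f(1)``,
the solution is ``u(y, t) = E_y[f(xi_t)]`` including the absorbed mass.  With
``f`` the fixation indicator this yields the fixation-time distribution
``P_y(tau_1 <= t)``.

A regime with size ratio kappa is handled by the exact reduction
``E_y^{gamma,kappa}[f(xi_t)] = E_y^{gamma*kappa,1}[f(xi_{t/kappa})]``.

Numerics: Crank-Nicolson on a uniform frequency grid with a geometrically
growing time step, Rannacher (implicit Euler) startup to damp oscillations
from discontinuous initial data, and first-order upwinding of the convection
term when the cell Peclet number ``|g|*dy`` exceeds 1 (very strong selection,
where the solution is vanishingly small anyway).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .core import SelectionRegime

__all__ = ["PDEEngine", "EngineTable", "pde_oracle"]


@dataclasses.dataclass(frozen=True)
class EngineTable:
    """Conditional expectations on a (time, frequency) grid.

    values[i, j] approximates ``E_{y_j}[f(xi_{tau_i})]`` for the reduced
    (kappa = 1) dynamics at effective selection ``gamma_eff``; ``se`` is the
    per-entry Monte-Carlo standard error (None for deterministic engines).
    """

    y: np.ndarray
    taus: np.ndarray
    values: np.ndarray
    gamma_eff: float
    f_at_0: float
    f_at_1: float
    se: np.ndarray | None = None


class PDEEngine:
    """Crank-Nicolson engine producing :class:`EngineTable` objects.

    Parameters
    ----------
    ny
        Number of frequency grid points including the boundaries.
    dt_init, dt_max, growth
        Time-step ramp: the step starts at ``dt_init`` and grows
        geometrically by ``growth`` per step up to ``dt_max`` (reduced time
        units), trading accuracy early (where transients are fast) for speed
        late.
    rannacher_steps
        Number of initial implicit-Euler half-steps.
    """

    name = "pde"
    is_stochastic = False

    def __init__(
        self,
        ny: int = 2001,
        dt_init: float = 1e-4,
        dt_max: float = 0.02,
        growth: float = 1.05,
        rannacher_steps: int = 4,
    ) -> None:
        if ny < 11:
            raise ValueError("ny too small for a meaningful solve")
        self.ny = ny
        self.dt_init = dt_init
        self.dt_max = dt_max
        self.growth = growth
        self.rannacher_steps = rannacher_steps
        self._memo: dict = {}

    # -- low-level march ---------------------------------------------------
    def _coefficients(self, gamma_eff: float):
        y = np.linspace(0.0, 1.0, self.ny)
        dy = y[1] - y[0]
        yi = y[1:-1]
        adv = gamma_eff * yi * (1.0 - yi)
        dif = 0.5 * yi * (1.0 - yi)
        if abs(gamma_eff) * dy <= 1.0:
            # central differencing of the convection term
            lower = dif / dy**2 - adv / (2.0 * dy)
            diag = -2.0 * dif / dy**2
            upper = dif / dy**2 + adv / (2.0 * dy)
        else:
            # upwind: deleterious selection advects mass toward y = 0
            a_minus = np.minimum(adv, 0.0)
            a_plus = np.maximum(adv, 0.0)
            lower = dif / dy**2 - a_minus / dy
            diag = -2.0 * dif / dy**2 - (a_plus - a_minus) / dy
            upper = dif / dy**2 + a_plus / dy
        return y, lower, diag, upper

    def evolve(
        self,
        u0: np.ndarray | Callable[[np.ndarray], np.ndarray],
        gamma_eff: float,
        taus: Sequence[float],
        fresh_start: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """March ``u0`` forward and record snapshots at each requested
        reduced time (sorted unique, must be >= 0).  Returns ``(y, values)``
        with ``values`` of shape ``(len(taus), ny)``."""
        y, lower, diag, upper = self._coefficients(gamma_eff)
        u = np.asarray(u0(y) if callable(u0) else u0, dtype=float).copy()
        if u.shape != y.shape:
            raise ValueError("u0 has wrong shape for this grid")
        taus = np.asarray(taus, dtype=float)
        if np.any(taus < 0.0):
            raise ValueError("reduced times must be nonnegative")
        order = np.argsort(taus, kind="stable")
        out = np.empty((len(taus), self.ny))
        t_now = 0.0
        dt = self.dt_init
        steps_done = 0
        k = 0
        while k < len(order) and taus[order[k]] <= t_now:
            out[order[k]] = u
            k += 1
        while k < len(order):
            target = taus[order[k]]
            step = min(dt, target - t_now)
            theta = 1.0 if (fresh_start and steps_done < self.rannacher_steps) else 0.5
            u = self._step(u, step, theta, lower, diag, upper)
            t_now += step
            steps_done += 1
            dt = min(dt * self.growth, self.dt_max)
            while k < len(order) and taus[order[k]] <= t_now + 1e-15:
                out[order[k]] = u
                k += 1
        return y, out

    def _step(self, u, dt, theta, lower, diag, upper):
        n = self.ny
        rhs = u.copy()
        if theta < 1.0:
            w = (1.0 - theta) * dt
            rhs[1:-1] += w * (lower * u[:-2] + diag * u[1:-1] + upper * u[2:])
        ab = np.zeros((3, n))
        ab[1, :] = 1.0
        w = theta * dt
        ab[0, 2:] = -w * upper
        ab[1, 1:-1] = 1.0 - w * diag
        ab[2, :-2] = -w * lower
        return solve_banded((1, 1), ab, rhs, overwrite_ab=True, overwrite_b=True)

    # -- engine interface --------------------------------------------------
    def moment_table(
        self,
        f: Callable[[np.ndarray], np.ndarray],
        gamma_eff: float,
        taus: Sequence[float],
    ) -> EngineTable:
        """Table of ``E_y[f(xi_tau)]`` for the reduced dynamics."""
        key = ("moment", getattr(f, "__name__", repr(f)), round(gamma_eff, 12),
               tuple(np.round(np.asarray(taus, dtype=float), 12)))
        if key in self._memo:
            return self._memo[key]
        y, vals = self.evolve(f, gamma_eff, taus)
        table = EngineTable(
            y=y, taus=np.asarray(taus, dtype=float), values=vals,
            gamma_eff=gamma_eff, f_at_0=float(f(0.0)), f_at_1=float(f(1.0)),
        )
        self._memo[key] = table
        return table

    def fixation_cdf_table(self, gamma_eff: float, taus: Sequence[float]) -> EngineTable:
        """Table of the fixation-time distribution ``P_y(tau_1 <= tau)``."""
        key = ("cdf", round(gamma_eff, 12),
               tuple(np.round(np.asarray(taus, dtype=float), 12)))
        if key in self._memo:
            return self._memo[key]
        y0 = np.zeros(self.ny)
        y0[-1] = 1.0  # already fixed
        y, vals = self.evolve(y0, gamma_eff, taus)
        vals = np.clip(vals, 0.0, 1.0)
        table = EngineTable(
            y=y, taus=np.asarray(taus, dtype=float), values=vals,
            gamma_eff=gamma_eff, f_at_0=0.0, f_at_1=1.0,
        )
        self._memo[key] = table
        return table


def pde_oracle(
    f: Callable[[np.ndarray], np.ndarray],
    y0: float,
    regime: SelectionRegime,
    t: float,
    engine: PDEEngine | None = None,
) -> float:
    """Deterministic value of ``E_{y0}^{gamma,kappa}[f(xi_t)]``.

    Solves the backward Kolmogorov equation for the reduced dynamics at
    ``gamma*kappa`` up to reduced time ``t/kappa`` and interpolates at
    ``y0``.  Serves as the independent oracle for the Wright-Fisher
    Monte-Carlo engine.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    engine = engine or PDEEngine()
    table = engine.moment_table(f, regime.gamma_eff, [t / regime.kappa])
    return float(np.interp(y0, table.y, table.values[0]))


def fixation_cdf_oracle(
    y0: float,
    regime: SelectionRegime,
    t: float,
    engine: PDEEngine | None = None,
) -> float:
    """Deterministic ``P_{y0}^{gamma,kappa}(tau_1 <= t)`` from the PDE."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    engine = engine or PDEEngine()
    table = engine.fixation_cdf_table(regime.gamma_eff, [t / regime.kappa])
    return float(np.interp(y0, table.y, table.values[0]))
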