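"""Nonstationary allele frequency spectrum after step size changes, and the
time-dependent measures of selection built on it.

After a single change from size N to kappa*N at time ``tstar``, the expected
AFS functional for a mutation class with scaled selection ``gamma`` is, for
``t > tstar``,

    E<X_t, f> = theta*f(1)*[omega_1*tstar + omega_k*(t - tstar)]
              + theta * int f(y) omega_k psi_k(y) dy
              + theta * int E_y^{gamma,kappa}[f(xi_{t-tstar})]
                        * [omega_1 psi_1(y) - omega_k psi_k(y)] dy,

while for ``t <= tstar`` the ancestral equilibrium functional applies.  The
third (transient) term tracks standing variation whose weights were set by
the ancestral spectrum but whose subsequent fate is governed by the new
size.  The conditional expectations E_y[f] and the fixation-time CDF
P_y(tau_1 <= u) are consumed through an engine interface, so the
deterministic PDE solver and the Wright-Fisher Monte-Carlo tables are
interchangeable.

Measures derived here: nucleotide diversities piS(t) (closed form) and
piN(t) (Gamma-DFE average), their ratio, cumulative fixation counts Z(t),
the fixation ratio omega_bar(t) = E[Z_V(t)]/Z_0(t), and the classical
weighted ratio omega_w(t) for comparison.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    SelectionRegime,
    SpectrumFunctional,
    equilibrium_functional,
    f_pw,
    fixation_prob,
    fixation_rate,
    omega_weighted,
    pi_equilibrium,
)
from .dfe import GammaDFE
from .history import SizeHistory
from .pde import EngineTable, PDEEngine

__all__ = [
    "afs_functional",
    "afs_functional_multi",
    "pi_s_t",
    "pi_n_t",
    "pi_n_gamma_t",
    "pin_pis_ratio",
    "fixations_t",
    "omega_bar",
    "compute_measure_series",
    "default_engine",
]

_DEFAULT_ENGINE: PDEEngine | None = None


def default_engine() -> PDEEngine:
    """Module-level deterministic engine (memoizes its tables)."""
    global _DEFAULT_ENGINE
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = PDEEngine()
    return _DEFAULT_ENGINE


# ----------------------------------------------------------------------
# the transient y-integral
# ----------------------------------------------------------------------

def _bracket(y: np.ndarray, gamma: float, kappa_old: float, kappa_new: float) -> np.ndarray:
    """Spectrum-intensity difference
    ``omega_{gamma,k_old} psi_{gamma,k_old}(y) - omega_{gamma,k_new} psi_{gamma,k_new}(y)``
    evaluated through the overflow-free identity
    ``omega*psi = 2*kappa*q(1-y)/(y*(1-y))``."""
    q_old = np.asarray(fixation_prob(1.0 - y, SelectionRegime(gamma, kappa_old)))
    q_new = np.asarray(fixation_prob(1.0 - y, SelectionRegime(gamma, kappa_new)))
    return (2.0 * kappa_old * q_old - 2.0 * kappa_new * q_new) / (y * (1.0 - y))


def _transient_rows(
    table: EngineTable, gamma: float, kappa_old: float, kappa_new: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate each time-row of an engine table against the intensity
    bracket, returning (integrals, standard errors).

    The integrand ``E_y[f] * bracket(y)`` is continuous on [0, 1]: near
    ``y=0`` the 1/y singularity of the bracket cancels against the O(y)
    decay of the expectation, with limit ``slope0 * 2*(kappa_old -
    kappa_new)`` where slope0 is the small-y slope of E_y[f]; near ``y=1``
    the bracket tends to ``2*(kappa_old*omega_old - kappa_new*omega_new)``.
    The slope is fitted through the origin from the three smallest grid
    frequencies, and the trapezoid rule is applied on the closed grid.
    """
    y = table.y
    interior = (y > 0.0) & (y < 1.0)
    yi = y[interior]
    br = _bracket(yi, gamma, kappa_old, kappa_new)
    vals = table.values[:, interior]
    rows = vals * br[None, :]

    # endpoint closures
    k_small = min(3, yi.size)
    ys = yi[:k_small]
    vs = vals[:, :k_small]
    slope0 = (vs * ys[None, :]).sum(axis=1) / (ys**2).sum()
    lim0 = 2.0 * (kappa_old - kappa_new)
    h0 = slope0 * lim0
    om_old = fixation_rate(SelectionRegime(gamma, kappa_old))
    om_new = fixation_rate(SelectionRegime(gamma, kappa_new))
    lim1 = 2.0 * (kappa_old * om_old - kappa_new * om_new)
    h1 = np.full(rows.shape[0], table.f_at_1 * lim1)

    grid = np.concatenate(([0.0], yi, [1.0]))
    full = np.concatenate((h0[:, None], rows, h1[:, None]), axis=1)
    integrals = np.trapezoid(full, grid, axis=1)

    if table.se is not None:
        se_rows = table.se[:, interior] * br[None, :]
        # trapezoid weights for the interior points
        w = np.empty_like(grid)
        w[0] = (grid[1] - grid[0]) / 2
        w[-1] = (grid[-1] - grid[-2]) / 2
        w[1:-1] = (grid[2:] - grid[:-2]) / 2
        ses = np.sqrt(((se_rows * w[None, 1:-1]) ** 2).sum(axis=1))
    else:
        ses = np.zeros(rows.shape[0])
    return integrals, ses


def _single_change(history: SizeHistory) -> tuple[float, float]:
    if not history.is_single:
        raise ValueError("this operation requires a single-change history")
    return history.epochs[0]


# ----------------------------------------------------------------------
# AFS functionals
# ----------------------------------------------------------------------

def afs_functional(
    f: Callable[[np.ndarray], np.ndarray],
    gamma: float,
    history: SizeHistory,
    theta: float,
    t: float,
    engine=None,
) -> SpectrumFunctional:
    """Expected AFS functional ``E<X_t, f>`` after a single size change.

    For ``t <= tstar`` this is the ancestral equilibrium functional; for
    ``t > tstar`` the three-term nonequilibrium expression.  The engine
    (default: deterministic PDE) supplies ``E_y[f]`` at effective selection
    ``gamma*kappa`` and reduced elapsed time ``(t - tstar)/kappa``.
    """
    tstar, kappa = _single_change(history)
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t <= tstar:
        return equilibrium_functional(f, SelectionRegime(gamma, 1.0), theta, t)
    engine = engine or default_engine()
    new = SelectionRegime(gamma, kappa)
    eq_new = equilibrium_functional(f, new, theta, 0.0)
    om1 = fixation_rate(SelectionRegime(gamma, 1.0))
    omk = fixation_rate(new)
    fixation_mass = theta * float(f(1.0)) * (om1 * tstar + omk * (t - tstar))
    table = engine.moment_table(f, new.gamma_eff, [(t - tstar) / kappa])
    integrals, ses = _transient_rows(table, gamma, 1.0, kappa)
    return SpectrumFunctional(
        fixation_mass=fixation_mass,
        polymorphic_mass=eq_new.polymorphic_mass,
        transient_mass=theta * float(integrals[0]),
        se=theta * float(ses[0]),
        quad_error=eq_new.quad_error,
    )


def afs_functional_multi(
    f: Callable[[np.ndarray], np.ndarray],
    gamma: float,
    history: SizeHistory,
    theta: float,
    t: float,
    engine: PDEEngine | None = None,
) -> SpectrumFunctional:
    """Expected AFS functional for an arbitrary multi-epoch step history.

    The polymorphic spectrum is decomposed into the current epoch's
    equilibrium plus the propagated deviations created at each past size
    change: the jump at change ``k`` (intensity difference between the
    outgoing and incoming equilibria) evolves to time ``t`` under the full
    multi-epoch expectation ``S_k f``, computed by marching the backward
    equation through every intervening epoch.  With a single change this
    reduces exactly to :func:`afs_functional`.  Requires the deterministic
    PDE engine (composed multi-epoch semigroups are not available from the
    Monte-Carlo tables).
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    engine = engine or default_engine()
    if not isinstance(engine, PDEEngine):
        raise TypeError("afs_functional_multi requires the PDE engine")
    changes = [(tk, kap) for tk, kap in history.epochs if tk < t]
    kappas = [1.0] + [kap for _, kap in changes]
    kappa_cur = kappas[-1]

    # fixation term: theta * f(1) * integral of omega over [0, t]
    om_integral = 0.0
    prev_t, prev_k = 0.0, 1.0
    for tk, kap in changes:
        om_integral += fixation_rate(SelectionRegime(gamma, prev_k)) * (tk - prev_t)
        prev_t, prev_k = tk, kap
    om_integral += fixation_rate(SelectionRegime(gamma, prev_k)) * (t - prev_t)
    fixation_mass = theta * float(f(1.0)) * om_integral

    eq_cur = equilibrium_functional(f, SelectionRegime(gamma, kappa_cur), theta, 0.0)

    # transient terms: march f backward through the epochs, most recent first
    transient = 0.0
    if changes:
        y = np.linspace(0.0, 1.0, engine.ny)
        u = np.asarray(f(y), dtype=float)
        t_upper = t
        fresh = True
        for idx in range(len(changes) - 1, -1, -1):
            tk, kap = changes[idx]
            tau = (t_upper - tk) / kap
            _, vals = engine.evolve(u, gamma * kap, [tau], fresh_start=fresh)
            u = vals[0]
            fresh = False
            table = EngineTable(
                y=y, taus=np.asarray([tau]), values=u[None, :],
                gamma_eff=gamma * kap, f_at_0=float(f(0.0)), f_at_1=float(f(1.0)),
            )
            kap_before = kappas[idx]
            integrals, _ = _transient_rows(table, gamma, kap_before, kap)
            transient += theta * float(integrals[0])
            t_upper = tk

    return SpectrumFunctional(
        fixation_mass=fixation_mass,
        polymorphic_mass=eq_cur.polymorphic_mass,
        transient_mass=transient,
        quad_error=eq_cur.quad_error,
    )


# ----------------------------------------------------------------------
# diversity measures
# ----------------------------------------------------------------------

def pi_s_t(history: SizeHistory, theta: float, t):
    """Synonymous (neutral) diversity after a single change, closed form:
    ``2*theta`` for ``t <= tstar`` and
    ``2*theta*kappa + 2*theta*(1-kappa)*exp(-(t-tstar)/kappa)`` after."""
    tstar, kappa = _single_change(history)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = np.where(
        t_arr <= tstar,
        2.0 * theta,
        2.0 * theta * kappa
        + 2.0 * theta * (1.0 - kappa) * np.exp(-np.maximum(t_arr - tstar, 0.0) / kappa),
    )
    return out if np.asarray(t).ndim else float(out)


def pi_n_gamma_t(
    gamma: float,
    history: SizeHistory,
    theta: float,
    t,
    engine=None,
) -> np.ndarray:
    """Nonsynonymous diversity of a single selection class over a time grid."""
    tstar, kappa = _single_change(history)
    engine = engine or default_engine()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    before = t_arr <= tstar
    out[before] = pi_equilibrium(SelectionRegime(gamma, 1.0), theta)
    after = ~before
    if after.any():
        eq_new = pi_equilibrium(SelectionRegime(gamma, kappa), theta)
        taus = (t_arr[after] - tstar) / kappa
        table = engine.moment_table(f_pw, gamma * kappa, taus)
        integrals, _ = _transient_rows(table, gamma, 1.0, kappa)
        out[after] = eq_new + theta * integrals
    return out if np.asarray(t).ndim else float(out[0])


def pi_n_t(
    dfe: GammaDFE,
    history: SizeHistory,
    theta: float,
    t,
    engine=None,
    n_nodes: int = 24,
    truncated: bool = True,
):
    """DFE-averaged nonsynonymous diversity ``piN(t)``.

    Equals ``E[piN^{V,1}]`` for ``t <= tstar`` and approaches the new
    equilibrium ``E[piN^{V,kappa}]`` as ``t`` grows.  The DFE integral is
    the outer loop so that one engine table per gamma-node serves the whole
    time grid.
    """
    engine = engine or default_engine()
    gammas, weights = dfe.nodes(n_nodes, truncated=truncated)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    acc = np.zeros_like(t_arr)
    for g_node, w in zip(gammas, weights):
        acc += w * pi_n_gamma_t(g_node, history, theta, t_arr, engine)
    return acc if np.asarray(t).ndim else float(acc[0])


def pin_pis_ratio(pi_n, pi_s):
    """Pointwise ratio piN/piS; requires piS > 0."""
    pi_s_arr = np.asarray(pi_s, dtype=float)
    if np.any(pi_s_arr <= 0):
        raise ValueError("piS must be positive")
    return np.asarray(pi_n, dtype=float) / pi_s_arr


# ----------------------------------------------------------------------
# fixations
# ----------------------------------------------------------------------

def fixations_t(
    gamma: float,
    history: SizeHistory,
    theta: float,
    t,
    engine=None,
):
    """Expected cumulative fixation count ``Z(t)`` of one mutation class.

    Linear ``theta*omega_1*t`` before the change; afterwards the two
    equilibrium-rate terms plus the transient integral of the fixation-time
    CDF of the standing variation.
    """
    tstar, kappa = _single_change(history)
    engine = engine or default_engine()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    om1 = fixation_rate(SelectionRegime(gamma, 1.0))
    omk = fixation_rate(SelectionRegime(gamma, kappa))
    out = np.where(
        t_arr <= tstar,
        theta * om1 * t_arr,
        theta * (om1 * tstar + omk * np.maximum(t_arr - tstar, 0.0)),
    )
    after = t_arr > tstar
    if after.any():
        taus = (t_arr[after] - tstar) / kappa
        table = engine.fixation_cdf_table(gamma * kappa, taus)
        integrals, _ = _transient_rows(table, gamma, 1.0, kappa)
        out = out.astype(float)
        out[after] += theta * integrals
    return out if np.asarray(t).ndim else float(out[0])


def omega_bar(
    dfe: GammaDFE,
    history: SizeHistory,
    theta: float,
    t,
    engine=None,
    n_nodes: int = 24,
    truncated: bool = True,
):
    """Cumulative fixation-rate ratio ``omega_bar(t) = E[Z_V(t)] / Z_0(t)``.

    Equals ``E[omega_{V,1}]`` for ``t <= tstar`` and approaches
    ``E[omega_{V,kappa}]`` as ``t -> infinity``.  Undefined at ``t = 0``
    (no synonymous fixations yet); the value reported there is the
    ``t -> 0+`` limit ``E[omega_{V,1}]``.
    """
    engine = engine or default_engine()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    gammas, weights = dfe.nodes(n_nodes, truncated=truncated)
    z_n = np.zeros_like(t_arr)
    for g_node, w in zip(gammas, weights):
        z_n += w * np.atleast_1d(fixations_t(g_node, history, theta, t_arr, engine))
    z_s = np.atleast_1d(fixations_t(0.0, history, theta, t_arr, engine))
    out = np.empty_like(t_arr)
    pos = t_arr > 0
    out[pos] = z_n[pos] / z_s[pos]
    if np.any(~pos):
        out[~pos] = dfe.expectation(
            lambda v: fixation_rate(SelectionRegime(float(v), 1.0)),
            n_nodes=n_nodes, truncated=truncated,
        )
    return out if np.asarray(t).ndim else float(out[0])


# ----------------------------------------------------------------------
# measure series
# ----------------------------------------------------------------------

def compute_measure_series(
    dfe: GammaDFE,
    history: SizeHistory,
    theta: float,
    t_grid: Sequence[float],
    engine=None,
    n_nodes: int = 24,
    truncated: bool = True,
) -> pd.DataFrame:
    """Time series of all selection measures after a single size change.

    Returns a DataFrame with columns ``time, pi_n, pi_s, pin_pis, z_n, z_s,
    omega_bar, omega_w`` plus provenance attributes (engine name, node
    count).  ``omega_w`` is the classical weighted-equilibrium comparison
    ratio.
    """
    tstar, kappa = _single_change(history)
    engine = engine or default_engine()
    t_arr = np.asarray(t_grid, dtype=float)
    gammas, weights = dfe.nodes(n_nodes, truncated=truncated)

    pi_s = np.atleast_1d(pi_s_t(history, theta, t_arr))
    pi_n = np.zeros_like(t_arr)
    z_n = np.zeros_like(t_arr)
    for g_node, w in zip(gammas, weights):
        pi_n += w * np.atleast_1d(pi_n_gamma_t(g_node, history, theta, t_arr, engine))
        z_n += w * np.atleast_1d(fixations_t(g_node, history, theta, t_arr, engine))
    z_s = np.atleast_1d(fixations_t(0.0, history, theta, t_arr, engine))

    om1 = float(np.dot(weights, [fixation_rate(SelectionRegime(g, 1.0)) for g in gammas]))
    omk = float(np.dot(weights, [fixation_rate(SelectionRegime(g, kappa)) for g in gammas]))
    om_w = np.where(
        t_arr <= tstar, om1,
        omega_weighted(np.maximum(t_arr, tstar), tstar, om1, omk),
    )

    with np.errstate(invalid="ignore", divide="ignore"):
        om_bar = np.where(t_arr > 0, z_n / np.where(z_s > 0, z_s, np.nan), om1)

    df = pd.DataFrame(
        {
            "time": t_arr,
            "pi_n": pi_n,
            "pi_s": pi_s,
            "pin_pis": pi_n / pi_s,
            "z_n": z_n,
            "z_s": z_s,
            "omega_bar": om_bar,
            "omega_w": om_w,
        }
    )
    df.attrs["engine"] = getattr(engine, "name", "unknown")
    df.attrs["n_nodes"] = n_nodes
    df.attrs["kappa"] = kappa
    df.attrs["tstar"] = tstar
    df.attrs["theta"] = theta
    return df
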