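"""Finite-(N, L) Poisson random field simulator.

Pathwise construction of the allele-frequency field: new mutations enter as
a Poisson stream (``theta * kappa(t)`` per generation, each at one copy),
each segregating site evolves independently by binomial Wright-Fisher
sampling with selection, and the standing variation at time 0 is drawn from
the ancestral equilibrium Poisson measure with intensity
``theta * omega_{gamma,1} * psi_{gamma,1}(y) dy``.

The simulator records the polymorphic functional ``<X_t, f> = sum_i f(y_i)``
over segregating sites and the cumulative count of fixations, and serves as
an independent oracle for the analytic nonequilibrium AFS.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .core import ModelParams, SelectionRegime, f_pw, sfs_intensity
from .dfe import GammaDFE
from .history import SizeHistory

__all__ = ["FieldResult", "simulate_poisson_field"]


@dataclasses.dataclass(frozen=True)
class FieldResult:
    """Time series from one realization of the mutation-drift field."""

    times: np.ndarray          # evolutionary time (units of N generations)
    functional: np.ndarray     # <X_t, f> over segregating sites
    n_segregating: np.ndarray
    fixations: np.ndarray      # cumulative fixation count over (0, t]
    seed: int


def _equilibrium_site_sample(
    theta: float, N: int, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw standing-variation counts from the discretized equilibrium
    intensity ``theta * omega * psi(j/N) / N`` for j = 1..N-1."""
    j = np.arange(1, N)
    lam = theta * sfs_intensity(j / N, SelectionRegime(gamma, 1.0)) / N
    counts = rng.poisson(lam)
    return np.repeat(j, counts)


def simulate_poisson_field(
    params: ModelParams,
    history: SizeHistory,
    regime_or_dfe: SelectionRegime | GammaDFE,
    t_end: float,
    seed: int = 0,
    f: Callable[[np.ndarray], np.ndarray] = f_pw,
    record_every: int = 1,
    ancestral_init: bool = True,
) -> FieldResult:
    """Simulate the allele-frequency field over ``[0, t_end]``.

    Parameters
    ----------
    params
        Supplies ``theta`` and the reference size ``N`` (the simulated,
        finite size; the analytic theory is its ``N -> infinity`` limit).
    history
        Step-function size history; ``kappa = 1`` before the first change.
    regime_or_dfe
        Either a single :class:`SelectionRegime` (its ``kappa`` is ignored;
        the history controls population size) or a :class:`GammaDFE` from
        which each mutation draws its own gamma.
    t_end
        End time in units of N generations.
    ancestral_init
        Start from the ancestral equilibrium Poisson measure (otherwise
        from an empty, fully monomorphic field).
    """
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    N = int(round(params.N))
    theta = params.theta
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x0F1E1D]))
    use_dfe = isinstance(regime_or_dfe, GammaDFE)

    if use_dfe:
        dfe = regime_or_dfe
        init_nodes, init_weights = dfe.nodes(48, truncated=True)
    else:
        gamma0 = regime_or_dfe.gamma

    counts: np.ndarray
    gammas: np.ndarray
    if ancestral_init:
        if use_dfe:
            parts, gparts = [], []
            for g_node, w in zip(init_nodes, init_weights):
                c = _equilibrium_site_sample(theta * w, N, g_node, rng)
                parts.append(c)
                gparts.append(np.full(c.size, g_node))
            counts = np.concatenate(parts) if parts else np.empty(0, np.int64)
            gammas = np.concatenate(gparts) if gparts else np.empty(0)
        else:
            counts = _equilibrium_site_sample(theta, N, gamma0, rng)
            gammas = np.full(counts.size, gamma0)
    else:
        counts = np.empty(0, dtype=np.int64)
        gammas = np.empty(0)

    n_gen = int(round(t_end * N))
    rec_gens = np.arange(0, n_gen + 1, record_every)
    times = rec_gens / N
    functional = np.empty(len(rec_gens))
    n_seg = np.empty(len(rec_gens), dtype=np.int64)
    fixations = np.empty(len(rec_gens), dtype=np.int64)

    n_cur = N
    fixed_total = 0
    rec_i = 0

    def record(g: int) -> None:
        nonlocal rec_i
        functional[rec_i] = float(np.sum(f(counts / n_cur))) if counts.size else 0.0
        n_seg[rec_i] = counts.size
        fixations[rec_i] = fixed_total
        rec_i += 1

    record(0)
    for g in range(1, n_gen + 1):
        t = g / N
        n_new = int(round(history.kappa_at(t) * N))
        if n_new != n_cur:
            # instantaneous size change: resample counts at the new size
            if counts.size:
                counts = rng.binomial(n_new, counts / n_cur)
                fixed_now = counts == n_new
                fixed_total += int(fixed_now.sum())
                keep = (counts > 0) & ~fixed_now
                counts, gammas = counts[keep], gammas[keep]
            n_cur = n_new
        # mutation inflow: theta * kappa per generation, one copy each
        m = rng.poisson(theta * n_cur / N)
        if m:
            counts = np.append(counts, np.ones(m, dtype=np.int64))
            if use_dfe:
                gammas = np.append(gammas, dfe.sample(m, rng))
            else:
                gammas = np.append(gammas, np.full(m, gamma0))
        if counts.size:
            # per-generation selection with reference scaling; the discrete
            # model caps lethality at s = -1
            s = np.maximum(gammas, -float(N)) / N
            p = counts * (1.0 + s) / (n_cur + s * counts)
            counts = rng.binomial(n_cur, p)
            fixed_now = counts == n_cur
            fixed_total += int(fixed_now.sum())
            keep = (counts > 0) & ~fixed_now
            counts, gammas = counts[keep], gammas[keep]
        if g % record_every == 0:
            record(g)

    return FieldResult(
        times=times, functional=functional, n_segregating=n_seg,
        fixations=fixations, seed=seed,
    )
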