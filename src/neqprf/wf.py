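"""Discrete Wright-Fisher simulation engine with selection.

Forward-in-time binomial resampling of a biallelic site in a haploid
population of size ``N``: given frequency ``y`` and per-generation selection
coefficient ``s`` (fitness 1+s for the derived allele), the next generation's
derived-allele count is Binomial(N, p*) with

    p* = y * (1 + s) / (1 + s * y),

whose expected change matches the diffusion drift ``gamma*y*(1-y)`` with
``gamma = N*s`` up to O(s^2).  A population of size ``kappa*N`` with scaled
selection ``gamma`` is simulated as the reference population with effective
selection ``gamma*kappa``; generation ``g`` then maps to evolutionary time
``t = kappa * g / N``.

The engine produces Monte-Carlo tables of the fixation-time distribution
``P_y(tau_1 <= t)`` and of conditional moments ``E_y[f(xi_t)]`` on (y, t)
grids, with reproducible per-(y, gamma) RNG streams derived from a master
seed so that tables do not depend on evaluation order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Callable, Sequence

import numpy as np

from .core import SelectionRegime, fixation_prob
from .pde import EngineTable

__all__ = [
    "WFConfig",
    "AbsorptionRecord",
    "FixationTimeCDF",
    "MomentTable",
    "simulate_wf_path",
    "estimate_fixation_cdf",
    "estimate_moment",
    "WFEngine",
    "default_y_grid",
]


@dataclasses.dataclass(frozen=True)
class WFConfig:
    """Simulation controls.

    N
        Simulated haploid size.
    n_gen
        Generation horizon; paths not absorbed by then are censored
        ("never fix").
    reps_fix
        Replicates per initial frequency for fixation-time CDFs; when None,
        100000 replicates are used for neutral classes and 10000 for
        selected ones.
    reps_moment
        Replicates per initial frequency for moment estimates.
    seed
        Master RNG seed; all streams derive from it deterministically.
    """

    N: int = 1000
    n_gen: int = 20_000
    reps_fix: int | None = None
    reps_moment: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2 or self.n_gen < 1 or self.reps_moment < 1:
            raise ValueError("population size, horizon and replicate counts must be positive")
        if self.reps_fix is not None and self.reps_fix < 1:
            raise ValueError("reps_fix must be positive")

    def reps_fix_for(self, gamma: float) -> int:
        if self.reps_fix is not None:
            return self.reps_fix
        return 100_000 if gamma == 0.0 else 10_000


@dataclasses.dataclass(frozen=True)
class AbsorptionRecord:
    outcome: str  # "lost" | "fixed" | "censored"
    generation: int


@dataclasses.dataclass(frozen=True)
class FixationTimeCDF:
    """Monte-Carlo estimate of ``P_{y0}(tau_1 <= t)`` on a time grid."""

    y0: float
    gamma_eff: float
    time_grid: np.ndarray  # evolutionary time under the (gamma, kappa) regime
    cdf: np.ndarray
    se: np.ndarray
    reps: int
    seed: int


@dataclasses.dataclass(frozen=True)
class MomentTable:
    """Monte-Carlo estimate of ``E_y[f(xi_t)]`` on a (y, t) grid."""

    y_grid: np.ndarray
    time_grid: np.ndarray
    values: np.ndarray  # shape (len(time_grid), len(y_grid))
    se: np.ndarray
    gamma_eff: float
    reps: int
    seed: int
    name: str = "f"


def default_y_grid(N: int) -> np.ndarray:
    """1/N plus 40 log-spaced initial frequencies up to 1 - 1/N."""
    return np.geomspace(1.0 / N, 1.0 - 1.0 / N, 41)


def _stream(seed: int, *key) -> np.random.Generator:
    """Reproducible child generator for a (purpose, gamma, y, ...) key."""
    digest = hashlib.blake2b(repr(key).encode(), digest_size=4).digest()
    child = int.from_bytes(digest, "big") & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, child]))


def _p_star(counts: np.ndarray, N: int, s: float) -> np.ndarray:
    return counts * (1.0 + s) / (N + s * counts)


def simulate_wf_path(
    y0: float,
    s: float,
    cfg: WFConfig,
    rng: np.random.Generator | None = None,
) -> AbsorptionRecord:
    """Simulate one path from frequency ``y0`` until absorption or censoring."""
    if s < -1.0:
        raise ValueError("per-generation selection must satisfy s >= -1")
    if rng is None:
        rng = _stream(cfg.seed, "path", s, y0)
    count = int(round(y0 * cfg.N))
    if count <= 0:
        return AbsorptionRecord("lost", 0)
    if count >= cfg.N:
        return AbsorptionRecord("fixed", 0)
    for gen in range(1, cfg.n_gen + 1):
        count = rng.binomial(cfg.N, _p_star(np.asarray(count, float), cfg.N, s))
        if count == 0:
            return AbsorptionRecord("lost", gen)
        if count == cfg.N:
            return AbsorptionRecord("fixed", gen)
    return AbsorptionRecord("censored", cfg.n_gen)


def _fixation_generations(
    count0: int, N: int, s: float, n_gen: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Generation of fixation per replicate; +inf if lost or censored."""
    active = np.full(reps, count0, dtype=np.int64)
    fix_gen = np.full(reps, np.inf)
    idx = np.arange(reps)
    gen = 0
    while active.size and gen < n_gen:
        gen += 1
        active = rng.binomial(N, _p_star(active.astype(float), N, s))
        fixed = active == N
        if fixed.any():
            fix_gen[idx[fixed]] = gen
        keep = (active > 0) & ~fixed
        active = active[keep]
        idx = idx[keep]
    return fix_gen


def estimate_fixation_cdf(
    y0: float,
    regime: SelectionRegime,
    time_grid: Sequence[float],
    cfg: WFConfig,
) -> FixationTimeCDF:
    """Monte-Carlo fixation-time distribution for the (gamma, kappa) regime.

    Simulates the reference-size population at effective selection
    ``gamma*kappa`` and maps generation ``g`` to evolutionary time
    ``kappa*g/N``.  Censored paths never fix; a warning is issued when the
    implied censoring bias among eventually-fixing paths exceeds 1% of the
    diffusion fixation probability.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(time_grid < 0.0):
        raise ValueError("time grid must be nonnegative")
    gamma_eff = regime.gamma_eff
    s = gamma_eff / cfg.N
    if s < -1.0:
        raise ValueError("gamma*kappa/N must be >= -1 for the discrete model")
    reps = cfg.reps_fix_for(regime.gamma)
    count0 = int(round(y0 * cfg.N))
    rng = _stream(cfg.seed, "cdf", round(gamma_eff, 12), count0)
    fix_gen = _fixation_generations(count0, cfg.N, s, cfg.n_gen, reps, rng)
    gens = time_grid * cfg.N / regime.kappa
    cdf = (fix_gen[None, :] <= gens[:, None]).mean(axis=1)
    se = np.sqrt(np.maximum(cdf * (1.0 - cdf), 0.0) / reps)
    q = fixation_prob(y0, regime)
    p_fixed = float(np.isfinite(fix_gen).mean())
    if q > 0 and (q - p_fixed) > 0.01 * q + 3.0 * np.sqrt(q * (1 - q) / reps):
        warnings.warn(
            f"censoring bias: observed fixation fraction {p_fixed:.4g} vs "
            f"diffusion q={q:.4g} at horizon {cfg.n_gen} generations",
            stacklevel=2,
        )
    return FixationTimeCDF(
        y0=y0, gamma_eff=gamma_eff, time_grid=time_grid,
        cdf=cdf, se=se, reps=reps, seed=cfg.seed,
    )


def estimate_moment(
    f: Callable[[np.ndarray], np.ndarray],
    y0: float | Sequence[float],
    regime: SelectionRegime,
    time_grid: Sequence[float],
    cfg: WFConfig,
) -> MomentTable:
    """Monte-Carlo ``E_y[f(xi_t)]`` averaged over ``cfg.reps_moment`` paths.

    Times are evolutionary units under the (gamma, kappa) regime; absorbed
    paths keep contributing ``f(0)`` or ``f(1)``.  At ``t = 0`` the estimate
    equals ``f(round(y0*N)/N)`` exactly.
    """
    y_grid = np.atleast_1d(np.asarray(y0, dtype=float))
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(time_grid < 0.0):
        raise ValueError("time grid must be nonnegative")
    gamma_eff = regime.gamma_eff
    s = gamma_eff / cfg.N
    if s < -1.0:
        raise ValueError("gamma*kappa/N must be >= -1 for the discrete model")
    reps = cfg.reps_moment
    gens = np.rint(time_grid * cfg.N / regime.kappa).astype(np.int64)
    max_gen = int(gens.max()) if gens.size else 0
    values = np.empty((len(time_grid), len(y_grid)))
    ses = np.empty_like(values)
    for j, y in enumerate(y_grid):
        count0 = int(round(y * cfg.N))
        rng = _stream(cfg.seed, "moment", round(gamma_eff, 12), count0)
        counts = np.full(reps, count0, dtype=np.int64)
        snapshots: dict[int, tuple[float, float]] = {}
        for g in range(0, max_gen + 1):
            if g > 0:
                counts = rng.binomial(cfg.N, _p_star(counts.astype(float), cfg.N, s))
            if g in gens:
                fv = np.asarray(f(counts / cfg.N), dtype=float)
                snapshots[g] = (float(fv.mean()), float(fv.std(ddof=1) / np.sqrt(reps)))
        for i, g in enumerate(gens):
            values[i, j], ses[i, j] = snapshots[int(g)]
    return MomentTable(
        y_grid=y_grid, time_grid=time_grid, values=values, se=ses,
        gamma_eff=gamma_eff, reps=reps, seed=cfg.seed,
        name=getattr(f, "__name__", "f"),
    )


class WFEngine:
    """Monte-Carlo engine exposing the same table interface as the PDE
    engine, for use by the nonequilibrium AFS functionals.

    Tables are computed on a fixed initial-frequency grid (default: 1/N plus
    40 log-spaced points up to 1-1/N) in reduced time units (kappa = 1 at
    effective selection gamma*kappa), exactly like the deterministic engine.
    """

    name = "wf"
    is_stochastic = True

    def __init__(
        self,
        cfg: WFConfig | None = None,
        y_grid: np.ndarray | None = None,
        reps_moment: int | None = None,
        reps_fix: int | None = None,
        cache=None,
    ) -> None:
        self.cfg = cfg or WFConfig()
        if reps_moment is not None or reps_fix is not None:
            self.cfg = dataclasses.replace(
                self.cfg,
                reps_moment=reps_moment or self.cfg.reps_moment,
                reps_fix=reps_fix if reps_fix is not None else self.cfg.reps_fix,
            )
        self.y_grid = default_y_grid(self.cfg.N) if y_grid is None else np.asarray(y_grid, float)
        self.cache = cache
        self._memo: dict = {}

    def _key(self, kind: str, fname: str, gamma_eff: float, taus) -> tuple:
        return (kind, fname, round(gamma_eff, 12),
                tuple(np.round(np.asarray(taus, dtype=float), 12)))

    def moment_table(self, f, gamma_eff: float, taus: Sequence[float]) -> EngineTable:
        key = self._key("moment", getattr(f, "__name__", "f"), gamma_eff, taus)
        if key in self._memo:
            return self._memo[key]
        table = self._load(key)
        if table is None:
            regime = SelectionRegime(gamma_eff, 1.0)
            mt = estimate_moment(f, self.y_grid, regime, taus, self.cfg)
            table = EngineTable(
                y=self.y_grid, taus=np.asarray(taus, float), values=mt.values,
                gamma_eff=gamma_eff, f_at_0=float(f(0.0)), f_at_1=float(f(1.0)),
                se=mt.se,
            )
            self._store(key, table)
        self._memo[key] = table
        return table

    def fixation_cdf_table(self, gamma_eff: float, taus: Sequence[float]) -> EngineTable:
        key = self._key("cdf", "f_fix", gamma_eff, taus)
        if key in self._memo:
            return self._memo[key]
        table = self._load(key)
        if table is None:
            regime = SelectionRegime(gamma_eff, 1.0)
            vals = np.empty((len(taus), len(self.y_grid)))
            ses = np.empty_like(vals)
            for j, y in enumerate(self.y_grid):
                c = estimate_fixation_cdf(y, regime, taus, self.cfg)
                vals[:, j] = c.cdf
                ses[:, j] = c.se
            table = EngineTable(
                y=self.y_grid, taus=np.asarray(taus, float), values=vals,
                gamma_eff=gamma_eff, f_at_0=0.0, f_at_1=1.0, se=ses,
            )
            self._store(key, table)
        self._memo[key] = table
        return table

    def _load(self, key):
        if self.cache is None:
            return None
        return self.cache.load(key, self.cfg)

    def _store(self, key, table) -> None:
        if self.cache is not None:
            self.cache.store(key, self.cfg, table)
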