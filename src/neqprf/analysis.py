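"""Orchestration: kappa sweeps, selection-drift tables and log-log slopes.

The central empirical object is the selection-drift relationship: at
equilibrium, for a Gamma DFE with shape ``a``,

    log(piN/piS) ~ -a * log(Neff) + C1,
    log(omega_bar) ~ -a * log(Neff) + C2,

so a sweep over size ratios kappa traces an approximately straight line of
slope ``-a`` in log-log space.  After a size change the measures react on
different timescales and the fitted slope departs from ``-a`` in a
direction that depends on which measure of selection is paired with which
measure of Neff.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("neqprf.analysis")

from .core import SelectionRegime, fixation_rate, pi_equilibrium
from .dfe import GammaDFE
from .history import SizeHistory
from .core import ModelParams
from .neff import neff_pi
from .nonequilibrium import (
    compute_measure_series,
    default_engine,
    pi_s_t,
)
from .pde import PDEEngine
from .wf import WFConfig, WFEngine

__all__ = [
    "RunConfig",
    "fit_loglog_slope",
    "equilibrium_table",
    "drift_selection_table",
    "measures_sweep",
    "write_tsv",
]


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full analysis run (flat, YAML-serializable)."""

    theta: float = 1.0
    N: float = 1000.0
    tstar: float = 1.0
    t_eval: tuple[float, ...] = (2.0, 10.0, 20.0)
    kappas: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0)
    dfe_shape: float = 0.15
    dfe_mean: float = 2500.0  # mean selection strength a*b
    gamma_min: float = -1000.0
    n_nodes: int = 24
    engine: str = "pde"
    pde_ny: int = 2001
    wf_N: int = 1000
    wf_n_gen: int = 20_000
    wf_reps_moment: int = 1000
    wf_reps_fix: int | None = None
    seed: int = 0
    t_grid_step: float = 0.1
    t_max: float = 20.0

    def __post_init__(self) -> None:
        if not self.kappas:
            raise ValueError("kappa list must be nonempty")
        if any(k <= 0 for k in self.kappas):
            raise ValueError("all kappa values must be positive")
        if any(t > self.t_max for t in self.t_eval):
            raise ValueError("evaluation times must not exceed t_max")

    @property
    def dfe(self) -> GammaDFE:
        return GammaDFE.from_mean(self.dfe_shape, self.dfe_mean, self.gamma_min)

    def params(self) -> ModelParams:
        return ModelParams(theta=self.theta, N=self.N, tstar=self.tstar, t_present=self.t_max)

    def make_engine(self):
        if self.engine == "pde":
            return PDEEngine(ny=self.pde_ny)
        if self.engine == "wf":
            cfg = WFConfig(
                N=self.wf_N, n_gen=self.wf_n_gen,
                reps_fix=self.wf_reps_fix, reps_moment=self.wf_reps_moment,
                seed=self.seed,
            )
            return WFEngine(cfg)
        raise ValueError(f"unknown engine {self.engine!r}")

    def t_grid(self) -> np.ndarray:
        n = int(round(self.t_max / self.t_grid_step))
        return np.linspace(0.0, self.t_max, n + 1)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("t_eval", "kappas"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["t_eval"] = list(self.t_eval)
        out["kappas"] = list(self.kappas)
        return out


def fit_loglog_slope(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares of log(y) on log(x); returns (slope, intercept)."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size < 2:
        raise ValueError("need at least two points")
    if np.any(x_arr <= 0) or np.any(y_arr <= 0):
        raise ValueError("all values must be positive for a log-log fit")
    lx = np.log(x_arr)
    if np.ptp(lx) < 1e-12:
        raise ValueError("degenerate x-spread")
    slope, intercept = np.polyfit(lx, np.log(y_arr), 1)
    return float(slope), float(intercept)


def equilibrium_table(
    dfe: GammaDFE,
    kappas: Sequence[float],
    theta: float = 1.0,
    N: float = 1000.0,
    n_nodes: int = 200,
    truncated: bool = True,
) -> pd.DataFrame:
    """Equilibrium kappa sweep: piN/piS, omega and Neff = kappa*N per kappa.

    Pure quadrature (no engine); the log-log relationship of these columns
    against Neff is the equilibrium selection-drift line of slope ``-a``.
    """
    gammas, weights = dfe.nodes(n_nodes, truncated=truncated)
    rows = []
    for kappa in kappas:
        pin = float(np.dot(weights, [pi_equilibrium(SelectionRegime(g, kappa), theta) for g in gammas]))
        om = float(np.dot(weights, [fixation_rate(SelectionRegime(g, kappa)) for g in gammas]))
        pis = 2.0 * theta * kappa
        rows.append(
            {
                "kappa": kappa,
                "neff": kappa * N,
                "pin_pis": pin / pis,
                "omega": om,
            }
        )
    df = pd.DataFrame(rows)
    df["log_neff"] = np.log(df["neff"])
    df["log_pin_pis"] = np.log(df["pin_pis"])
    df["log_omega"] = np.log(df["omega"])
    return df


def drift_selection_table(cfg: RunConfig, engine=None) -> pd.DataFrame:
    """One row per (kappa, eval time): measures of selection and Neff.

    Engine tables are shared across kappa through the gamma*kappa
    reparameterization and the engine's internal memoization.
    """
    engine = engine or cfg.make_engine()
    dfe = cfg.dfe
    params = cfg.params()
    rows = []
    for kappa in cfg.kappas:
        history = SizeHistory.single_change(cfg.N, cfg.tstar, kappa)
        try:
            series = compute_measure_series(
                dfe, history, cfg.theta, np.asarray(cfg.t_eval), engine, n_nodes=cfg.n_nodes
            )
        except Exception:  # engine failure: skip the row block, keep the sweep
            logger.exception("measure series failed for kappa=%g", kappa)
            continue
        pis = np.atleast_1d(pi_s_t(history, cfg.theta, np.asarray(cfg.t_eval)))
        for i, t in enumerate(cfg.t_eval):
            npi = float(neff_pi(pis[i], params))
            nh = history.harmonic_mean_size(t) if t > 0 else cfg.N
            rows.append(
                {
                    "kappa": kappa,
                    "eval_time": t,
                    "neff_pi": npi,
                    "neff_h": nh,
                    "pin_pis": float(series["pin_pis"].iloc[i]),
                    "omega_bar": float(series["omega_bar"].iloc[i]),
                }
            )
    df = pd.DataFrame(rows)
    for col in ("neff_pi", "neff_h", "pin_pis", "omega_bar"):
        df[f"log_{col}"] = np.log(df[col])
    return df


def measures_sweep(cfg: RunConfig, engine=None) -> dict[float, pd.DataFrame]:
    """Full measure time series for each kappa (the figure-style sweep)."""
    engine = engine or cfg.make_engine()
    out = {}
    for kappa in cfg.kappas:
        history = SizeHistory.single_change(cfg.N, cfg.tstar, kappa)
        out[kappa] = compute_measure_series(
            cfg.dfe, history, cfg.theta, cfg.t_grid(), engine, n_nodes=cfg.n_nodes
        )
    return out


def write_tsv(df: pd.DataFrame, path, config_echo: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed provenance comments echoing the config."""
    buf = io.StringIO()
    if config_echo:
        for key, val in config_echo.items():
            buf.write(f"# {key}: {json.dumps(val) if isinstance(val, (list, dict)) else val}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (skipping comment lines)."""
    return pd.read_csv(path, sep="\t", comment="#")
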