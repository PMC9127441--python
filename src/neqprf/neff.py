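"""Effective-population-size proxies.

Two common Neff measures with deliberately different timescales:

* ``neff_pi`` — scaled synonymous diversity ``piS(t) / (2 L mu) = N *
  piS(t) / (2 theta)``; a microevolutionary (snapshot) measure that tracks
  the current level of neutral variation.
* ``neff_h`` — harmonic-mean population size over ``[0, t]``; a
  macroevolutionary, variance-type measure that averages drift over the
  whole interval and therefore reacts slowly to recent size changes.

Both equal N in the ancestral equilibrium and tend to ``kappa*N`` long
after a single change.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import ModelParams
from .history import SizeHistory
from .nonequilibrium import pi_s_t

__all__ = ["neff_pi", "neff_h", "neff_series"]


def neff_pi(pi_s_value, params: ModelParams):
    """Diversity-based effective size ``piS / (2 L mu) = N piS / (2 theta)``.

    The number of sites L cancels against the per-site mutation rate, so
    only theta and N are needed.
    """
    pi_arr = np.asarray(pi_s_value, dtype=float)
    if np.any(pi_arr <= 0):
        raise ValueError("piS must be positive")
    out = params.N * pi_arr / (2.0 * params.theta)
    return out if np.asarray(pi_s_value).ndim else float(out)


def neff_h(t, history: SizeHistory, params: ModelParams | None = None):
    """Harmonic-mean effective size over ``[0, t]``.

    For a single change at ``tstar`` to ratio ``kappa`` this is the closed
    form ``kappa*N*t / (tstar*(kappa - 1) + t)`` for ``t >= tstar`` and N
    before the change; the general step-function integral is used for
    multi-epoch histories.  Requires ``t > 0``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise ValueError("t must be positive")
    out = np.asarray([history.harmonic_mean_size(ti) for ti in t_arr])
    return out if np.asarray(t).ndim else float(out[0])


def neff_series(
    history: SizeHistory,
    params: ModelParams,
    t_grid: Sequence[float],
) -> pd.DataFrame:
    """DataFrame with columns ``time, neff_pi, neff_h`` on a time grid."""
    t_arr = np.asarray(t_grid, dtype=float)
    pi_s = np.atleast_1d(pi_s_t(history, params.theta, t_arr))
    npi = neff_pi(pi_s, params)
    nh = np.asarray(
        [history.harmonic_mean_size(ti) if ti > 0 else history.N_ref for ti in t_arr]
    )
    return pd.DataFrame({"time": t_arr, "neff_pi": npi, "neff_h": nh})
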