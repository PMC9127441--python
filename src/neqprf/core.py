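"""Equilibrium building blocks of the Poisson random field (PRF) model.

A population of haploid reference size ``N`` evolves under the Wright-Fisher
diffusion with additive selection.  Each mutation class is described by a
population-scaled selection coefficient ``gamma`` (negative = deleterious) and
a size ratio ``kappa`` (current size over reference size).  In equilibrium the
PRF machinery reduces to three classical objects:

* the fixation probability ``q(y)`` of a derived allele at frequency ``y``,
* the instantaneous fixation rate ``omega`` of the selected class relative to
  a neutral class (the population analogue of dN/dS),
* the intensity density ``psi(y)`` of segregating frequencies, so that the
  expected equilibrium spectrum of polymorphic sites is
  ``theta * omega * psi(y) dy``.

All three depend on ``gamma`` and ``kappa`` only through the product
``gamma * kappa``; evaluation is numerically stable over the full range used
downstream (``gamma`` down to -1000, ``kappa`` in [0.1, 4]).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np
from scipy import integrate

__all__ = [
    "SelectionRegime",
    "ModelParams",
    "SpectrumFunctional",
    "QuadratureError",
    "f_pw",
    "f_fix",
    "fixation_prob",
    "fixation_rate",
    "sfs_density",
    "sfs_intensity",
    "equilibrium_functional",
    "pi_equilibrium",
    "omega_weighted",
]

#: |2*gamma*kappa| below this is treated as neutral (analytic limits).
NEUTRAL_EPS = 1e-8
#: exp() overflow guard; beyond this exponentials are evaluated in log space.
_EXP_CAP = 700.0


@dataclasses.dataclass(frozen=True)
class SelectionRegime:
    """Selection regime of one mutation class: scaled selection ``gamma``
    (relative to the reference size) and size ratio ``kappa``."""

    gamma: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if not (self.kappa > 0.0 and math.isfinite(self.kappa)):
            raise ValueError("kappa must be positive and finite")

    @property
    def gamma_eff(self) -> float:
        """Effective scaled selection ``gamma * kappa`` of the reduced
        (reference-size, time-rescaled) dynamics."""
        return self.gamma * self.kappa

    def reduced(self) -> "SelectionRegime":
        """The reference-size regime with the same ``gamma * kappa``."""
        return SelectionRegime(self.gamma_eff, 1.0)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Global model parameters.

    theta
        Population mutation intensity per generation in the reference
        population (dimensionless, ``theta = L * N * mu``).
    N
        Reference haploid population size (individuals).
    tstar
        Time of the size change, in units of N generations.
    t_present
        Present time, same units.
    L
        Number of independent sites; optional, only needed to convert
        ``theta`` to a per-site mutation rate.
    """

    theta: float
    N: float
    tstar: float = 1.0
    t_present: float = 20.0
    L: float | None = None

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if not self.N >= 2:
            raise ValueError("N must be at least 2")
        if not (0.0 <= self.tstar <= self.t_present):
            raise ValueError("need 0 <= tstar <= t_present")
        if self.L is not None and not self.L > 0:
            raise ValueError("L must be positive when supplied")

    @property
    def mu(self) -> float:
        """Per-site, per-individual mutation rate ``theta / (L N)``."""
        if self.L is None:
            raise ValueError("L is required to compute mu")
        return self.theta / (self.L * self.N)


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to reach the requested accuracy."""


def f_pw(y):
    """Pairwise-difference function ``2 y (1 - y)`` (nucleotide diversity)."""
    y = np.asarray(y, dtype=float)
    out = 2.0 * y * (1.0 - y)
    return out if out.ndim else float(out)


def f_fix(y):
    """Indicator of fixation, ``1{y == 1}``."""
    y = np.asarray(y, dtype=float)
    out = np.where(y == 1.0, 1.0, 0.0)
    return out if out.ndim else float(out)


def _log_expm1(z: np.ndarray) -> np.ndarray:
    """log(exp(z) - 1) for z > 0, stable for large z."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    big = z > 33.0
    out[big] = z[big] + np.log1p(-np.exp(-z[big]))
    with np.errstate(divide="ignore"):  # z == 0 -> -inf, maps back to q = 0
        out[~big] = np.log(np.expm1(z[~big]))
    return out


def fixation_prob(y, regime: SelectionRegime):
    """Fixation probability ``q(y)`` of a derived allele at frequency ``y``.

    ``q(y) = (1 - exp(-2*gamma*kappa*y)) / (1 - exp(-2*gamma*kappa))`` for
    ``gamma != 0`` and ``q(y) = y`` in the neutral limit.  Stable for
    ``|2*gamma*kappa|`` far beyond the exp() overflow threshold.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0.0) or np.any(y_arr > 1.0):
        raise ValueError("y must lie in [0, 1]")
    x = 2.0 * regime.gamma_eff
    if abs(x) < NEUTRAL_EPS:
        out = y_arr.copy()
    elif -x <= _EXP_CAP:
        # direct evaluation; for x > 0 both expm1 arguments are negative
        out = np.expm1(-x * y_arr) / np.expm1(-x)
    else:
        # strongly deleterious: evaluate the ratio in log space
        with np.errstate(invalid="ignore"):
            out = np.exp(_log_expm1(-x * y_arr) - _log_expm1(-x))
        out = np.where(y_arr == 0.0, 0.0, out)
    out = np.clip(out, 0.0, 1.0)
    return out if np.asarray(y).ndim else float(out)


def fixation_rate(regime: SelectionRegime) -> float:
    """Instantaneous fixation rate ``omega`` relative to neutral.

    ``omega = 2*gamma*kappa / (1 - exp(-2*gamma*kappa))``, with ``omega = 1``
    at ``gamma = 0``.  Monotone increasing in ``gamma``; underflows gracefully
    to 0 for strongly negative ``gamma*kappa``.
    """
    x = 2.0 * regime.gamma_eff
    if abs(x) < NEUTRAL_EPS:
        return 1.0
    if -x > _EXP_CAP:
        return -x * math.exp(x)  # asymptotic tail, may be subnormal/zero
    return -x / math.expm1(-x)


def sfs_density(y, regime: SelectionRegime):
    """Equilibrium intensity density ``psi(y)`` of segregating frequencies.

    ``psi(y) = (1 - exp(-2*gamma*kappa*(1-y))) / (gamma * y * (1-y))`` with
    neutral limit ``2*kappa/y``.  For extreme deleterious regimes the true
    value exceeds float range and the function returns ``inf``; integrals
    should use :func:`sfs_intensity`, which is stable everywhere.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= 0.0) or np.any(y_arr >= 1.0):
        raise ValueError("y must lie in the open interval (0, 1)")
    x = 2.0 * regime.gamma_eff
    if abs(x) < NEUTRAL_EPS:
        out = 2.0 * regime.kappa / y_arr
    else:
        z = -x * (1.0 - y_arr)  # positive for deleterious gamma
        out = np.empty_like(y_arr)
        safe = z <= _EXP_CAP
        out[safe] = -np.expm1(z[safe]) / (regime.gamma * y_arr[safe] * (1.0 - y_arr[safe]))
        if np.any(~safe):
            logs = _log_expm1(z[~safe]) - np.log(
                abs(regime.gamma) * y_arr[~safe] * (1.0 - y_arr[~safe])
            )
            with np.errstate(over="ignore"):
                out[~safe] = np.exp(logs)
    return out if np.asarray(y).ndim else float(out)


def sfs_intensity(y, regime: SelectionRegime):
    """Stable product ``omega * psi(y)``, the equilibrium spectrum intensity.

    Uses the identity ``omega*psi(y) = 2*kappa*q(1-y) / (y*(1-y))`` with the
    bounded fixation probability ``q``, which avoids overflow for any
    ``gamma*kappa``.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= 0.0) or np.any(y_arr >= 1.0):
        raise ValueError("y must lie in the open interval (0, 1)")
    q = fixation_prob(1.0 - y_arr, regime)
    out = 2.0 * regime.kappa * np.asarray(q) / (y_arr * (1.0 - y_arr))
    return out if np.asarray(y).ndim else float(out)


@dataclasses.dataclass(frozen=True)
class SpectrumFunctional:
    """Decomposition of the expected AFS functional ``E<X_t, f>``.

    fixation_mass
        Contribution of accumulated fixations, ``theta * f(1) * integral of
        omega over [0, t]``.
    polymorphic_mass
        Equilibrium polymorphic contribution ``theta * int f omega psi dy``
        for the current epoch.
    transient_mass
        Nonequilibrium contribution of standing variation carried across size
        changes (zero in equilibrium and for ``t <= tstar``).
    se
        Monte-Carlo standard error of ``transient_mass`` when a stochastic
        engine supplied the conditional expectations (0 for analytic/PDE).
    """

    fixation_mass: float
    polymorphic_mass: float
    transient_mass: float = 0.0
    se: float = 0.0
    quad_error: float = 0.0

    @property
    def total(self) -> float:
        return self.fixation_mass + self.polymorphic_mass + self.transient_mass


def equilibrium_functional(
    f: Callable[[float], float],
    regime: SelectionRegime,
    theta: float,
    t: float,
    rtol: float = 1e-8,
) -> SpectrumFunctional:
    """Equilibrium AFS functional: ``theta*omega*f(1)*t`` (fixations) plus
    ``theta * int_0^1 f(y) omega psi(y) dy`` (polymorphic spectrum).

    ``f`` must make ``f(y)*psi(y)`` integrable near 0, i.e. ``f(y) = O(y)``.
    Raises :class:`QuadratureError` when the adaptive quadrature cannot
    certify the requested relative accuracy.
    """
    omega = fixation_rate(regime)
    fixation_mass = theta * omega * float(f(1.0)) * t

    def integrand(y: float) -> float:
        return float(f(y)) * sfs_intensity(y, regime)

    val, err = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-13, epsrel=1e-11, limit=200)
    if val != 0.0 and err > rtol * abs(val) and err > 1e-12:
        raise QuadratureError(
            f"polymorphic-mass quadrature did not converge: value {val!r}, "
            f"error estimate {err!r}"
        )
    rel_err = err / abs(val) if val != 0.0 else err
    return SpectrumFunctional(
        fixation_mass=fixation_mass,
        polymorphic_mass=theta * val,
        quad_error=rel_err,
    )


def pi_equilibrium(regime: SelectionRegime, theta: float) -> float:
    """Equilibrium nucleotide diversity of the class,
    ``4*theta*kappa*(1/(1-exp(-2*gamma*kappa)) - 1/(2*gamma*kappa))``,
    with neutral limit ``2*theta*kappa``.
    """
    x = 2.0 * regime.gamma_eff
    if abs(x) < 1e-3:
        # series of 1/(1-e^-x) - 1/x; avoids catastrophic cancellation
        phi = 0.5 + x / 12.0 - x**3 / 720.0
    elif -x > _EXP_CAP:
        phi = -math.exp(x) - 1.0 / x
    else:
        phi = -1.0 / math.expm1(-x) - 1.0 / x
    return 4.0 * theta * regime.kappa * phi


def omega_weighted(t, tstar: float, omega_anc: float, omega_new: float):
    """Time-weighted average fixation-rate ratio
    ``[tstar*omega_anc + (t - tstar)*omega_new] / t``.

    This is the classical stationary-theory treatment of a size change: the
    ancestral and new equilibrium rates are mixed in proportion to the time
    spent in each epoch, ignoring the transient dynamics of standing
    variation.  Defined for ``0 < tstar <= t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not tstar > 0.0:
        raise ValueError("tstar must be positive")
    if np.any(t_arr < tstar):
        raise ValueError("t must satisfy t >= tstar")
    out = (tstar * omega_anc + (t_arr - tstar) * omega_new) / t_arr
    return out if np.asarray(t).ndim else float(out)
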