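"""Step-function population-size histories."""

from __future__ import annotations

import dataclasses

__all__ = ["SizeHistory"]


@dataclasses.dataclass(frozen=True)
class SizeHistory:
    """Population size over time as a step function of the reference size.

    The population has size ``N_ref`` (``kappa = 1``) before the first
    change; each epoch ``(t_k, kappa_k)`` sets the size to ``kappa_k *
    N_ref`` from time ``t_k`` on.  Times are in units of N_ref generations
    and must be strictly increasing.
    """

    N_ref: float
    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.N_ref >= 2:
            raise ValueError("N_ref must be at least 2")
        times = [t for t, _ in self.epochs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("change times must be strictly increasing")
        if any(t <= 0 for t in times):
            raise ValueError("change times must be positive")
        if any(k <= 0 for _, k in self.epochs):
            raise ValueError("size ratios must be positive")
        object.__setattr__(self, "epochs", tuple((float(t), float(k)) for t, k in self.epochs))

    @classmethod
    def single_change(cls, N_ref: float, tstar: float, kappa: float) -> "SizeHistory":
        return cls(N_ref=N_ref, epochs=((tstar, kappa),))

    @property
    def is_single(self) -> bool:
        return len(self.epochs) == 1

    @property
    def tstar(self) -> float:
        """Time of the (first) size change."""
        if not self.epochs:
            raise ValueError("history has no size change")
        return self.epochs[0][0]

    @property
    def kappa(self) -> float:
        """Size ratio after the (last) change; 1 if no change."""
        return self.epochs[-1][1] if self.epochs else 1.0

    def kappa_at(self, t: float) -> float:
        """Size ratio in force at time ``t`` (right-continuous)."""
        k = 1.0
        for t_k, kap in self.epochs:
            if t >= t_k:
                k = kap
            else:
                break
        return k

    def harmonic_mean_size(self, t: float) -> float:
        """Harmonic-mean population size over ``[0, t]``."""
        if not t > 0:
            raise ValueError("t must be positive")
        total = 0.0
        prev_t, prev_k = 0.0, 1.0
        for t_k, kap in self.epochs:
            if t_k >= t:
                break
            total += (t_k - prev_t) / prev_k
            prev_t, prev_k = t_k, kap
        total += (t - prev_t) / prev_k
        return self.N_ref * t / total
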