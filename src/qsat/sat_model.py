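"""Parametric speed-accuracy tradeoff (SAT) function.

The SAT function describes how response accuracy grows with processing time
in a time-controlled (response-signal) task.  It is modelled as a shifted
exponential approach to an asymptote,

    psi(t) = lam * (1 - exp(-gam * (t - delta)))   for t > delta, else 0,

where ``lam`` is the asymptotic *above-chance* accuracy, ``gam`` the rate of
information accrual (1/s) and ``delta`` the intercept (s) before which
performance is at chance.  Probability correct adds the task's guessing
rate: ``pc(t) = chance + psi(t)`` (``chance = 0.5`` for 2AFC).

All times are in seconds throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SATParams", "TaskSpec", "psi", "prob_correct"]


@dataclass(frozen=True)
class SATParams:
    """SAT curve parameters (lam: above-chance asymptote, gam: 1/s, delta: s)."""

    lam: float
    gam: float
    delta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lam <= 0.5):
            raise ValueError(f"lam must lie in (0, 0.5], got {self.lam}")
        if not self.gam > 0.0:
            raise ValueError(f"gam must be positive, got {self.gam}")
        if not self.delta >= 0.0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam, self.gam, self.delta])


@dataclass(frozen=True)
class TaskSpec:
    """Task constants: guessing probability and response-window length (s)."""

    chance: float = 0.5
    window: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.chance < 1.0):
            raise ValueError(f"chance must lie in [0, 1), got {self.chance}")
        if not self.window > 0.0:
            raise ValueError(f"window must be positive, got {self.window}")


def psi(params: SATParams, t):
    """Above-chance accuracy at time ``t`` (scalar or array, seconds).

    Returns ``lam * (1 - exp(-gam*(t - delta)))`` for ``t > delta`` and 0
    otherwise (the boundary ``t == delta`` takes the zero branch).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    dt = np.maximum(t - params.delta, 0.0)
    out = params.lam * -np.expm1(-params.gam * dt)
    return out if out.ndim else float(out)


def prob_correct(params: SATParams, task: TaskSpec, t):
    """Probability correct at time ``t``: ``chance + psi(t)``."""
    return task.chance + psi(params, t)
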