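"""Virtual observers for the response-signal SAT paradigm.

A virtual observer couples a true SAT curve with an ex-Gaussian response-time
distribution.  On each trial the response signal appears after a chosen SOA
(stimulus-onset asynchrony) and the observer may respond only within a short
window after it; the realized RT is an ex-Gaussian draw constrained to
``[soa, soa + window]`` and correctness is Bernoulli with probability
``prob_correct`` evaluated at that realized RT (the conditional accuracy
function), not at the SOA.

Truncation is by rejection sampling from the unconstrained ex-Gaussian; when
the window carries essentially no mass (long SOAs with the default RT
parameters), the sampler falls back to a uniform draw on the window after
``MAX_REJECTION_ATTEMPTS`` failures per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sat_model import SATParams, TaskSpec, prob_correct

__all__ = [
    "ExGaussParams",
    "VirtualObserver",
    "TrialRecord",
    "BlockRecord",
    "STUDY_OBSERVERS",
    "DEFAULT_RT_DIST",
    "sample_rt",
    "sample_rts",
    "simulate_trial",
    "simulate_block",
    "trials_to_frame",
    "write_trials_csv",
    "read_trials_csv",
]

logger = logging.getLogger(__name__)

#: rejection attempts per trial before falling back to a uniform draw
MAX_REJECTION_ATTEMPTS = 1000


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian RT distribution: Normal(mu, sigma) + Exponential(tau), seconds."""

    mu: float = 0.3
    sigma: float = 0.06
    tau: float = 0.08

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


@dataclass(frozen=True)
class VirtualObserver:
    sat: SATParams
    rtdist: ExGaussParams = field(default_factory=ExGaussParams)
    task: TaskSpec = field(default_factory=TaskSpec)


#: simulated-observer SAT parameters used throughout the validation study
STUDY_OBSERVERS: dict[int, SATParams] = {
    1: SATParams(0.470, 7.5, 0.28),
    2: SATParams(0.450, 5.0, 0.22),
    3: SATParams(0.495, 22.0, 0.24),
    4: SATParams(0.495, 20.0, 0.36),
}

DEFAULT_RT_DIST = ExGaussParams()


@dataclass(frozen=True)
class TrialRecord:
    """One observation: SOA (s), realized RT (s), correctness (0/1)."""

    soa: float
    rt: float
    correct: int


@dataclass(frozen=True)
class BlockRecord:
    """An ordered run of trials sharing one SOA."""

    soa: float
    trials: tuple[TrialRecord, ...]

    def __post_init__(self) -> None:
        if any(tr.soa != self.soa for tr in self.trials):
            raise ValueError("all trials in a block must share the block SOA")


def sample_rts(
    rtdist: ExGaussParams,
    soa: float,
    window: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` RTs from the ex-Gaussian truncated to ``[soa, soa + window]``.

    Vectorized rejection sampling; trials still unresolved after
    ``MAX_REJECTION_ATTEMPTS`` proposals each are filled uniformly on the
    window (logged once per call).
    """
    if not window > 0:
        raise ValueError("window must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = soa, soa + window
    out = np.full(n, np.nan)
    pending = np.arange(n)
    attempts = 0
    chunk = 64
    while pending.size and attempts < MAX_REJECTION_ATTEMPTS:
        take = min(chunk, MAX_REJECTION_ATTEMPTS - attempts)
        draws = rng.normal(rtdist.mu, rtdist.sigma, (pending.size, take))
        draws += rng.exponential(rtdist.tau, (pending.size, take))
        ok = (draws >= lo) & (draws <= hi)
        hit = ok.any(axis=1)
        first = ok.argmax(axis=1)
        out[pending[hit]] = draws[hit, first[hit]]
        pending = pending[~hit]
        attempts += take
        chunk = min(chunk * 4, 1024)
    if pending.size:
        logger.info(
            "ex-Gaussian window [%g, %g] carries negligible mass; "
            "uniform fallback for %d/%d trials", lo, hi, pending.size, n,
        )
        out[pending] = rng.uniform(lo, hi, pending.size)
    return out


def sample_rt(
    rtdist: ExGaussParams, soa: float, window: float, rng: np.random.Generator
) -> float:
    """Single truncated ex-Gaussian RT draw in ``[soa, soa + window]``."""
    return float(sample_rts(rtdist, soa, window, 1, rng)[0])


def simulate_trial(
    obs: VirtualObserver, soa: float, rng: np.random.Generator
) -> TrialRecord:
    """Simulate one response-signal trial at the given SOA."""
    rt = sample_rt(obs.rtdist, soa, obs.task.window, rng)
    pc = prob_correct(obs.sat, obs.task, rt)
    correct = int(rng.random() < pc)
    return TrialRecord(soa=soa, rt=rt, correct=correct)


def simulate_block(
    obs: VirtualObserver, soa: float, n: int, rng: np.random.Generator
) -> BlockRecord:
    """Simulate ``n`` independent trials at one SOA."""
    if n < 1:
        raise ValueError("block must contain at least one trial")
    rts = sample_rts(obs.rtdist, soa, obs.task.window, n, rng)
    pcs = prob_correct(obs.sat, obs.task, rts)
    corrects = (rng.random(n) < pcs).astype(int)
    trials = tuple(
        TrialRecord(soa=soa, rt=float(r), correct=int(c))
        for r, c in zip(rts, corrects)
    )
    return BlockRecord(soa=soa, trials=trials)


# ---------------------------------------------------------------------------
# trial-data interchange (CSV: soa, rt, correct, block_index)

def trials_to_frame(blocks: list[BlockRecord]) -> pd.DataFrame:
    rows = [
        (tr.soa, tr.rt, tr.correct, b)
        for b, blk in enumerate(blocks)
        for tr in blk.trials
    ]
    return pd.DataFrame(rows, columns=["soa", "rt", "correct", "block_index"])


def write_trials_csv(blocks: list[BlockRecord], path) -> None:
    trials_to_frame(blocks).to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    """Read and validate a trial CSV (columns soa, rt, correct[, block_index])."""
    df = pd.read_csv(path)
    required = {"soa", "rt", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("trial CSV contains no trials")
    bad = df.index[~df["correct"].isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"correct column must be 0/1; offending rows (0-based): {list(bad[:10])}"
        )
    return df
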