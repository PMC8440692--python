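"""Information-gain-maximizing SOA selection for block-wise SAT testing.

Because the response-signal paradigm changes the SOA per *block* rather than
per trial, the next stimulus is chosen by a multiple-step-ahead search: for
each candidate SOA the outcome of the upcoming n-trial block is modelled as
a binomial count of correct responses, with success probability given by the
SAT curve evaluated at the block's *expected* RT (the midpoint of the
response window, ``soa + window/2``).  The selected SOA maximizes the mutual
information between that count and the parameters,

    I(R; Theta) = H(R) - sum_theta p(theta) H(R | theta),

with entropies in nats and the marginal predictive
``p(k) = sum_theta p(theta) Binom(k; n, pc_theta)``.  Ties break toward the
smallest SOA so selection is deterministic.

:class:`InformationGainPlanner` precomputes the binomial outcome tensor and
per-theta conditional entropies once per (grid, space, design), reducing
each selection to a single matrix-vector product against the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, xlogy

from .bayes_engine import ParameterGrid, Posterior, pc_grid
from .sat_model import TaskSpec

__all__ = [
    "StimulusSpace",
    "BlockDesign",
    "expected_rt",
    "block_outcome_likelihood",
    "expected_information_gain",
    "select_soa",
    "InformationGainPlanner",
]


@dataclass(frozen=True)
class StimulusSpace:
    """Candidate SOAs; default 49 equally spaced values on [0, 1.2] s."""

    soas: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.2, 49))

    def __post_init__(self) -> None:
        a = np.asarray(self.soas, dtype=float)
        if a.ndim != 1 or a.size < 1 or (a.size > 1 and not np.all(np.diff(a) > 0)):
            raise ValueError("soas must be a strictly increasing 1-D array")
        object.__setattr__(self, "soas", a)


@dataclass(frozen=True)
class BlockDesign:
    """Trials per block and response-window length (s)."""

    n_trials: int = 16
    window: float = 0.2

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.window > 0:
            raise ValueError("window must be positive")


def expected_rt(soa: float, window: float) -> float:
    """Expected RT for a block: the response-window midpoint, soa + window/2."""
    return soa + window / 2.0


def block_outcome_likelihood(pc, n: int) -> np.ndarray:
    """Binomial mass over k = 0..n correct responses out of n trials.

    ``pc`` may be scalar or an array; the k axis is appended last.
    """
    pc = np.asarray(pc, dtype=float)
    if np.any((pc < 0) | (pc > 1)):
        raise ValueError("pc must lie in [0, 1]")
    k = np.arange(n + 1, dtype=float)
    logcomb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    p = pc[..., None]
    logpmf = logcomb + xlogy(k, p) + xlogy(n - k, 1.0 - p)
    return np.exp(logpmf)


def _entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in nats along ``axis`` with 0 log 0 := 0."""
    return -xlogy(p, p).sum(axis=axis)


class InformationGainPlanner:
    """Precomputed expected-information-gain evaluator for one design.

    Parameters are fixed at construction (grid, task, stimulus space, block
    design); :meth:`gains` then costs one GEMV per posterior.
    """

    def __init__(
        self,
        grid: ParameterGrid,
        task: TaskSpec,
        space: StimulusSpace | None = None,
        design: BlockDesign | None = None,
    ) -> None:
        self.grid = grid
        self.task = task
        self.space = space if space is not None else StimulusSpace()
        self.design = design if design is not None else BlockDesign()
        xs = np.array([expected_rt(s, self.design.window) for s in self.space.soas])
        pcs = pc_grid(grid, task, xs).reshape(xs.size, -1)  # (S, T)
        # binomial pmf over k = 0..n, built in log space without per-element
        # xlogy (pc is bounded away from 0 by the chance level; 1-pc is
        # clipped against round-off at extreme RTs)
        n = self.design.n_trials
        k = np.arange(n + 1, dtype=float)
        logcomb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        logpc = np.log(np.clip(pcs, 1e-300, None))
        log1m = np.log(np.clip(1.0 - pcs, 1e-300, None))
        logpmf = (logcomb[None, None, :]
                  + k[None, None, :] * logpc[..., None]
                  + (n - k)[None, None, :] * log1m[..., None])  # (S, T, K)
        pmf = np.exp(logpmf)
        self._cond_entropy = -(pmf * logpmf).sum(axis=-1)  # (S, T)
        # (S*K, T) so the predictive for all SOAs is one matvec
        self._pmf_matrix = np.ascontiguousarray(
            pmf.transpose(0, 2, 1).reshape(-1, pcs.shape[1]))
        self._n_out = self.design.n_trials + 1

    def gains(self, post: Posterior) -> np.ndarray:
        """Expected information gain (nats) for every SOA in the space."""
        w = post.mass.ravel()
        predictive = (self._pmf_matrix @ w).reshape(-1, self._n_out)  # (S, K)
        h_marginal = _entropy(predictive)
        h_conditional = self._cond_entropy @ w
        return np.maximum(h_marginal - h_conditional, 0.0)

    def select(self, post: Posterior) -> tuple[float, float]:
        """(best SOA, its expected gain); ties break to the smallest SOA."""
        g = self.gains(post)
        i = int(np.argmax(g))  # argmax returns the first (smallest-SOA) maximum
        return float(self.space.soas[i]), float(g[i])


def expected_information_gain(
    post: Posterior, task: TaskSpec, soa: float, design: BlockDesign
) -> float:
    """Expected information gain (nats) of an n-trial block at one SOA."""
    planner = InformationGainPlanner(
        post.grid, task, StimulusSpace(np.array([soa])), design)
    return float(planner.gains(post)[0])


def select_soa(
    post: Posterior,
    task: TaskSpec,
    space: StimulusSpace,
    design: BlockDesign,
) -> float:
    """SOA maximizing expected information gain over the stimulus space."""
    return InformationGainPlanner(post.grid, task, space, design).select(post)[0]
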