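"""The four SAT estimation procedures run as simulated experiments.

Procedure 1 — method of constant stimuli (MCS) data; at each checkpoint the
model is fitted by maximum likelihood to per-SOA *averaged* data (binomial
correct counts evaluated at per-SOA mean RTs).  The traditional analysis.

Procedure 2 — the same MCS data, but fitted trial-by-trial: each (rt,
correct) pair contributes its own Bernoulli likelihood, without averaging.

Procedure 3 — the same MCS data again, analysed online with the grid-based
Bayesian engine (uniform prior, per-trial updates, marginal-mean estimates).

Procedure 4 — Bayesian adaptive: each block's SOA is chosen to maximize the
expected information gain of the upcoming block (multiple-step-ahead
search); by default the posterior is updated per trial on realized
(rt, correct) pairs, with a block-granularity variant available that updates
once per block on the binomial count at the block's expected RT.

All four consume and emit the same trial schema and the same
:class:`RunResult` trajectory structure, so their accuracy and precision can
be compared checkpoint-by-checkpoint.  For a fixed random generator state,
Procedures 1-3 simulate byte-identical MCS datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .adaptive_selection import (
    BlockDesign,
    InformationGainPlanner,
    StimulusSpace,
    block_outcome_likelihood,
    expected_rt,
)
from .bayes_engine import (
    DEFAULT_HWCI_LEVEL,
    ParameterGrid,
    Posterior,
    estimate_params,
    hwci,
    init_prior,
    marginal,
    pc_grid,
    reconstruct_function,
    update,
)
from .observer_sim import VirtualObserver, sample_rts
from .sat_model import SATParams, TaskSpec, prob_correct

__all__ = [
    "DEFAULT_SOA_LEVELS",
    "DEFAULT_EVAL_TIMES",
    "DEFAULT_CHECKPOINTS",
    "DEFAULT_FIT_BOUNDS",
    "ProcedureConfig",
    "RunResult",
    "FitResult",
    "mle_fit",
    "run_procedure1",
    "run_procedure2",
    "run_procedure3",
    "run_procedure4",
    "run_procedure",
]

#: MCS SOA levels (s) of the validation study
DEFAULT_SOA_LEVELS = (0.06, 0.09, 0.12, 0.24, 0.36, 0.48, 0.60, 1.20)
#: time points (s) at which estimated SAT functions are evaluated
DEFAULT_EVAL_TIMES = (0.06, 0.09, 0.12, 0.24, 0.36, 0.48, 0.60, 1.20)
#: powers of two up to the full run, plus the 100-trial probe
DEFAULT_CHECKPOINTS = (1, 2, 4, 8, 16, 32, 64, 100, 128, 256, 512, 1024, 2048)
#: fit bounds equal to the Bayesian grid ranges, for comparability
DEFAULT_FIT_BOUNDS = ((0.4, 0.5), (1.0, 30.0), (0.02, 0.5))


@dataclass(frozen=True)
class ProcedureConfig:
    """Settings for one simulated estimation run."""

    procedure_id: int
    soa_levels: tuple[float, ...] = DEFAULT_SOA_LEVELS
    trials_per_condition: int = 256
    block_length: int = 16
    total_trials: int = 2048
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS
    eval_times: tuple[float, ...] = DEFAULT_EVAL_TIMES
    mcs_mode: str = "short"           # "short": randomized block_length blocks;
                                      # "long": one trials_per_condition block per SOA
    fit_method: str = "mle"           # "mle" | "lse" (Procedures 1-2)
    update_granularity: str = "trial"  # "trial" | "block" (Procedure 4)
    n_resamples: int = 1000
    hwci_level: float = DEFAULT_HWCI_LEVEL

    def __post_init__(self) -> None:
        if self.procedure_id not in (1, 2, 3, 4):
            raise ValueError("procedure_id must be 1, 2, 3 or 4")
        if self.block_length < 1 or self.total_trials < 1:
            raise ValueError("block_length and total_trials must be >= 1")
        if self.total_trials % self.block_length:
            raise ValueError("total_trials must be a multiple of block_length")
        cps = tuple(sorted(set(int(c) for c in self.checkpoints
                               if int(c) <= self.total_trials)))
        if not cps or cps[0] < 1:
            raise ValueError("checkpoints must include a value in [1, total_trials]")
        object.__setattr__(self, "checkpoints", cps)
        if self.procedure_id in (1, 2, 3):
            per_cond = self.total_trials / len(self.soa_levels)
            if per_cond != int(per_cond):
                raise ValueError(
                    "total_trials must divide evenly across soa_levels for MCS")
        if self.mcs_mode not in ("short", "long"):
            raise ValueError("mcs_mode must be 'short' or 'long'")
        if self.fit_method not in ("mle", "lse"):
            raise ValueError("fit_method must be 'mle' or 'lse'")
        if self.update_granularity not in ("trial", "block"):
            raise ValueError("update_granularity must be 'trial' or 'block'")


@dataclass
class RunResult:
    """Per-checkpoint trajectories of one simulated run.

    Arrays are indexed by checkpoint; fits that failed or were unidentifiable
    hold NaN with ``identifiable`` False.  ``hwcis`` and ``curve_hwcis`` are
    None for the non-Bayesian procedures.
    """

    procedure_id: int
    checkpoints: np.ndarray             # (C,)
    estimates: np.ndarray               # (C, 3) lam, gam, delta
    curves: np.ndarray                  # (C, K) estimated pc at eval_times
    eval_times: np.ndarray              # (K,)
    identifiable: np.ndarray            # (C,) bool
    hwcis: np.ndarray | None = None     # (C, 3)
    curve_hwcis: np.ndarray | None = None  # (C, K)
    soa_history: np.ndarray | None = None  # (B,) per-block SOA
    expected_gains: np.ndarray | None = None  # (B,) nats, Procedure 4
    realized_gains: np.ndarray | None = None  # (B,) nats, Procedure 4
    trials: pd.DataFrame | None = None


@dataclass(frozen=True)
class FitResult:
    params: SATParams | None
    objective: float
    converged: bool
    identifiable: bool


# ---------------------------------------------------------------------------
# maximum-likelihood / least-squares fitting (Procedures 1-2)

def _neg_loglik(x, rt, k, n, chance):
    lam, gam, dlt = x
    pc = chance + lam * -np.expm1(-gam * np.maximum(rt - dlt, 0.0))
    pc = np.clip(pc, 1e-10, 1.0 - 1e-10)
    return -(k * np.log(pc) + (n - k) * np.log1p(-pc)).sum()


def _sse(x, rt, k, n, chance):
    lam, gam, dlt = x
    pc = chance + lam * -np.expm1(-gam * np.maximum(rt - dlt, 0.0))
    return (((k / n) - pc) ** 2).sum()


def mle_fit(
    rt,
    k,
    n=None,
    *,
    task: TaskSpec,
    bounds=DEFAULT_FIT_BOUNDS,
    n_starts: int = 8,
    rng: np.random.Generator | None = None,
    method: str = "mle",
) -> FitResult:
    """Bounded multi-start fit of the SAT curve to binomial data.

    ``rt`` are the time points, ``k`` the correct counts and ``n`` the trial
    counts per point (``n=None`` means trial-wise data with one trial per
    point, i.e. ``k`` in {0, 1}).  Starting points come from a seeded Latin
    hypercube over the bounds; the best converged solution is returned.
    Data with fewer than 3 distinct time points cannot pin down 3 parameters
    and are flagged unidentifiable.
    """
    rt = np.asarray(rt, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.ones_like(k) if n is None else np.asarray(n, dtype=float)
    if np.unique(rt).size < 3:
        return FitResult(None, np.nan, False, False)
    rng = np.random.default_rng() if rng is None else rng
    objective = _neg_loglik if method == "mle" else _sse
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=3, seed=rng)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, args=(rt, k, n, task.chance),
            method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    params = SATParams(*np.clip(best.x, lo, hi))
    return FitResult(params, float(best.fun), bool(best.success), True)


# ---------------------------------------------------------------------------
# simulated data collection

def _mcs_block_soas(cfg: ProcedureConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomized block order for MCS data collection.

    The fixed SOA set is presented repeatedly in random order: each round
    presents every level once as one block, with an independent shuffle per
    round, so accumulated data stay balanced across conditions.
    """
    levels = np.array(cfg.soa_levels)
    if cfg.mcs_mode == "long":
        return rng.permutation(levels)
    rounds = cfg.total_trials // (levels.size * cfg.block_length)
    return np.concatenate([rng.permutation(levels) for _ in range(rounds)])


def _simulate_blocks(
    obs: VirtualObserver, soas: np.ndarray, n_per_block: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate blocks of trials; returns flat (soa, rt, correct) arrays."""
    all_soa, all_rt, all_c = [], [], []
    for soa in soas:
        rts = sample_rts(obs.rtdist, float(soa), obs.task.window, n_per_block, rng)
        pcs = prob_correct(obs.sat, obs.task, rts)
        cs = (rng.random(n_per_block) < pcs).astype(int)
        all_soa.append(np.full(n_per_block, soa))
        all_rt.append(rts)
        all_c.append(cs)
    return np.concatenate(all_soa), np.concatenate(all_rt), np.concatenate(all_c)


def _trials_frame(soa, rt, correct, n_per_block) -> pd.DataFrame:
    return pd.DataFrame({
        "soa": soa,
        "rt": rt,
        "correct": correct,
        "block_index": np.arange(soa.size) // n_per_block,
    })


# ---------------------------------------------------------------------------
# checkpoint recording helpers

def _record_bayes_checkpoint(
    post: Posterior, task: TaskSpec, cfg: ProcedureConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    est = estimate_params(post)
    g = post.grid
    hw = np.array([
        hwci(marginal(post, "lam"), g.lam_axis, cfg.hwci_level).half_width,
        hwci(marginal(post, "gam"), g.gam_axis, cfg.hwci_level).half_width,
        hwci(marginal(post, "del"), g.del_axis, cfg.hwci_level).half_width,
    ])
    curve, spread = reconstruct_function(
        post, task, np.array(cfg.eval_times), cfg.n_resamples, rng,
        cfg.hwci_level)
    return est.as_array(), hw, curve, spread


def _plugin_curve(params: SATParams | None, task: TaskSpec, times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if params is None:
        return np.full(times.size, np.nan)
    return np.asarray(prob_correct(params, task, times))


# ---------------------------------------------------------------------------
# the four procedures

def _run_mcs_fit(
    obs: VirtualObserver, cfg: ProcedureConfig, rng: np.random.Generator,
    trialwise: bool,
) -> RunResult:
    """Shared driver for Procedures 1 (binned fit) and 2 (trial-wise fit)."""
    n_per_block = (cfg.trials_per_condition if cfg.mcs_mode == "long"
                   else cfg.block_length)
    block_soas = _mcs_block_soas(cfg, rng)
    soa, rt, correct = _simulate_blocks(obs, block_soas, n_per_block, rng)
    C = len(cfg.checkpoints)
    K = len(cfg.eval_times)
    estimates = np.full((C, 3), np.nan)
    curves = np.full((C, K), np.nan)
    identifiable = np.zeros(C, dtype=bool)
    for ci, t in enumerate(cfg.checkpoints):
        if trialwise:
            fit = mle_fit(rt[:t], correct[:t], task=obs.task, rng=rng,
                          method=cfg.fit_method)
        else:
            df = pd.DataFrame({"soa": soa[:t], "rt": rt[:t], "c": correct[:t]})
            agg = df.groupby("soa").agg(
                mean_rt=("rt", "mean"), k=("c", "sum"), n=("c", "size"))
            fit = mle_fit(agg["mean_rt"], agg["k"], agg["n"], task=obs.task,
                          rng=rng, method=cfg.fit_method)
        if fit.identifiable:
            estimates[ci] = fit.params.as_array()
            curves[ci] = _plugin_curve(fit.params, obs.task, cfg.eval_times)
            identifiable[ci] = True
    return RunResult(
        procedure_id=cfg.procedure_id,
        checkpoints=np.array(cfg.checkpoints),
        estimates=estimates, curves=curves,
        eval_times=np.array(cfg.eval_times),
        identifiable=identifiable,
        soa_history=block_soas,
        trials=_trials_frame(soa, rt, correct, n_per_block),
    )


def run_procedure1(
    obs: VirtualObserver, cfg: ProcedureConfig, rng: np.random.Generator
) -> RunResult:
    """MCS data, checkpointed fits to per-SOA mean RT and accuracy."""
    if cfg.procedure_id != 1:
        raise ValueError("cfg.procedure_id must be 1")
    return _run_mcs_fit(obs, cfg, rng, trialwise=False)


def run_procedure2(
    obs: VirtualObserver, cfg: ProcedureConfig, rng: np.random.Generator
) -> RunResult:
    """MCS data, checkpointed trial-by-trial Bernoulli fits."""
    if cfg.procedure_id != 2:
        raise ValueError("cfg.procedure_id must be 2")
    return _run_mcs_fit(obs, cfg, rng, trialwise=True)


def run_procedure3(
    obs: VirtualObserver, cfg: ProcedureConfig, rng: np.random.Generator,
    grid: ParameterGrid | None = None,
) -> RunResult:
    """MCS data analysed online with grid-based Bayesian updating."""
    if cfg.procedure_id != 3:
        raise ValueError("cfg.procedure_id must be 3")
    grid = ParameterGrid() if grid is None else grid
    n_per_block = (cfg.trials_per_condition if cfg.mcs_mode == "long"
                   else cfg.block_length)
    block_soas = _mcs_block_soas(cfg, rng)
    soa, rt, correct = _simulate_blocks(obs, block_soas, n_per_block, rng)
    C, K = len(cfg.checkpoints), len(cfg.eval_times)
    estimates = np.full((C, 3), np.nan)
    hwcis = np.full((C, 3), np.nan)
    curves = np.full((C, K), np.nan)
    spreads = np.full((C, K), np.nan)
    cpset = {t: i for i, t in enumerate(cfg.checkpoints)}
    post = init_prior(grid)
    for t in range(cfg.total_trials):
        post = update(post, obs.task, float(rt[t]), int(correct[t]))
        ci = cpset.get(t + 1)
        if ci is not None:
            estimates[ci], hwcis[ci], curves[ci], spreads[ci] = (
                _record_bayes_checkpoint(post, obs.task, cfg, rng))
    return RunResult(
        procedure_id=3,
        checkpoints=np.array(cfg.checkpoints),
        estimates=estimates, curves=curves,
        eval_times=np.array(cfg.eval_times),
        identifiable=np.ones(C, dtype=bool),
        hwcis=hwcis, curve_hwcis=spreads,
        soa_history=block_soas,
        trials=_trials_frame(soa, rt, correct, n_per_block),
    )


def run_procedure4(
    obs: VirtualObserver, cfg: ProcedureConfig, rng: np.random.Generator,
    grid: ParameterGrid | None = None,
    space: StimulusSpace | None = None,
    planner: InformationGainPlanner | None = None,
) -> RunResult:
    """Bayesian adaptive runs: select SOA by information gain, block by block.

    A prebuilt :class:`InformationGainPlanner` (matching grid, space and
    block design) may be supplied to amortize its setup across replications.
    """
    if cfg.procedure_id != 4:
        raise ValueError("cfg.procedure_id must be 4")
    grid = ParameterGrid() if grid is None else grid
    space = StimulusSpace() if space is None else space
    design = BlockDesign(n_trials=cfg.block_length, window=obs.task.window)
    if planner is None:
        planner = InformationGainPlanner(grid, obs.task, space, design)
    n_blocks = cfg.total_trials // cfg.block_length
    C, K = len(cfg.checkpoints), len(cfg.eval_times)
    estimates = np.full((C, 3), np.nan)
    hwcis = np.full((C, 3), np.nan)
    curves = np.full((C, K), np.nan)
    spreads = np.full((C, K), np.nan)
    soa_hist = np.empty(n_blocks)
    exp_gains = np.empty(n_blocks)
    real_gains = np.empty(n_blocks)
    all_soa = np.empty(cfg.total_trials)
    all_rt = np.empty(cfg.total_trials)
    all_c = np.empty(cfg.total_trials, dtype=int)
    cpset = {t: i for i, t in enumerate(cfg.checkpoints)}
    post = init_prior(grid)
    t_done = 0
    for b in range(n_blocks):
        soa, gain = planner.select(post)
        soa_hist[b] = soa
        exp_gains[b] = gain
        h_before = post.entropy()
        rts = sample_rts(obs.rtdist, soa, obs.task.window, cfg.block_length, rng)
        pcs = prob_correct(obs.sat, obs.task, rts)
        cs = (rng.random(cfg.block_length) < pcs).astype(int)
        sl = slice(t_done, t_done + cfg.block_length)
        all_soa[sl], all_rt[sl], all_c[sl] = soa, rts, cs
        if cfg.update_granularity == "block":
            x = expected_rt(soa, obs.task.window)
            pc_theta = pc_grid(grid, obs.task, x).ravel()
            lik = block_outcome_likelihood(pc_theta, cfg.block_length)[:, int(cs.sum())]
            m = post.mass.ravel() * np.clip(lik, 1e-300, None)
            post = Posterior(grid, (m / m.sum()).reshape(grid.shape))
            t_done += cfg.block_length
            ci = cpset.get(t_done)
            if ci is not None:
                estimates[ci], hwcis[ci], curves[ci], spreads[ci] = (
                    _record_bayes_checkpoint(post, obs.task, cfg, rng))
        else:
            for j in range(cfg.block_length):
                post = update(post, obs.task, float(rts[j]), int(cs[j]))
                t_done += 1
                ci = cpset.get(t_done)
                if ci is not None:
                    estimates[ci], hwcis[ci], curves[ci], spreads[ci] = (
                        _record_bayes_checkpoint(post, obs.task, cfg, rng))
        real_gains[b] = h_before - post.entropy()
    return RunResult(
        procedure_id=4,
        checkpoints=np.array(cfg.checkpoints),
        estimates=estimates, curves=curves,
        eval_times=np.array(cfg.eval_times),
        identifiable=np.ones(C, dtype=bool),
        hwcis=hwcis, curve_hwcis=spreads,
        soa_history=soa_hist,
        expected_gains=exp_gains, realized_gains=real_gains,
        trials=_trials_frame(all_soa, all_rt, all_c, cfg.block_length),
    )


_RUNNERS = {1: run_procedure1, 2: run_procedure2, 3: run_procedure3,
            4: run_procedure4}


def run_procedure(
    obs: VirtualObserver, cfg: ProcedureConfig, rng: np.random.Generator,
    **kwargs,
) -> RunResult:
    """Dispatch to the runner for ``cfg.procedure_id``."""
    return _RUNNERS[cfg.procedure_id](obs, cfg, rng, **kwargs)
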