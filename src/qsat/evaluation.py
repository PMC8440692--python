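"""Accuracy and precision metrics over replicated simulation runs.

Conventions: J replications indexed j, K evaluation time points indexed k,
checkpoints indexed i.  All metrics ignore replications whose fit failed
(NaN estimates) and record the count actually used.

* parameter bias — mean absolute error of an estimate over replications.
* function average absolute bias — per time point, the absolute value of the
  replication-*summed* signed error, summed over time points and divided by
  J*K.  Signed errors may cancel across replications inside the absolute
  value; the stricter per-replication mean absolute error is also provided
  as ``function_mae``.
* function SD — the per-time-point SD of curve values across replications,
  averaged over time points ("averaged standard deviation over SOAs"); this
  is the headline precision measure.  A pooled variant (single RMS over all
  (j, k) cells, ``function_sd_pooled``) is computed alongside; it weights
  heterogeneous per-time variances differently (near-chance time points have
  essentially zero variance, so pooling yields a larger value than
  averaging the SDs).
* trials-to-precision — the trial count at which the SD trajectory falls
  below a threshold for good, with linear interpolation between checkpoints.
  Bayesian trajectories start near zero spread (every replication shares the
  same prior) and rise before falling, so the crossing is taken *downward*:
  the interpolated crossing after the last checkpoint above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .procedures import DEFAULT_EVAL_TIMES, RunResult
from .sat_model import SATParams, TaskSpec, prob_correct

__all__ = [
    "EvalConfig",
    "EvalSummary",
    "NOT_REACHED",
    "param_bias",
    "function_bias",
    "function_mae",
    "function_sd",
    "function_sd_pooled",
    "trials_to_precision",
    "summarize_runs",
    "summary_to_frame",
]

#: sentinel for a precision threshold the trajectory never reaches
NOT_REACHED = float("inf")


@dataclass(frozen=True)
class EvalConfig:
    eval_times: tuple[float, ...] = DEFAULT_EVAL_TIMES
    precision_threshold: float = 0.02
    hwci_level: float = 0.682
    n_reps: int = 200

    def __post_init__(self) -> None:
        if not self.eval_times:
            raise ValueError("eval_times must be non-empty")
        if not self.precision_threshold > 0:
            raise ValueError("precision_threshold must be positive")


@dataclass
class EvalSummary:
    """Checkpointed metrics aggregated over J replications of one condition."""

    checkpoints: np.ndarray            # (C,)
    param_bias: np.ndarray             # (C, 3)
    param_sd: np.ndarray               # (C, 3)
    function_bias: np.ndarray          # (C,)  signed-cancelling form
    function_mae: np.ndarray           # (C,)  per-replication |error| form
    function_sd: np.ndarray            # (C,)  averaged per-time SD
    function_sd_pooled: np.ndarray     # (C,)  pooled RMS variant
    mean_hwci: np.ndarray | None       # (C, 3) Bayesian procedures only
    mean_curve_hwci: np.ndarray | None  # (C,)
    n_used: np.ndarray                 # (C,) replications with a valid fit
    trials_to_precision: float = field(default=NOT_REACHED)
    n_reps: int = 0
    n_times: int = 0


def param_bias(estimates, truth: float) -> float:
    """Mean absolute error of per-replication estimates against the truth."""
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    return float(np.abs(est - truth).mean())


def function_bias(curves, truth_curve) -> float:
    """Average absolute bias of estimated curves (signed errors cancel).

    ``curves`` is (J, K); per time point the signed errors are summed over
    replications, the absolute value taken, then summed over time points and
    divided by J*K — i.e. the mean over k of |mean over j of error|.
    """
    curves = np.asarray(curves, dtype=float)
    err = curves - np.asarray(truth_curve, dtype=float)[None, :]
    return float(np.abs(np.nanmean(err, axis=0)).mean())


def function_mae(curves, truth_curve) -> float:
    """Mean absolute error over all (replication, time) cells."""
    curves = np.asarray(curves, dtype=float)
    err = curves - np.asarray(truth_curve, dtype=float)[None, :]
    return float(np.nanmean(np.abs(err)))


def function_sd(curves) -> float:
    """Per-time replication SDs averaged over time points."""
    curves = np.asarray(curves, dtype=float)
    dev = curves - np.nanmean(curves, axis=0, keepdims=True)
    return float(np.sqrt(np.nanmean(dev ** 2, axis=0)).mean())


def function_sd_pooled(curves) -> float:
    """Pooled RMS deviation over all (replication, time) cells."""
    curves = np.asarray(curves, dtype=float)
    dev = curves - np.nanmean(curves, axis=0, keepdims=True)
    return float(np.sqrt(np.nanmean(dev ** 2)))


def trials_to_precision(
    checkpoints, sd_trajectory, threshold: float = 0.02
) -> float:
    """Trial count at which the SD trajectory settles below ``threshold``.

    Returns the linearly interpolated downward crossing after the last
    checkpoint above threshold.  If the trajectory never exceeds the
    threshold, the first checkpoint is returned; if it never falls below it
    (or ends above it), :data:`NOT_REACHED`.
    """
    cps = np.asarray(checkpoints, dtype=float)
    sd = np.asarray(sd_trajectory, dtype=float)
    ok = np.isfinite(sd)
    cps, sd = cps[ok], sd[ok]
    if sd.size == 0:
        return NOT_REACHED
    above = np.nonzero(sd > threshold)[0]
    if above.size == 0:
        return float(cps[0])
    i = above[-1]
    if i == sd.size - 1:
        return NOT_REACHED
    # interpolate between the last point above and the next point below
    t = (sd[i] - threshold) / (sd[i] - sd[i + 1])
    return float(cps[i] + t * (cps[i + 1] - cps[i]))


def summarize_runs(
    runs: list[RunResult],
    truth: SATParams,
    task: TaskSpec,
    cfg: EvalConfig | None = None,
) -> EvalSummary:
    """Aggregate replicated runs of one observer x procedure condition."""
    cfg = EvalConfig() if cfg is None else cfg
    if not runs:
        raise ValueError("no runs to summarize")
    cps = runs[0].checkpoints
    times = runs[0].eval_times
    est = np.stack([r.estimates for r in runs])   # (J, C, 3)
    curves = np.stack([r.curves for r in runs])   # (J, C, K)
    truth_vec = truth.as_array()
    truth_curve = np.asarray(prob_correct(truth, task, times))
    C = cps.size
    pb = np.full((C, 3), np.nan)
    psd = np.full((C, 3), np.nan)
    fb = np.full(C, np.nan)
    fmae = np.full(C, np.nan)
    fsd = np.full(C, np.nan)
    fsdp = np.full(C, np.nan)
    n_used = np.zeros(C, dtype=int)
    for i in range(C):
        valid = np.isfinite(est[:, i, :]).all(axis=1)
        n_used[i] = int(valid.sum())
        if not n_used[i]:
            continue
        e = est[valid, i, :]
        pb[i] = np.abs(e - truth_vec[None, :]).mean(axis=0)
        psd[i] = e.std(axis=0)
        c = curves[valid, i, :]
        fb[i] = function_bias(c, truth_curve)
        fmae[i] = function_mae(c, truth_curve)
        fsd[i] = function_sd(c)
        fsdp[i] = function_sd_pooled(c)
    if runs[0].hwcis is not None:
        mh = np.stack([r.hwcis for r in runs]).mean(axis=0)
        mch = np.stack([r.curve_hwcis for r in runs]).mean(axis=(0, 2))
    else:
        mh = mch = None
    ttp = trials_to_precision(cps, fsd, cfg.precision_threshold)
    return EvalSummary(
        checkpoints=cps, param_bias=pb, param_sd=psd,
        function_bias=fb, function_mae=fmae, function_sd=fsd,
        function_sd_pooled=fsdp,
        mean_hwci=mh, mean_curve_hwci=mch, n_used=n_used,
        trials_to_precision=ttp, n_reps=len(runs), n_times=times.size,
    )


def summary_to_frame(
    summary: EvalSummary, procedure: int, observer: int
) -> pd.DataFrame:
    """Tidy (procedure, observer, checkpoint, metric, value, J, K) rows."""
    rows = []
    names = ("lam", "gam", "delta")
    for i, cp in enumerate(summary.checkpoints):
        for p, name in enumerate(names):
            rows.append((int(cp), f"bias_{name}", summary.param_bias[i, p]))
            rows.append((int(cp), f"sd_{name}", summary.param_sd[i, p]))
            if summary.mean_hwci is not None:
                rows.append((int(cp), f"hwci_{name}", summary.mean_hwci[i, p]))
        rows.append((int(cp), "function_bias", summary.function_bias[i]))
        rows.append((int(cp), "function_mae", summary.function_mae[i]))
        rows.append((int(cp), "function_sd", summary.function_sd[i]))
        rows.append((int(cp), "function_sd_pooled", summary.function_sd_pooled[i]))
        if summary.mean_curve_hwci is not None:
            rows.append((int(cp), "function_hwci", summary.mean_curve_hwci[i]))
    df = pd.DataFrame(rows, columns=["checkpoint", "metric", "value"])
    df.insert(0, "observer", observer)
    df.insert(0, "procedure", procedure)
    df["J"] = summary.n_reps
    df["K"] = summary.n_times
    return df
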