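"""Configuration, orchestration and reproducibility layer.

An :class:`ExperimentConfig` (usually loaded from YAML) names the virtual
observers, the procedures to run, the parameter grid, stimulus space and
evaluation settings.  :func:`run_experiment` executes every observer x
procedure condition for ``n_reps`` replications with per-replication seeds
derived deterministically from the master seed via
``numpy.random.SeedSequence([master_seed, observer_id, procedure_id, rep])``,
writes per-run checkpoint CSVs, a tidy metrics CSV and a JSON summary, and
records a manifest (config hash + seeds) sufficient for bit-identical
replay.

:func:`fit_data` fits previously collected trial data (CSV with columns
soa, rt, correct) offline with the Procedure 1, 2 or 3 analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes_engine import (
    ParameterGrid,
    estimate_params,
    hwci,
    init_prior,
    marginal,
    reconstruct_function,
    update,
)
from .adaptive_selection import BlockDesign, InformationGainPlanner, StimulusSpace
from .evaluation import EvalConfig, EvalSummary, summarize_runs, summary_to_frame
from .observer_sim import ExGaussParams, VirtualObserver, read_trials_csv
from .procedures import (
    ProcedureConfig,
    RunResult,
    mle_fit,
    run_procedure,
)
from .sat_model import SATParams, TaskSpec, prob_correct

__all__ = [
    "ExperimentConfig",
    "load_config",
    "study_config",
    "derive_seed",
    "run_condition",
    "run_experiment",
    "fit_data",
]


@dataclass(frozen=True)
class ExperimentConfig:
    observers: dict[int, VirtualObserver]
    procedures: tuple[ProcedureConfig, ...]
    grid: ParameterGrid = field(default_factory=ParameterGrid)
    space: StimulusSpace = field(default_factory=StimulusSpace)
    eval: EvalConfig = field(default_factory=EvalConfig)
    n_reps: int = 200
    master_seed: int = 0
    output_dir: str = "qsat_out"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.observers:
            raise ValueError("at least one observer is required")
        if not self.procedures:
            raise ValueError("at least one procedure is required")


def _cfg_get(d: dict, key: str, path: str, default=None, required=False):
    if key not in d:
        if required:
            raise ValueError(f"config field missing: {path}.{key}")
        return default
    return d[key]


def _parse_axis(spec, path: str) -> np.ndarray:
    try:
        lo, hi, n = spec
        return np.linspace(float(lo), float(hi), int(n))
    except Exception as exc:
        raise ValueError(f"config field {path} must be [low, high, n]") from exc


def load_config(source) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file path or a parsed dict."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    task_raw = raw.get("task", {})
    task = TaskSpec(
        chance=float(task_raw.get("chance", 0.5)),
        window=float(task_raw.get("window", 0.2)),
    )
    observers = {}
    for i, ob in enumerate(_cfg_get(raw, "observers", "", required=True)):
        path = f"observers[{i}]"
        sat = SATParams(
            lam=float(_cfg_get(ob, "lam", path, required=True)),
            gam=float(_cfg_get(ob, "gam", path, required=True)),
            delta=float(_cfg_get(ob, "delta", path, required=True)),
        )
        rt_raw = ob.get("rt", {})
        rtdist = ExGaussParams(
            mu=float(rt_raw.get("mu", 0.3)),
            sigma=float(rt_raw.get("sigma", 0.06)),
            tau=float(rt_raw.get("tau", 0.08)),
        )
        observers[int(ob.get("id", i + 1))] = VirtualObserver(sat, rtdist, task)
    procedures = tuple(
        ProcedureConfig(**pc) for pc in _cfg_get(raw, "procedures", "", required=True)
    )
    grid_raw = raw.get("grid", {})
    grid = ParameterGrid(
        lam_axis=_parse_axis(grid_raw.get("lam", [0.4, 0.5, 21]), "grid.lam"),
        gam_axis=_parse_axis(grid_raw.get("gam", [1, 30, 30]), "grid.gam"),
        del_axis=_parse_axis(grid_raw.get("delta", [0.02, 0.5, 25]), "grid.delta"),
    )
    sp_raw = raw.get("stimulus_space", {})
    space = StimulusSpace(_parse_axis(
        [sp_raw.get("min", 0.0), sp_raw.get("max", 1.2), sp_raw.get("n", 49)],
        "stimulus_space"))
    ev_raw = raw.get("eval", {})
    ev = EvalConfig(
        eval_times=tuple(ev_raw.get(
            "eval_times", (0.06, 0.09, 0.12, 0.24, 0.36, 0.48, 0.60, 1.20))),
        precision_threshold=float(ev_raw.get("precision_threshold", 0.02)),
        hwci_level=float(ev_raw.get("hwci_level", 0.682)),
        n_reps=int(raw.get("n_reps", 200)),
    )
    return ExperimentConfig(
        observers=observers,
        procedures=procedures,
        grid=grid,
        space=space,
        eval=ev,
        n_reps=int(raw.get("n_reps", 200)),
        master_seed=int(raw.get("master_seed", 0)),
        output_dir=str(raw.get("output_dir", "qsat_out")),
    )


def study_config() -> ExperimentConfig:
    """The bundled default configuration (four observers x four procedures)."""
    ref = resources.files("qsat").joinpath("configs/study.yaml")
    return load_config(yaml.safe_load(ref.read_text()))


def derive_seed(master_seed: int, observer_id: int, procedure_id: int,
                rep: int) -> np.random.SeedSequence:
    """Deterministic per-replication seed stream."""
    return np.random.SeedSequence([master_seed, observer_id, procedure_id, rep])


def run_condition(
    obs: VirtualObserver,
    pcfg: ProcedureConfig,
    n_reps: int,
    master_seed: int,
    observer_id: int = 0,
    grid: ParameterGrid | None = None,
    space: StimulusSpace | None = None,
) -> list[RunResult]:
    """Run ``n_reps`` seeded replications of one observer x procedure pair.

    For Procedure 4 the information-gain planner is built once and shared
    across replications (it depends only on grid, task, space and design).
    """
    grid = ParameterGrid() if grid is None else grid
    space = StimulusSpace() if space is None else space
    kwargs = {}
    if pcfg.procedure_id == 4:
        design = BlockDesign(n_trials=pcfg.block_length, window=obs.task.window)
        kwargs["planner"] = InformationGainPlanner(grid, obs.task, space, design)
        kwargs["grid"] = grid
        kwargs["space"] = space
    elif pcfg.procedure_id == 3:
        kwargs["grid"] = grid
    runs = []
    for rep in range(n_reps):
        rng = np.random.default_rng(
            derive_seed(master_seed, observer_id, pcfg.procedure_id, rep))
        runs.append(run_procedure(obs, pcfg, rng, **kwargs))
    return runs


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = repr(cfg).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_run_csv(run: RunResult, path: Path) -> None:
    df = pd.DataFrame({
        "checkpoint": run.checkpoints,
        "lam": run.estimates[:, 0],
        "gam": run.estimates[:, 1],
        "delta": run.estimates[:, 2],
        "identifiable": run.identifiable.astype(int),
    })
    if run.hwcis is not None:
        for p, name in enumerate(("lam", "gam", "delta")):
            df[f"hwci_{name}"] = run.hwcis[:, p]
    for k, t in enumerate(run.eval_times):
        df[f"pc_{t:g}"] = run.curves[:, k]
    df.to_csv(path, index=False)


def run_experiment(cfg: ExperimentConfig) -> dict[tuple[int, int], EvalSummary]:
    """Execute all conditions; write results and a replay manifest.

    Returns ``{(observer_id, procedure_id): EvalSummary}``.  Output layout:
    ``runs/obs{o}_proc{p}_rep{r}.csv`` per-run checkpoint trajectories,
    ``metrics.csv`` tidy aggregated metrics, ``summary.json`` headline
    numbers, ``manifest.json`` config hash and seeds.
    """
    out = Path(cfg.output_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    summaries: dict[tuple[int, int], EvalSummary] = {}
    frames = []
    headline: dict[str, dict] = {}
    for oid, obs in cfg.observers.items():
        for pcfg in cfg.procedures:
            runs = run_condition(
                obs, pcfg, cfg.n_reps, cfg.master_seed,
                observer_id=oid, grid=cfg.grid, space=cfg.space)
            for r, run in enumerate(runs):
                _write_run_csv(
                    run, out / "runs" / f"obs{oid}_proc{pcfg.procedure_id}_rep{r}.csv")
            summ = summarize_runs(runs, obs.sat, obs.task, cfg.eval)
            summaries[(oid, pcfg.procedure_id)] = summ
            frames.append(summary_to_frame(summ, pcfg.procedure_id, oid))
            headline[f"obs{oid}_proc{pcfg.procedure_id}"] = {
                "trials_to_precision": summ.trials_to_precision,
                "final_function_bias": float(summ.function_bias[-1]),
                "final_function_sd": float(summ.function_sd[-1]),
            }
    pd.concat(frames, ignore_index=True).to_csv(out / "metrics.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(headline, fh, indent=2, default=float)
    manifest = {
        "config_hash": _config_hash(cfg),
        "master_seed": cfg.master_seed,
        "n_reps": cfg.n_reps,
        "seed_scheme": "SeedSequence([master_seed, observer_id, procedure_id, rep])",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summaries


def fit_data(
    path,
    method: int,
    task: TaskSpec | None = None,
    grid: ParameterGrid | None = None,
    eval_times=(0.06, 0.09, 0.12, 0.24, 0.36, 0.48, 0.60, 1.20),
    rng: np.random.Generator | None = None,
    window_policy: str = "warn",
) -> dict:
    """Fit recorded trial data offline with the Procedure 1/2/3 analysis.

    ``window_policy`` governs RTs outside [soa, soa + window]: ``"warn"``
    keeps them, ``"reject"`` drops them.  Returns a dict with the parameter
    estimates, the reconstructed curve at ``eval_times`` and, for the
    Bayesian method, marginal HWCIs.
    """
    if method not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")
    task = TaskSpec() if task is None else task
    rng = np.random.default_rng(0) if rng is None else rng
    df = read_trials_csv(path)
    outside = (df["rt"] < df["soa"]) | (df["rt"] > df["soa"] + task.window)
    n_outside = int(outside.sum())
    if n_outside and window_policy == "reject":
        df = df[~outside]
        if df.empty:
            raise ValueError("all trials rejected by the window policy")
    times = np.asarray(eval_times, dtype=float)
    report: dict = {"n_trials": int(len(df)), "n_outside_window": n_outside,
                    "method": method}
    if method in (1, 2):
        if method == 1:
            agg = df.groupby("soa").agg(
                mean_rt=("rt", "mean"), k=("correct", "sum"),
                n=("correct", "size"))
            fit = mle_fit(agg["mean_rt"], agg["k"], agg["n"], task=task, rng=rng)
        else:
            fit = mle_fit(df["rt"], df["correct"], task=task, rng=rng)
        if not fit.identifiable:
            raise ValueError("data insufficient to identify 3 SAT parameters")
        report["params"] = fit.params
        report["curve"] = np.asarray(prob_correct(fit.params, task, times))
        report["converged"] = fit.converged
        return report
    grid = ParameterGrid() if grid is None else grid
    post = init_prior(grid)
    for rt, c in zip(df["rt"].to_numpy(), df["correct"].to_numpy()):
        post = update(post, task, float(rt), int(c))
    report["params"] = estimate_params(post)
    report["hwci"] = {
        name: hwci(marginal(post, name), grid.axis(name)).half_width
        for name in ("lam", "gam", "delta")
    }
    curve, spread = reconstruct_function(post, task, times, 1000, rng)
    report["curve"] = curve
    report["curve_hwci"] = spread
    report["posterior"] = post
    return report
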