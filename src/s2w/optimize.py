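"""Shooting-based optimization of the controller's free parameters.

Candidates are encoded as flat vectors (one entry per free parameter, in the
registry order of :class:`s2w.control.ControllerConfig`), evaluated by
decode -> simulate -> score, and searched with CMA-ES (population 10 by
default).  Multiple restarts share the initial mean but use distinct seeds;
a warm start loads a saved parameter file as the initial mean.

Internally the search runs in box-normalized coordinates (each parameter
mapped to [0, 1] by its bounds) with sigma0 = 0.1, i.e. an initial step of
10% of each parameter's range.
"""

from __future__ import annotations

import csv
import fnmatch
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cmaes import CMAResult, minimize
from .control import ControllerConfig, default_config
from .engine import SimulationEngine
from .model import build_model
from .objectives import evaluate
from .scenario import (ScenarioConfig, chair_position, measure_config,
                       seated_posture)


@dataclass
class ParameterVector:
    names: list
    values: np.ndarray
    stds: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __len__(self):
        return len(self.names)


def encode(config: ControllerConfig) -> ParameterVector:
    lo, hi = config.bounds()
    return ParameterVector(names=config.names(), values=config.values(),
                           stds=config.stds(), lower=lo, upper=hi)


def decode(vector, template: ControllerConfig) -> ControllerConfig:
    """Write a value vector into a copy of the template config (clipped to
    bounds)."""
    cfg = ControllerConfig(sharing=template.sharing,
                           constants=template.constants)
    if isinstance(vector, ParameterVector):
        vector = vector.values
    cfg.set_values(vector)
    return cfg


#: desk-scale search configuration: the parameter blocks explored by the
#: scaled-down smoke optimization (drives, vestibular feedback, trunk
#: servos, gait feedback gains, phase timing) and per-block relative step
#: sizes (servo and vestibular gains destabilize rollouts at large steps).
DESK_FREE_PARAMS = [
    "p1.*C0", "p1.*vest.*", "p1.theta0", "p1.lumbar.*", "p1.thoracic.*",
    "p2.*C0", "p2.*vest.*", "p2.theta0", "p2.lumbar.*", "p2.thoracic.*",
    "gait.*C0", "gait.*vest.*", "gait.*KF*", "gait.*KL*", "gait.*L0",
    "gait.*KA", "gait.lumbar.*", "gait.thoracic.*",
    "T1", "T2", "load_threshold",
]
DESK_SCALES = {
    "*.vest.KP": 0.25, "*.vest.KV": 0.15, "*.KP": 0.05, "*.KV": 0.04,
    "*.Q0": 0.5, "*theta0": 0.5, "T1": 0.3, "T2": 0.3,
}


@dataclass
class OptimizationConfig:
    popsize: int = 10
    generations: int = 100
    seed: int = 1
    n_runs: int = 1
    sigma0: float = 0.1            # in box-normalized coordinates
    warm_start: Optional[str] = None
    max_wall_time: Optional[float] = None   # s, soft cap per run
    free_params: Optional[list] = None      # glob patterns; None = all
    scales: Optional[dict] = None           # glob pattern -> relative step

    def __post_init__(self):
        if self.popsize < 2:
            raise ValueError("population size must be >= 2")


@dataclass
class OptimizationResult:
    best_config: ControllerConfig
    best_objective: float
    runs: list                      # CMAResult per parallel run
    best_run: int


class CandidateEvaluator:
    """decode -> simulate -> total objective for one scenario."""

    def __init__(self, engine: SimulationEngine, scenario: ScenarioConfig,
                 template: Optional[ControllerConfig] = None):
        self.engine = engine
        self.scenario = scenario
        self.template = template or default_config()
        self.posture = seated_posture(engine.model, scenario)
        self.q0 = self.posture.to_q()
        self.box_pos = chair_position(engine.model, scenario, self.posture)
        self.measures = measure_config(engine.model, scenario, self.posture)

    def __call__(self, values: np.ndarray) -> float:
        cfg = decode(values, self.template)
        try:
            traj = self.engine.rollout(
                self.q0, controller=cfg, box_pos=self.box_pos,
                t_max=self.scenario.max_time)
        except RuntimeError:
            return 1e6      # diverged candidate: worse than any fall
        rep = evaluate(traj, self.engine.model, self.measures)
        return rep.total

    def report(self, values: np.ndarray):
        cfg = decode(values, self.template)
        traj = self.engine.rollout(self.q0, controller=cfg,
                                   box_pos=self.box_pos,
                                   t_max=self.scenario.max_time)
        return traj, evaluate(traj, self.engine.model, self.measures), cfg


def optimize(opt: OptimizationConfig, scenario: ScenarioConfig,
             engine: Optional[SimulationEngine] = None,
             template: Optional[ControllerConfig] = None,
             log_dir=None, verbose: bool = False) -> OptimizationResult:
    """CMA-ES policy search; returns the best candidate across runs."""
    if engine is None:
        engine = SimulationEngine(build_model())
    template = template or default_config()
    if opt.warm_start:
        template.load(opt.warm_start)
    evaluator = CandidateEvaluator(engine, scenario, template)

    vec = encode(template)
    span = vec.upper - vec.lower
    x0n_full = (vec.values - vec.lower) / span
    if opt.free_params:
        free = np.array([any(fnmatch.fnmatch(n, pat)
                             for pat in opt.free_params)
                         for n in vec.names])
        if not free.any():
            raise ValueError("free_params matched no parameters")
    else:
        free = np.ones(len(vec), dtype=bool)
    x0n = x0n_full[free]

    def unbox(xn_sub):
        xn = x0n_full.copy()
        xn[free] = np.clip(xn_sub, 0.0, 1.0)
        return vec.lower + xn * span

    f0 = evaluator(unbox(x0n))
    runs = []
    for run in range(opt.n_runs):
        seed = opt.seed + run
        t_start = time.time()
        stop = {"flag": False}

        def cb(gen, es, best_x, best_f, _t0=t_start, _stop=stop):
            if verbose and gen % 10 == 0:
                print(f"  run seed={seed} gen={gen} best={best_f:.4f} "
                      f"sigma={es.sigma:.3f}", flush=True)
            if opt.max_wall_time and time.time() - _t0 > opt.max_wall_time:
                _stop["flag"] = True
                return True             # stop this run early

        ndim = int(free.sum())
        scales = None
        if opt.scales:
            scales = np.ones(ndim)
            sub_names = [n for n, f in zip(vec.names, free) if f]
            for i, n in enumerate(sub_names):
                for pat, sc in opt.scales.items():
                    if fnmatch.fnmatch(n, pat):
                        scales[i] = sc
        res = minimize(lambda xn: evaluator(unbox(xn)), x0n, opt.sigma0,
                       popsize=opt.popsize, generations=opt.generations,
                       seed=seed, bounds=(np.zeros(ndim), np.ones(ndim)),
                       callback=cb, f0=f0, scales=scales)
        runs.append(res)
        if log_dir is not None:
            _write_history(Path(log_dir) / f"history_seed{seed}.csv", res)

    best_run = int(np.argmin([r.best_f for r in runs]))
    best = runs[best_run]
    best_cfg = decode(unbox(best.best_x), template)
    return OptimizationResult(best_config=best_cfg,
                              best_objective=best.best_f,
                              runs=runs, best_run=best_run)


def _write_history(path, res: CMAResult):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["gen", "best", "median", "sigma",
                                           "best_ever", "seed"])
        w.writeheader()
        for rec in res.history:
            w.writerow({**rec, "seed": res.seed})
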