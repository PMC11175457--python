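"""Covariance matrix adaptation evolution strategy ((mu/mu_w, lambda)).

Self-contained implementation of the standard algorithm (rank-one and
rank-mu covariance updates, cumulative step-size adaptation) used for
shooting-based policy search.  Minimizes; deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np


@dataclass
class CMAResult:
    best_x: np.ndarray
    best_f: float
    history: list          # per generation: dict(gen, best, median, sigma)
    evaluations: int
    seed: int


class CMAES:
    """Ask/tell CMA-ES minimizer on R^n."""

    def __init__(self, x0, sigma0: float, popsize: Optional[int] = None,
                 seed: int = 0, bounds=None, scales=None):
        self.mean = np.array(x0, dtype=float)
        n = len(self.mean)
        self.n = n
        self.sigma = float(sigma0)
        self.lam = popsize or 4 + int(3 * math.log(n))
        if self.lam < 2:
            raise ValueError("population size must be >= 2")
        self.mu = self.lam // 2
        w = math.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / float(self.weights @ self.weights)

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = 1 + 2 * max(0.0, math.sqrt((self.mueff - 1) / (n + 1)) - 1) \
            + self.cs
        self.chin = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        if scales is None:
            scales = np.ones(n)
        scales = np.asarray(scales, dtype=float)
        self.C = np.diag(scales ** 2)
        self.B = np.eye(n)
        self.D = scales.copy()
        self.invsqrtC = np.diag(1.0 / scales)
        self.eigen_stale = 0
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.bounds = bounds
        self.generation = 0

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T
        xs = self.mean + self.sigma * y
        if self.bounds is not None:
            lo, hi = self.bounds
            xs = np.clip(xs, lo, hi)
        self._last = xs
        return xs

    def tell(self, xs: np.ndarray, fs):
        fs = np.asarray(fs, dtype=float)
        order = np.argsort(fs)
        xsel = xs[order[:self.mu]]
        old_mean = self.mean
        self.mean = self.weights @ xsel
        yw = (self.mean - old_mean) / self.sigma

        self.ps = (1 - self.cs) * self.ps + \
            math.sqrt(self.cs * (2 - self.cs) * self.mueff) * \
            (self.invsqrtC @ yw)
        hsig = (np.linalg.norm(self.ps)
                / math.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
                / self.chin) < 1.4 + 2 / (self.n + 1)
        self.pc = (1 - self.cc) * self.pc + \
            (math.sqrt(self.cc * (2 - self.cc) * self.mueff) * yw
             if hsig else 0.0)

        artmp = (xsel - old_mean) / self.sigma
        rank_mu = artmp.T @ (self.weights[:, None] * artmp)
        self.C = (1 - self.c1 - self.cmu) * self.C \
            + self.c1 * (np.outer(self.pc, self.pc)
                         + (0.0 if hsig else self.cc * (2 - self.cc)) * self.C) \
            + self.cmu * rank_mu
        self.sigma *= math.exp((self.cs / self.damps)
                               * (np.linalg.norm(self.ps) / self.chin - 1))

        self.generation += 1
        self.eigen_stale += 1
        if self.eigen_stale > max(1, int(1 / ((self.c1 + self.cmu) * self.n * 10))):
            self._update_eigen()

    def _update_eigen(self):
        self.eigen_stale = 0
        self.C = (self.C + self.C.T) / 2
        d, B = np.linalg.eigh(self.C)
        d = np.maximum(d, 1e-20)
        self.B = B
        self.D = np.sqrt(d)
        self.invsqrtC = B @ np.diag(1.0 / self.D) @ B.T


def minimize(func: Callable, x0, sigma0: float, *, popsize: int = 10,
             generations: int = 100, seed: int = 0, bounds=None,
             callback: Optional[Callable] = None,
             f0: Optional[float] = None, scales=None) -> CMAResult:
    """Run CMA-ES; returns the best-ever candidate and a per-generation log.

    The generation-0 record carries the objective of the initial mean so a
    warm start is visible in the history.
    """
    es = CMAES(x0, sigma0, popsize=popsize, seed=seed, bounds=bounds,
               scales=scales)
    best_x = np.array(x0, dtype=float)
    best_f = func(best_x) if f0 is None else float(f0)
    history = [dict(gen=0, best=best_f, median=best_f, sigma=es.sigma,
                    best_ever=best_f)]
    nevals = 1
    for gen in range(1, generations + 1):
        xs = es.ask()
        fs = np.array([func(x) for x in xs])
        nevals += len(fs)
        es.tell(xs, fs)
        i = int(np.argmin(fs))
        if fs[i] < best_f:
            best_f = float(fs[i])
            best_x = xs[i].copy()
        rec = dict(gen=gen, best=float(fs[i]), median=float(np.median(fs)),
                   sigma=es.sigma, best_ever=best_f)
        history.append(rec)
        if callback is not None:
            if callback(gen, es, best_x, best_f):
                break
    return CMAResult(best_x=best_x, best_f=best_f, history=history,
                     evaluations=nevals, seed=seed)
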