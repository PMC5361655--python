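"""Compact covariance-matrix-adaptation evolution strategy.

Standard (mu/mu_w, lambda)-CMA-ES with rank-one and rank-mu covariance
updates and cumulative step-size adaptation, operating on a box-normalized
parameter space (candidates are clipped to [0, 1] before evaluation).
Deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CMAES", "minimize"]


class CMAES:
    """Ask/tell CMA-ES over the unit box.

    Parameters
    ----------
    x0 : array
        Initial mean in [0, 1]^n.
    sigma0 : float
        Initial step size.
    popsize : int, optional
        Offspring per generation (default ``4 + floor(3 ln n)``).
    seed : int
        RNG seed; the full run is reproducible.
    """

    def __init__(self, x0, sigma0=0.2, popsize=None, seed=0):
        self.n = len(x0)
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.rng = np.random.default_rng(seed)
        n = self.n
        self.lam = popsize or (4 + int(3 * np.log(n)))
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.w = w / w.sum()
        self.mueff = 1.0 / np.sum(self.w ** 2)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))
        self.gen = 0
        self._eig_stale = 0

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T
        x = self.mean + self.sigma * y
        return np.clip(x, 0.0, 1.0)

    def tell(self, x: np.ndarray, f: np.ndarray):
        order = np.argsort(f)
        xsel = x[order[: self.mu]]
        old_mean = self.mean.copy()
        self.mean = self.w @ xsel
        y = (self.mean - old_mean) / self.sigma
        Cinv_y = self.B @ ((self.B.T @ y) / self.D)
        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff) * Cinv_y
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * (self.gen + 1)))
                / self.chiN) < 1.4 + 2 / (self.n + 1)
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff) * y
        artmp = (xsel - old_mean) / self.sigma
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (not hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * (artmp.T * self.w) @ artmp)
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        self.sigma = min(self.sigma, 1.0)
        self.gen += 1
        self._eig_stale += 1
        if self._eig_stale >= max(1, int(1 / ((self.c1 + self.cmu) * self.n * 10))):
            self._eig_stale = 0
            self.C = 0.5 * (self.C + self.C.T)
            d2, self.B = np.linalg.eigh(self.C)
            self.D = np.sqrt(np.maximum(d2, 1e-20))


def minimize(fun, x0, sigma0=0.2, budget=1000, popsize=None, seed=0,
             callback=None):
    """Minimize ``fun`` over [0, 1]^n with at most ``budget`` evaluations.

    Always evaluates ``x0`` first so a budget of 1 returns the initial
    candidate.  Returns ``(x_best, f_best, n_evals)``.
    """
    x0 = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    f_best = fun(x0)
    x_best = x0.copy()
    evals = 1
    es = CMAES(x0, sigma0, popsize=popsize, seed=seed)
    while evals < budget:
        X = es.ask()
        k = min(len(X), budget - evals)
        F = np.empty(len(X))
        for i in range(len(X)):
            if i < k:
                F[i] = fun(X[i])
            else:
                F[i] = np.inf
        evals += k
        for i in range(k):
            if F[i] < f_best:
                f_best = F[i]
                x_best = X[i].copy()
        es.tell(X, F)
        if callback is not None:
            callback(es, x_best, f_best, evals)
    return x_best, f_best, evals
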