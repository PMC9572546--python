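"""Gaussian-process Bayesian optimization over small hyperparameter spaces.

A standard sequential model-based optimizer: evaluate a seeded random
initial design, fit a Matern-5/2 GP with a white-noise term to the observed
objective, and pick each next point by maximizing expected improvement over
a seeded candidate cloud. Integer and log-scaled dimensions are handled by
transforming the search space to the unit cube. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class Dimension:
    """One search dimension: continuous, log-continuous or integer."""

    name: str
    low: float
    high: float
    kind: str = "float"  # float | log | int

    def __post_init__(self) -> None:
        if self.kind not in ("float", "log", "int"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.kind == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log dimension needs positive bounds")

    def from_unit(self, u: float) -> float | int:
        u = float(np.clip(u, 0.0, 1.0))
        if self.kind == "log":
            value = self.low * (self.high / self.low) ** u
        else:
            value = self.low + u * (self.high - self.low)
        if self.kind == "int":
            return int(np.clip(round(value), self.low, self.high))
        return float(value)

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass
class OptimizationResult:
    best_params: dict[str, float | int]
    best_value: float
    trace: list[dict] = field(default_factory=list)  # per-iteration params + objective


def maximize(objective: Callable[[dict], float],
             dimensions: Sequence[Dimension],
             budget: int = 50,
             n_initial: int = 10,
             seed: int = 0,
             n_candidates: int = 512) -> OptimizationResult:
    """Maximize ``objective`` over the box defined by ``dimensions``.

    budget counts total objective evaluations (initial design included) and
    must be at least the initial design size.
    """
    if budget < n_initial:
        raise ValueError(f"budget {budget} is smaller than the initial design ({n_initial})")
    dims = list(dimensions)
    rng = np.random.default_rng(seed)

    unit_points: list[np.ndarray] = []
    values: list[float] = []
    trace: list[dict] = []

    def evaluate(u: np.ndarray) -> None:
        params = {d.name: d.from_unit(ui) for d, ui in zip(dims, u)}
        y = float(objective(params))
        unit_points.append(u)
        values.append(y)
        trace.append({"iteration": len(values), **params, "objective": y})

    for _ in range(n_initial):
        evaluate(rng.uniform(size=len(dims)))

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=np.full(len(dims), 0.3),
                       length_scale_bounds=(1e-2, 1e2), nu=2.5)
              + WhiteKernel(1e-4, (1e-8, 1e-1)))

    for _ in range(budget - n_initial):
        X = np.vstack(unit_points)
        y = np.asarray(values)
        y_mean, y_std = y.mean(), y.std()
        y_std = y_std if y_std > 0 else 1.0
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                      alpha=1e-10, random_state=seed)
        gp.fit(X, (y - y_mean) / y_std)
        best = (y.max() - y_mean) / y_std

        candidates = rng.uniform(size=(n_candidates, len(dims)))
        mu, sigma = gp.predict(candidates, return_std=True)
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best) / sigma
        ei = sigma * (z * norm.cdf(z) + norm.pdf(z))
        evaluate(candidates[int(np.argmax(ei))])

    i_best = int(np.argmax(values))
    best_params = {d.name: d.from_unit(ui) for d, ui in zip(dims, unit_points[i_best])}
    return OptimizationResult(best_params=best_params,
                              best_value=float(values[i_best]),
                              trace=trace)
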