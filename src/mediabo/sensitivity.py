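"""Post-hoc model interrogation.

Two complementary views of what a fitted growth model believes:

* **Optimum distribution** — repeated single-start bounded ascents from
  random initial points, under either a pure max-growth objective or the
  cost-aware acquisition constrained to beat a reference medium's predicted
  growth. The spread of solutions across restarts shows which components the
  model pins down and which it leaves free.

* **Integrated directional variogram** — a VARS-style global sensitivity
  measure. For component k the directional variogram
  gamma_k(h) = 1/2 E[(f(x + h e_k) - f(x))^2] is estimated at a grid of lags
  up to a cap h_max and integrated by the trapezoid rule; larger integrals
  mean the output changes more along that coordinate. Values are on the
  squared output scale (scaling f by c scales every value by c^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .acquisition import MCSampleSet, ObjectiveSpec, alpha
from .gp import MISGPModel

__all__ = [
    "OptimRunSample",
    "VariogramResult",
    "optimum_distribution",
    "integrated_variogram",
    "model_mean_function",
]


@dataclass(frozen=True)
class OptimRunSample:
    """Solution of one randomized restart of the optimizer."""

    restart: int
    condition: str              # "max_growth" | "max_alpha_constrained"
    x: np.ndarray
    value: float


@dataclass(frozen=True)
class VariogramResult:
    """Per-component integrated variogram values and the importance ranking."""

    values: np.ndarray          # (p,), >= 0, squared-output units
    ranking: np.ndarray         # component indices, descending importance
    h_max: float
    n_samples: int

    def to_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        p = len(self.values)
        names = list(names) if names is not None else [f"x{k}" for k in range(p)]
        order = self.ranking
        return pd.DataFrame({
            "component": [names[k] for k in order],
            "value": self.values[order],
            "rank": np.arange(1, p + 1),
        })


def model_mean_function(model: MISGPModel) -> Callable[[np.ndarray], np.ndarray]:
    """High-fidelity posterior-mean field of a fitted model, vectorized."""
    return lambda X: model.posterior(np.atleast_2d(X), m=0).mu


# ---------------------------------------------------------------------------
# Optimum distribution
# ---------------------------------------------------------------------------

def optimum_distribution(model: MISGPModel, condition: str, restarts: int = 50,
                         seed: int = 0, cost_fn: Callable | None = None,
                         objective: ObjectiveSpec | None = None,
                         n_mc: int = 1000) -> list[OptimRunSample]:
    """Solutions of ``restarts`` independent randomized ascents.

    ``condition="max_growth"`` maximizes the posterior mean mu(x) alone.
    ``condition="max_alpha_constrained"`` maximizes the q = 1 constrained
    acquisition; the minimum-growth bound is ``objective.ymin`` (set it to
    the reference medium's predicted growth to ask for media that beat it).
    Each restart is a single L-BFGS-B ascent from its own uniform start, so
    the returned list is the distribution of local optima the model induces.
    """
    p = model.data.p
    rng = np.random.default_rng(seed)
    if condition == "max_growth":
        fun = model_mean_function(model)
        scalar = lambda x: float(fun(x[None, :])[0])
    elif condition == "max_alpha_constrained":
        if cost_fn is None or objective is None:
            raise ValueError("constrained condition needs cost_fn and objective")
        mc = MCSampleSet(n_mc, seed=seed)
        scalar = lambda x: alpha(x[None, :], model, objective, mc, cost_fn)
    else:
        raise ValueError(f"unknown condition {condition!r}")

    out = []
    bounds = [(0.0, 1.0)] * p
    for r in range(restarts):
        x0 = rng.uniform(0.0, 1.0, p)
        res = minimize(lambda v: -scalar(v), x0, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 100})
        out.append(OptimRunSample(restart=r, condition=condition,
                                  x=np.clip(res.x, 0, 1), value=-res.fun))
    return out


# ---------------------------------------------------------------------------
# Integrated variogram
# ---------------------------------------------------------------------------

def integrated_variogram(model_or_function, p: int | None = None,
                         h_max: float = 0.3, n_samples: int = 1000,
                         seed: int = 0, n_bins: int = 10) -> VariogramResult:
    """VARS-style per-component sensitivity of a field on the unit box.

    For each component k the directional variogram is estimated at ``n_bins``
    evenly spaced lags h_j = j * h_max / n_bins (j = 1..n_bins): random base
    points are drawn uniformly with x_k restricted to [0, 1 - h_j] so the
    shifted point stays inside the box, and
    gamma_k(h_j) = 1/2 mean[(f(x + h_j e_k) - f(x))^2] over n_samples/n_bins
    pairs per lag. The integral over [0, h_max] is taken by the trapezoid
    rule on the full lag grid including gamma_k(0) = 0.

    Accepts a fitted :class:`MISGPModel` (queried at its high-fidelity
    posterior mean) or any vectorized callable on (n, p) arrays (then ``p``
    is required).
    """
    if isinstance(model_or_function, MISGPModel):
        f = model_mean_function(model_or_function)
        p = model_or_function.data.p
    else:
        f = model_or_function
        if p is None:
            raise ValueError("p is required for a bare function")
    if not (0 < h_max <= 1):
        raise ValueError("h_max must be in (0, 1]")
    if n_samples < 100:
        raise ValueError("need at least 100 samples")
    rng = np.random.default_rng(seed)
    n_per = max(n_samples // n_bins, 1)
    lags = h_max * np.arange(1, n_bins + 1) / n_bins
    values = np.zeros(p)
    for k in range(p):
        gammas = np.zeros(n_bins)
        for j, h in enumerate(lags):
            X = rng.uniform(0.0, 1.0, size=(n_per, p))
            X[:, k] = rng.uniform(0.0, 1.0 - h, size=n_per)
            Xs = X.copy()
            Xs[:, k] += h
            diff = np.asarray(f(Xs), float) - np.asarray(f(X), float)
            gammas[j] = 0.5 * np.mean(diff**2)
        grid = np.concatenate([[0.0], lags])
        vals = np.concatenate([[0.0], gammas])
        values[k] = np.trapezoid(vals, grid)
    ranking = np.argsort(-values, kind="stable")
    return VariogramResult(values=values, ranking=ranking,
                           h_max=h_max, n_samples=n_samples)
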