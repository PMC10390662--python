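"""Synthetic multi-fidelity growth problems and a closed-loop benchmark.

Stands in for the wet lab: a smooth ground-truth growth surface g0 on the
unit box is the high-fidelity target (m = 0, unbiased, small noise); each
low-fidelity source m >= 1 reports g0 plus a smooth systematic bias field
delta_m and larger noise, mimicking cheap proxy assays that correlate with —
but do not equal — the expensive long-term growth readout. Cost is the same
linear model used for real media.

Presets
-------
``peaks2d``
    2-D sum of Gaussian bumps with one dominant optimum; linear cost
    (0.5, 0.3). The workhorse for closed-loop benchmarks.
``media26``
    26-D surface over the packaged media design space with 8 active
    dimensions (sparse importance, as real media screens show) and the
    packaged cost coefficients.
``linear-check``
    Linear g0 with zero bias, zero noise and zero cost — closed-form
    behavior for tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .acquisition import hypervolume
from .campaign import LoopConfig, _derive_seed, ingest_results, initialize_campaign, run_batch
from .design_space import (
    ComponentSpec,
    DesignSpace,
    cost_from_unit_batch,
    media26_design_space,
)
from .gp import Dataset

__all__ = [
    "SyntheticProblem",
    "SimObservation",
    "make_problem",
    "evaluate",
    "evaluate_batch",
    "closed_loop_benchmark",
    "DESK_SCALE_CONFIG",
]


@dataclass(frozen=True)
class SyntheticProblem:
    """A multi-fidelity growth surface with a linear cost objective."""

    name: str
    space: DesignSpace
    g0: Callable[[np.ndarray], np.ndarray]          # vectorized (n,p)->(n,)
    biases: dict[int, Callable[[np.ndarray], np.ndarray]]
    noise_sds: dict[int, float]                     # 0 = high fidelity
    seed: int = 0

    @property
    def p(self) -> int:
        return self.space.p

    def truth(self, X: np.ndarray, m: int = 0) -> np.ndarray:
        """Noise-free response of source m: g0 plus its bias field."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(self.g0(X), dtype=float)
        if m != 0:
            if m not in self.biases:
                raise ValueError(f"unknown fidelity code {m}")
            y = y + np.asarray(self.biases[m](X), dtype=float)
        return y


@dataclass(frozen=True)
class SimObservation:
    x: np.ndarray
    m: int
    y: float
    seed: int
    draw_index: int


def _unit_box_space(p: int, cost_coeffs: Sequence[float]) -> DesignSpace:
    comps = tuple(
        ComponentSpec(name=f"x{k}", conc_min=0.0, conc_max=1.0,
                      cost_coeff=float(c))
        for k, c in zip(range(p), cost_coeffs)
    )
    return DesignSpace(components=comps)


def _gaussian_bumps(centers: np.ndarray, widths: np.ndarray,
                    heights: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    def f(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(len(X))
        for c, w, h in zip(centers, widths, heights):
            sq = np.sum((X - c) ** 2, axis=1)
            out += h * np.exp(-0.5 * sq / w**2)
        return out
    return f


def _random_smooth_field(p: int, seed: int, amplitude: float,
                         lengthscale: float = 0.3,
                         n_bumps: int = 8) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth GP-like bias draw: a random superposition of RBF bumps."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, 1.0, size=(n_bumps, p))
    heights = rng.normal(0.0, amplitude / np.sqrt(n_bumps), size=n_bumps)
    widths = np.full(n_bumps, lengthscale)
    return _gaussian_bumps(centers, widths, heights)


def make_problem(preset: str, p: int | None = None, seed: int = 0) -> SyntheticProblem:
    """Build a synthetic problem.

    Low-fidelity bias amplitude defaults to 30% of the ground-truth signal
    scale, so cheap sources are informative but systematically wrong.
    """
    if preset == "peaks2d":
        g0 = _gaussian_bumps(
            centers=np.array([[0.75, 0.25], [0.20, 0.80], [0.50, 0.60]]),
            widths=np.array([0.18, 0.22, 0.30]),
            heights=np.array([2.0, 1.2, 0.5]),
        )
        space = _unit_box_space(2, [0.5, 0.3])
        biases = {1: _random_smooth_field(2, _derive_seed(seed, 101), 0.3 * 2.0)}
        return SyntheticProblem(name=preset, space=space, g0=g0, biases=biases,
                                noise_sds={0: 0.05, 1: 0.15}, seed=seed)
    if preset == "media26":
        space = media26_design_space()
        rng = np.random.default_rng(_derive_seed(seed, 102))
        active = np.sort(rng.choice(space.p, size=8, replace=False))
        weights = rng.uniform(0.5, 2.0, size=8)
        opt = rng.uniform(0.2, 0.8, size=8)

        def g0(X: np.ndarray) -> np.ndarray:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            out = np.zeros(len(X))
            for k, w, o in zip(active, weights, opt):
                out += w * np.exp(-0.5 * (X[:, k] - o) ** 2 / 0.25**2)
            return out

        g0.active_dims = active           # exposed for self-consistency tests
        g0.weights = weights
        amp = 0.3 * float(np.mean(weights))
        biases = {1: _random_smooth_field(space.p, _derive_seed(seed, 103), amp)}
        return SyntheticProblem(name=preset, space=space, g0=g0, biases=biases,
                                noise_sds={0: 0.05, 1: 0.15}, seed=seed)
    if preset == "linear-check":
        p = p or 2
        w = 2.0 ** -np.arange(p)

        def g0(X: np.ndarray) -> np.ndarray:
            return np.atleast_2d(np.asarray(X, dtype=float)) @ w

        space = _unit_box_space(p, np.zeros(p))
        zero = lambda X: np.zeros(len(np.atleast_2d(X)))
        return SyntheticProblem(name=preset, space=space, g0=g0,
                                biases={1: zero}, noise_sds={0: 0.0, 1: 0.0},
                                seed=seed)
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# Observation draws
# ---------------------------------------------------------------------------

def _x_digest(x: np.ndarray) -> int:
    h = hashlib.blake2b(np.ascontiguousarray(x, dtype=float).tobytes(),
                        digest_size=4)
    return int.from_bytes(h.digest(), "little")


def evaluate(problem: SyntheticProblem, x: np.ndarray, m: int, seed: int,
             draw_index: int = 0) -> SimObservation:
    """One simulated assay readout: g0 + bias_m (if m != 0) + Gaussian noise.

    Deterministic given (x, m, seed, draw_index) — repeating a draw returns
    the identical value; bump ``draw_index`` for independent replicates.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must lie in the unit box")
    mean = float(problem.truth(x[None, :], m)[0])
    sd = problem.noise_sds.get(m)
    if sd is None:
        raise ValueError(f"unknown fidelity code {m}")
    rng = np.random.default_rng((seed, m, draw_index, _x_digest(x)))
    y = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return SimObservation(x=x, m=m, y=y, seed=seed, draw_index=draw_index)


def evaluate_batch(problem: SyntheticProblem, X: np.ndarray, m: np.ndarray,
                   seed: int, draw_index: int = 0) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = np.asarray(m, dtype=int)
    return np.array([
        evaluate(problem, x, int(mi), seed, draw_index).y for x, mi in zip(X, m)
    ])


# ---------------------------------------------------------------------------
# Closed-loop benchmark
# ---------------------------------------------------------------------------

#: Desk-scale loop settings for simulation benchmarks: small batches, fewer
#: restarts, fewer MC samples — the loop's behavior at laptop cost.
DESK_SCALE_CONFIG = dict(q=6, q0=2, n_init=10, n_mc=256, max_batches=6,
                         acq_restarts=4, fit_restarts=4, acq_maxiter=30)

_HV_REF = (0.0, -1.1)   # raw growth floor 0; cost floor 10% beyond unit cost


def _hf_metrics(X: np.ndarray, m: np.ndarray, y: np.ndarray,
                problem: SyntheticProblem) -> tuple[float, float]:
    """Dominated hypervolume and best growth of the high-fidelity observations."""
    mask = m == 0
    if not np.any(mask):
        return 0.0, -np.inf
    pts = np.column_stack([
        y[mask], -cost_from_unit_batch(X[mask], problem.space)
    ])
    return hypervolume(pts, np.array(_HV_REF)), float(y[mask].max())


def _init_fidelities(n: int, low_codes: Sequence[int]) -> np.ndarray:
    """Alternate high fidelity with the low-fidelity codes round-robin."""
    codes = [0] + list(low_codes)
    return np.array([codes[i % len(codes)] for i in range(n)], dtype=int)


def closed_loop_benchmark(problem: SyntheticProblem, config: LoopConfig,
                          seeds: Sequence[int],
                          include_random: bool = True) -> pd.DataFrame:
    """Run full campaigns on a synthetic problem and record the trajectory.

    Per seed and batch (0 = the initialization design) the table records the
    dominated hypervolume of all high-fidelity observations so far and the
    best observed high-fidelity growth. A uniform random-search baseline with
    the identical evaluation budget and fidelity mix is included by default.
    """
    rows = []
    for seed in seeds:
        cfg = LoopConfig(**{**config.__dict__, "seed": int(seed)})
        X0 = initialize_campaign(problem.space, cfg)
        m0 = _init_fidelities(cfg.n_init, cfg.low_fidelity_codes)
        y0 = evaluate_batch(problem, X0, m0, seed=_derive_seed(seed, 201))
        X_all, m_all, y_all = X0, m0, y0
        dataset = Dataset(X=X0, m=m0, y=y0).standardize()
        hv, bg = _hf_metrics(X_all, m_all, y_all, problem)
        rows.append(dict(seed=seed, method="mobo", batch=0, hv=hv,
                         best_growth=bg, n_hf=int((m_all == 0).sum())))
        for b in range(1, cfg.max_batches + 1):
            proposal = run_batch(dataset, problem.space, cfg, b)
            y_new = evaluate_batch(problem, proposal.candidates,
                                   proposal.fidelities,
                                   seed=_derive_seed(seed, 202, b))
            dataset = ingest_results(dataset, proposal, y_new)
            X_all = np.vstack([X_all, proposal.candidates])
            m_all = np.concatenate([m_all, proposal.fidelities])
            y_all = np.concatenate([y_all, y_new])
            hv, bg = _hf_metrics(X_all, m_all, y_all, problem)
            rows.append(dict(seed=seed, method="mobo", batch=b, hv=hv,
                             best_growth=bg, n_hf=int((m_all == 0).sum())))
        if include_random:
            rng = np.random.default_rng(_derive_seed(seed, 203))
            Xr = rng.uniform(0, 1, size=(cfg.n_init, problem.p))
            mr = _init_fidelities(cfg.n_init, cfg.low_fidelity_codes)
            yr = evaluate_batch(problem, Xr, mr, seed=_derive_seed(seed, 204))
            hv, bg = _hf_metrics(Xr, mr, yr, problem)
            rows.append(dict(seed=seed, method="random", batch=0, hv=hv,
                             best_growth=bg, n_hf=int((mr == 0).sum())))
            for b in range(1, cfg.max_batches + 1):
                Xb = rng.uniform(0, 1, size=(cfg.q, problem.p))
                mb = np.array([0] * cfg.q0
                              + [cfg.low_fidelity_codes[j % len(cfg.low_fidelity_codes)]
                                 for j in range(cfg.q - cfg.q0)])
                yb = evaluate_batch(problem, Xb, mb,
                                    seed=_derive_seed(seed, 205, b))
                Xr = np.vstack([Xr, Xb])
                mr = np.concatenate([mr, mb])
                yr = np.concatenate([yr, yb])
                hv, bg = _hf_metrics(Xr, mr, yr, problem)
                rows.append(dict(seed=seed, method="random", batch=b, hv=hv,
                                 best_growth=bg, n_hf=int((mr == 0).sum())))
    return pd.DataFrame(rows)
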