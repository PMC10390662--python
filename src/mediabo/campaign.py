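"""The closed batch-design campaign.

One turn of the loop: refit the multi-source surrogate on all data, maximize
the constrained batch acquisition for q candidate media, allocate the q0
high-fidelity slots by enumerating every size-q0 sub-batch and keeping the
one with the highest acquisition value, emit a lab sheet, ingest the
measured results, advance the minimum-growth schedule, repeat.

Defaults mirror a wet-lab campaign: batches of q = 15 media with q0 = 3
high-fidelity (second-passage count) slots, 10 Latin-hypercube initialization
designs, N = 1000 Monte Carlo samples, and a minimum-growth threshold that
tightens from 0.5 to 0.75 to 1.0 (standardized units) at batches 5 and 10 to
steer later batches toward high-growth regions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .acquisition import (
    MCSampleSet,
    ObjectiveSpec,
    alpha,
    maximize_scalar_field,
    nei,
    optimize_acquisition,
)
from .design_space import DesignSpace, MediumFormulation, cost_from_unit_batch, denormalize
from .gp import Dataset, FitConfig, MISGPModel, fit_hyperparameters

__all__ = [
    "LoopConfig",
    "BatchProposal",
    "AllocationResult",
    "initialize_campaign",
    "allocate_fidelities",
    "run_batch",
    "ingest_results",
    "pure_growth_probe",
    "Campaign",
]


@dataclass(frozen=True)
class LoopConfig:
    """Campaign settings.

    ``ymin_schedule`` is a list of (batch_index, threshold) pairs, batches
    1-indexed; the threshold in force at batch b is the entry with the
    largest index <= b. Thresholds must be non-decreasing. The default
    schedule raises the minimum-growth constraint at batches 5 and 10.
    """

    q: int = 15
    q0: int = 3
    n_init: int = 10
    n_mc: int = 1000
    ymin_schedule: tuple[tuple[int, float], ...] = ((1, 0.5), (5, 0.75), (10, 1.0))
    max_batches: int = 12
    seed: int = 0
    acq_restarts: int = 20
    fit_restarts: int = 10
    sigma_min_sq: float = 0.05
    epsilon: float = 1e-3
    ref_cost: float = -1.1
    ref_growth_n_sd: float = 4.0
    low_fidelity_codes: tuple[int, ...] = (1,)
    cost_scale: str = "fraction_of_max"
    acq_maxiter: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.q0 <= self.q):
            raise ValueError("require 0 < q0 <= q")
        idx = [b for b, _ in self.ymin_schedule]
        thr = [t for _, t in self.ymin_schedule]
        if any(b2 <= b1 for b1, b2 in zip(idx, idx[1:])):
            raise ValueError("ymin schedule batch indices must be increasing")
        if any(t2 < t1 for t1, t2 in zip(thr, thr[1:])):
            raise ValueError("ymin schedule thresholds must be non-decreasing")

    def ymin_for_batch(self, batch_index: int) -> float:
        """Threshold in force at a 1-indexed batch (-inf before the first)."""
        ymin = -np.inf
        for b, t in self.ymin_schedule:
            if batch_index >= b:
                ymin = t
        return ymin


@dataclass(frozen=True)
class BatchProposal:
    """q candidate media with fidelity assignments for one batch."""

    candidates: np.ndarray        # (q, p) on the min-max [0,1] scale
    fidelities: np.ndarray        # (q,) codes; exactly q0 zeros
    alpha_value: float            # acquisition of the chosen high-fidelity subset
    batch_index: int

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.candidates, dtype=float))
        fid = np.asarray(self.fidelities, dtype=int)
        if len(fid) != len(X):
            raise ValueError("one fidelity code per candidate required")
        if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
            raise ValueError("candidates must lie in the unit box")
        object.__setattr__(self, "candidates", np.clip(X, 0.0, 1.0))
        object.__setattr__(self, "fidelities", fid)

    def formulations(self, space: DesignSpace) -> list[MediumFormulation]:
        out = []
        for i, x in enumerate(self.candidates):
            conc = denormalize(x, space)
            out.append(MediumFormulation(
                x=x, conc=conc,
                label=f"batch{self.batch_index}_well{i}_m{self.fidelities[i]}"))
        return out


@dataclass(frozen=True)
class AllocationResult:
    fidelities: np.ndarray
    best_subset: tuple[int, ...]
    best_alpha: float
    n_evaluations: int


def _derive_seed(seed: int, *stream: int) -> int:
    """Deterministic child seed below 2^31 from a campaign seed and stream tag."""
    return int(np.random.SeedSequence((seed, *stream)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_campaign(space: DesignSpace, config: LoopConfig) -> np.ndarray:
    """Latin-hypercube initialization designs on the unit box, (n_init, p).

    One point per equal-probability stratum of every coordinate. Use
    :func:`mediabo.design_space.denormalize` to produce the lab sheet.
    """
    sampler = qmc.LatinHypercube(d=space.p, seed=_derive_seed(config.seed, 0))
    return sampler.random(n=config.n_init)


# ---------------------------------------------------------------------------
# Fidelity allocation by sub-batch enumeration
# ---------------------------------------------------------------------------

def allocate_fidelities(X_star: np.ndarray, model: MISGPModel,
                        objective: ObjectiveSpec, config: LoopConfig,
                        cost_fn: Callable, mc: MCSampleSet | None = None) -> AllocationResult:
    """Assign the q0 high-fidelity slots among the q proposed candidates.

    Evaluates the acquisition on every size-q0 subset of the batch — exactly
    C(q, q0) evaluations sharing one fixed Monte Carlo sample set so all
    subsets are scored against the same yardstick — and assigns fidelity 0
    to the highest-scoring subset (ties broken by the lexicographically
    smallest index set). Remaining candidates get the configured low-fidelity
    codes round-robin.
    """
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    q = len(X_star)
    q0 = config.q0
    if q0 > q:
        raise ValueError("q0 must not exceed the batch size")
    mc = mc or MCSampleSet(config.n_mc, seed=_derive_seed(config.seed, 1))
    best_subset, best_val = None, -np.inf
    n_evals = 0
    for subset in itertools.combinations(range(q), q0):
        val = alpha(X_star[list(subset)], model, objective, mc, cost_fn)
        n_evals += 1
        if val > best_val:   # strict: lexicographically first subset wins ties
            best_subset, best_val = subset, val
    fid = np.empty(q, dtype=int)
    low = [i for i in range(q) if i not in best_subset]
    for j, i in enumerate(low):
        fid[i] = config.low_fidelity_codes[j % len(config.low_fidelity_codes)]
    for i in best_subset:
        fid[i] = 0
    return AllocationResult(fidelities=fid, best_subset=best_subset,
                            best_alpha=float(best_val), n_evaluations=n_evals)


# ---------------------------------------------------------------------------
# One loop turn
# ---------------------------------------------------------------------------

def run_batch(dataset: Dataset, space: DesignSpace, config: LoopConfig,
              batch_index: int) -> BatchProposal:
    """Refit the surrogate, optimize the batch acquisition, allocate fidelities.

    ``dataset`` must be standardized. Deterministic given ``config.seed`` and
    ``batch_index`` (per-batch seeds are derived from both).
    """
    seed_fit = _derive_seed(config.seed, 2, batch_index)
    seed_acq = _derive_seed(config.seed, 3, batch_index)
    hyper = fit_hyperparameters(
        dataset,
        FitConfig(restarts=config.fit_restarts, sigma_min_sq=config.sigma_min_sq,
                  seed=seed_fit),
    )
    model = MISGPModel(dataset, hyper)
    objective = ObjectiveSpec.from_dataset(
        dataset, ymin=config.ymin_for_batch(batch_index),
        n_sd=config.ref_growth_n_sd, ref_cost=config.ref_cost,
        epsilon=config.epsilon,
    )
    cost_fn = lambda X: cost_from_unit_batch(X, space, scale=config.cost_scale)
    mc = MCSampleSet(config.n_mc, seed=seed_acq)
    X_star, _, _ = optimize_acquisition(
        model, objective, config.q, cost_fn, restarts=config.acq_restarts,
        seed=seed_acq, mc=mc, maxiter=config.acq_maxiter,
    )
    alloc = allocate_fidelities(X_star, model, objective, config, cost_fn, mc=mc)
    return BatchProposal(candidates=X_star, fidelities=alloc.fidelities,
                         alpha_value=alloc.best_alpha, batch_index=batch_index)


def ingest_results(dataset: Dataset, proposal: BatchProposal,
                   measurements: Sequence[float]) -> Dataset:
    """Append measured assay values (raw scale, one averaged technical
    replicate per medium) for a proposal and re-standardize jointly."""
    y = np.asarray(measurements, dtype=float)
    if y.shape != (len(proposal.candidates),):
        raise ValueError(
            f"expected {len(proposal.candidates)} measurements, got {y.shape}"
        )
    return dataset.append(proposal.candidates, proposal.fidelities, y)


def pure_growth_probe(model: MISGPModel, config: LoopConfig,
                      seed: int | None = None) -> tuple[np.ndarray, float]:
    """Single high-fidelity candidate maximizing noisy expected improvement.

    Growth only, no cost — used late in a campaign to bias toward the best
    achievable growth. Returns (x*, NEI(x*)).
    """
    seed = _derive_seed(config.seed, 4) if seed is None else seed
    mc = MCSampleSet(config.n_mc, seed=seed)
    mask = model.data.m == 0
    incumbents = np.unique(model.data.X[mask], axis=0)
    fun = lambda x: nei(x, model, mc, incumbents=incumbents)
    extra = np.clip(
        incumbents + np.random.default_rng(seed).normal(0, 0.05, incumbents.shape),
        0, 1,
    )
    res = maximize_scalar_field(fun, model.data.p, restarts=config.acq_restarts,
                                seed=seed, extra_starts=extra)
    return res.X, res.value


# ---------------------------------------------------------------------------
# Campaign state
# ---------------------------------------------------------------------------

class Campaign:
    """Stateful campaign: dataset + batch counter + (de)serialization.

    Per-batch seeds are derived from the campaign seed and the batch index,
    so a campaign reloaded from its state file reproduces the next proposal
    exactly.
    """

    def __init__(self, space: DesignSpace, config: LoopConfig,
                 dataset: Dataset | None = None, batch_index: int = 0):
        self.space = space
        self.config = config
        self.dataset = dataset
        self.batch_index = batch_index   # number of completed batches

    def propose_initial(self) -> np.ndarray:
        return initialize_campaign(self.space, self.config)

    def set_initial_data(self, X: np.ndarray, m: np.ndarray, y: np.ndarray) -> None:
        self.dataset = Dataset(X=X, m=m, y=y).standardize()

    def propose_batch(self) -> BatchProposal:
        if self.dataset is None:
            raise RuntimeError("no data yet: run the initialization first")
        return run_batch(self.dataset, self.space, self.config, self.batch_index + 1)

    def ingest(self, proposal: BatchProposal, measurements: Sequence[float]) -> None:
        self.dataset = ingest_results(self.dataset, proposal, measurements)
        self.batch_index = proposal.batch_index

    # -- serialization ------------------------------------------------------

    def to_state(self) -> dict:
        d = self.dataset
        return {
            "batch_index": self.batch_index,
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "q", "q0", "n_init", "n_mc", "max_batches", "seed",
                    "acq_restarts", "fit_restarts", "sigma_min_sq", "epsilon",
                    "ref_cost", "ref_growth_n_sd", "cost_scale", "acq_maxiter")},
                "ymin_schedule": [list(t) for t in self.config.ymin_schedule],
                "low_fidelity_codes": list(self.config.low_fidelity_codes),
            },
            "space_hash": self.space.content_hash(),
            "dataset": None if d is None else {
                "X": d.X.tolist(), "m": d.m.tolist(),
                "y_raw": np.asarray(d.unstandardize(d.y)).tolist(),
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_state(), indent=1))

    @classmethod
    def from_state(cls, state: dict, space: DesignSpace) -> "Campaign":
        if state.get("space_hash") and state["space_hash"] != space.content_hash():
            raise ValueError("state file belongs to a different design space")
        cfg = dict(state["config"])
        cfg["ymin_schedule"] = tuple(tuple(t) for t in cfg["ymin_schedule"])
        cfg["low_fidelity_codes"] = tuple(cfg["low_fidelity_codes"])
        config = LoopConfig(**cfg)
        camp = cls(space, config, batch_index=state["batch_index"])
        ds = state.get("dataset")
        if ds is not None:
            camp.set_initial_data(np.array(ds["X"]), np.array(ds["m"]),
                                  np.array(ds["y_raw"]))
        return camp

    @classmethod
    def load(cls, path: str | Path, space: DesignSpace) -> "Campaign":
        return cls.from_state(json.loads(Path(path).read_text()), space)
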