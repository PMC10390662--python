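"""Hypervolume machinery and the constrained batch acquisition function.

The campaign ranks candidate media on two objectives to maximize: predicted
high-fidelity growth mu(x) and negated cost -c(x). Progress is measured by
dominated hypervolume above a reference point l = (l_growth, l_cost); the
value of running a batch X of q candidates is the expected joint hypervolume
improvement (qEHVI), estimated by Monte Carlo with the reparameterization
trick, with each candidate's contribution weighted by a sigmoid feasibility
score that softly enforces a minimum-growth constraint mu(x) >= ymin.

Pipeline per acquisition evaluation:

1. box-decompose the region above the reference point not dominated by the
   incumbent front into K axis-aligned rectangles (exact staircase, S = 2);
2. draw N joint posterior growth samples at the candidates
   (Y = mu(X) + L(X) Z with fixed standard-normal Z);
3. score each sample's joint improvement by inclusion-exclusion over
   candidate subsets against the K rectangles, weighting each subset by the
   product of its members' feasibility scores;
4. average over the N samples.

The acquisition is maximized over the unit box by multi-start L-BFGS-B with
finite-difference gradients; the fixed Z makes the surface deterministic
given the seed, so quasi-Newton ascent is well behaved.
"""

from __future__ import annotations

import functools as _functools
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .gp import MISGPModel, _chol_with_jitter

__all__ = [
    "ObjectiveSpec",
    "BoxDecomposition",
    "MCSampleSet",
    "OptimResult",
    "pareto_front",
    "hypervolume",
    "box_decompose",
    "hvi_from_boxes",
    "qhvi",
    "sample_joint_posterior",
    "feasibility",
    "incumbent_front",
    "alpha",
    "nei",
    "optimize_acquisition",
    "maximize_scalar_field",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """The two maximization objectives and the growth constraint.

    ``ref`` is the hypervolume reference point (l_growth, l_cost). The
    default rule recomputes l_growth each batch as the mean of all
    standardized growth observations minus four of their standard deviations,
    and fixes l_cost = -1.1 (10% beyond the worst possible unit cost).
    ``ymin`` is the minimum acceptable predicted growth on the standardized
    scale; ``epsilon`` the sigmoid temperature of the soft constraint.
    ``feasibility_on_samples`` applies the constraint to each sampled growth
    value (default) rather than to the posterior mean.
    """

    ref: tuple[float, float] = (-4.0, -1.1)
    ymin: float = -np.inf
    epsilon: float = 1e-3
    feasibility_on_samples: bool = True
    cap_margin: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not np.all(np.isfinite(self.ref)):
            raise ValueError("reference point must be finite")

    @classmethod
    def from_dataset(cls, data, *, ymin: float = -np.inf, n_sd: float = 4.0,
                     ref_cost: float = -1.1, **kw) -> "ObjectiveSpec":
        """Reference-point rule: l_growth = mean(y) - n_sd * sd(y)."""
        y = np.asarray(data.y, dtype=float)
        lg = float(np.mean(y) - n_sd * np.std(y))
        return cls(ref=(lg, ref_cost), ymin=ymin, **kw)


@dataclass(frozen=True)
class BoxDecomposition:
    """K axis-aligned rectangles partitioning the not-yet-dominated region."""

    lowers: np.ndarray  # (K, S)
    uppers: np.ndarray  # (K, S)

    def __post_init__(self) -> None:
        lo = np.atleast_2d(np.asarray(self.lowers, dtype=float))
        up = np.atleast_2d(np.asarray(self.uppers, dtype=float))
        if lo.shape != up.shape:
            raise ValueError("lowers and uppers must have identical shape")
        if np.any(up - lo < -1e-12):
            raise ValueError("rectangles must have non-negative side lengths")
        object.__setattr__(self, "lowers", lo)
        object.__setattr__(self, "uppers", up)

    @property
    def K(self) -> int:
        return len(self.lowers)


class MCSampleSet:
    """Fixed standard-normal draws shared across acquisition evaluations.

    ``draws(k)`` returns an (N, k) matrix that is deterministic given
    (seed, k) and cached, so the acquisition surface stays fixed for the
    lifetime of one optimization.
    """

    def __init__(self, n_samples: int, seed: int = 0):
        if n_samples < 1:
            raise ValueError("need at least one MC sample")
        self.n_samples = int(n_samples)
        self.seed = int(seed)
        self._cache: dict[int, np.ndarray] = {}

    def draws(self, k: int) -> np.ndarray:
        if k not in self._cache:
            rng = np.random.default_rng((self.seed, k))
            self._cache[k] = rng.standard_normal((self.n_samples, k))
        return self._cache[k]


# ---------------------------------------------------------------------------
# Hypervolume and box decomposition (exact for S = 2)
# ---------------------------------------------------------------------------

def pareto_front(points: np.ndarray) -> np.ndarray:
    """Non-dominated subset under maximization (duplicates collapsed)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        return pts
    pts = np.unique(pts, axis=0)
    keep = []
    for i, f in enumerate(pts):
        dominated = False
        for j, g in enumerate(pts):
            if j != i and np.all(g >= f) and np.any(g > f):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return pts[keep]


def hypervolume(points: np.ndarray, ref: np.ndarray) -> float:
    """Lebesgue measure of the union of boxes [ref, f] over the points.

    Exact sweep for S = 2; inclusion-exclusion for other S on small sets.
    Points with any coordinate <= ref contribute nothing.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if len(pts) == 0:
        return 0.0
    pts = pts[np.all(pts > ref, axis=1)]
    if len(pts) == 0:
        return 0.0
    S = pts.shape[1]
    if S == 2:
        front = pareto_front(pts)
        order = np.argsort(front[:, 0])
        front = front[order]
        hv, prev_f1 = 0.0, ref[0]
        for f1, f2 in front:
            hv += (f1 - prev_f1) * (f2 - ref[1])
            prev_f1 = f1
        return float(hv)
    # general-S fallback by inclusion-exclusion (small point sets only)
    front = pareto_front(pts)
    if len(front) > 15:
        raise ValueError("general-S hypervolume limited to <= 15 points")
    hv = 0.0
    for r in range(1, len(front) + 1):
        for idx in itertools.combinations(range(len(front)), r):
            lowest = np.min(front[list(idx)], axis=0)
            hv += (-1) ** (r + 1) * np.prod(np.maximum(lowest - ref, 0.0))
    return float(hv)


def box_decompose(incumbent_front: np.ndarray, ref: np.ndarray,
                  caps: np.ndarray) -> BoxDecomposition:
    """Partition the region above ``ref`` not dominated by the front (S = 2).

    Sorted-staircase construction: with the non-dominated front sorted
    ascending in the first objective (hence descending in the second), the
    K = n_front + 1 rectangles tile the region where a new point can add
    hypervolume, capped above at ``caps``. An empty front yields the single
    rectangle [ref, caps].
    """
    ref = np.asarray(ref, dtype=float)
    caps = np.asarray(caps, dtype=float)
    if ref.shape != (2,) or caps.shape != (2,):
        raise ValueError("box decomposition is implemented for S = 2 only")
    pts = np.atleast_2d(np.asarray(incumbent_front, dtype=float))
    if pts.size:
        pts = pts[np.all(pts > ref, axis=1)]
        pts = pareto_front(pts) if len(pts) else pts
    if pts.size == 0:
        return BoxDecomposition(lowers=ref[None, :], uppers=caps[None, :])
    order = np.argsort(pts[:, 0])
    f1 = pts[order, 0]
    f2 = pts[order, 1]
    n = len(f1)
    x_lo = np.concatenate([[ref[0]], f1])          # (n+1,)
    y_lo = np.concatenate([f2, [ref[1]]])          # (n+1,)
    y_hi = np.concatenate([[caps[1]], f2])         # (n+1,)
    lowers = np.column_stack([x_lo, y_lo])
    uppers = np.column_stack([np.full(n + 1, caps[0]), y_hi])
    return BoxDecomposition(lowers=lowers, uppers=uppers)


def hvi_from_boxes(f: np.ndarray, boxes: BoxDecomposition) -> float:
    """Single-point hypervolume improvement via the clipped-box sum."""
    f = np.asarray(f, dtype=float)
    z = np.minimum(boxes.uppers, f[None, :])
    vols = np.prod(np.maximum(z - boxes.lowers, 0.0), axis=1)
    return float(np.sum(vols))


@_functools.lru_cache(maxsize=32)
def _subset_masks(q: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean membership matrix (2^q - 1, q) and inclusion-exclusion signs."""
    subsets = [J for j in range(1, q + 1)
               for J in itertools.combinations(range(q), j)]
    B = np.zeros((len(subsets), q), dtype=bool)
    for i, J in enumerate(subsets):
        B[i, list(J)] = True
    signs = np.array([(-1.0) ** (B[i].sum() + 1) for i in range(len(subsets))])
    return B, signs


def qhvi(F: np.ndarray, boxes: BoxDecomposition,
         weights: np.ndarray | None = None) -> np.ndarray:
    """Joint hypervolume improvement of q sampled outcomes, per MC sample.

    ``F`` has shape (N, q, S) (or (q, S) for a single sample): sampled
    objective vectors for each of the q candidates. Computed by
    inclusion-exclusion over all non-empty candidate subsets: for subset J
    the integrand against box k uses z_{s,k} = min(u_{s,k}, min_{i in J}
    f_{s,i}), signed by (-1)^{|J|+1}, which measures the union volume without
    double counting. Optional ``weights`` (N, q) multiply each subset's term
    by the product of its members' feasibility scores.

    Cost is exponential in q (all 2^q - 1 subsets are enumerated), which is
    the intended regime for the small sub-batches scored here.
    Returns the (N,) vector of per-sample improvements.
    """
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    if single:
        F = F[None, ...]
    N, q, S = F.shape
    if q == 0:
        return np.zeros(1 if single else N)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (N, q):
            raise ValueError("weights must have shape (N, q)")
    B, signs = _subset_masks(q)                          # (n_sub, q), (n_sub,)
    # subset-wise minima: mask non-members to +inf, min over the q axis
    Fm = np.where(B[None, :, :, None], F[:, None, :, :], np.inf)
    fmin = Fm.min(axis=2)                                # (N, n_sub, S)
    z = np.minimum(boxes.uppers[None, None, :, :], fmin[:, :, None, :])
    vols = np.prod(np.maximum(z - boxes.lowers[None, None, :, :], 0.0),
                   axis=3).sum(axis=2)                   # (N, n_sub)
    if weights is not None:
        wprod = np.prod(np.where(B[None, :, :], weights[:, None, :], 1.0),
                        axis=2)                          # (N, n_sub)
        vols = vols * wprod
    total = vols @ signs
    return total[0:1] if single else total


# ---------------------------------------------------------------------------
# Posterior sampling, feasibility, and the acquisition
# ---------------------------------------------------------------------------

def _qhvi_growth_cost(G: np.ndarray, cost: np.ndarray, boxes: BoxDecomposition,
                      weights: np.ndarray | None = None) -> np.ndarray:
    """Fast qhvi for the growth/cost specialization (S = 2, cost deterministic).

    Algebraically identical to :func:`qhvi` on F = [G, -cost]: subset minima
    are built incrementally over the bitmask lattice (each subset reuses the
    subset without its lowest candidate), and the deterministic cost factor
    of every (subset, box) pair is computed once instead of per MC sample.
    """
    N, q = G.shape
    n_sub = (1 << q) - 1
    # subset-wise minima of sampled growth, and of the weights product
    M = np.empty((N, n_sub + 1))
    cmin = np.empty(n_sub + 1)
    if weights is not None:
        W = np.empty((N, n_sub + 1))
    for sub in range(1, n_sub + 1):
        i = (sub & -sub).bit_length() - 1
        parent = sub & (sub - 1)
        if parent == 0:
            M[:, sub] = G[:, i]
            cmin[sub] = -cost[i]
            if weights is not None:
                W[:, sub] = weights[:, i]
        else:
            np.minimum(M[:, parent], G[:, i], out=M[:, sub])
            cmin[sub] = min(cmin[parent], -cost[i])
            if weights is not None:
                np.multiply(W[:, parent], weights[:, i], out=W[:, sub])
    signs = np.array([(-1.0) ** (sub.bit_count() + 1)
                      for sub in range(1, n_sub + 1)])
    vols = np.zeros((N, n_sub))
    Msub = M[:, 1:]
    for k in range(boxes.K):
        (l1, l2), (u1, u2) = boxes.lowers[k], boxes.uppers[k]
        c2 = np.maximum(np.minimum(cmin[1:], u2) - l2, 0.0)   # (n_sub,)
        live = c2 > 0
        if not np.any(live):
            continue
        t1 = np.maximum(np.minimum(Msub[:, live], u1) - l1, 0.0)
        vols[:, live] += t1 * c2[live]
    if weights is not None:
        vols = vols * W[:, 1:]
    return vols @ signs


def sample_joint_posterior(X: np.ndarray, model: MISGPModel,
                           mc: MCSampleSet) -> np.ndarray:
    """N joint high-fidelity posterior samples at the q candidates.

    Reparameterization trick: Y = mu(X) + L(X) z with L the (jittered)
    Cholesky factor of the joint posterior covariance and z the fixed
    standard-normal draws — deterministic given the sample set's seed.
    Returns shape (N, q).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu, cov = model.posterior_joint(X, m=0)
    L = _chol_with_jitter(cov)
    Z = mc.draws(len(X))
    return mu[None, :] + Z @ L.T


def feasibility(mu, ymin: float, epsilon: float = 1e-3):
    """Soft minimum-growth constraint: sigmoid((mu - ymin) / epsilon).

    Exactly 0.5 at mu = ymin, strictly increasing in mu, and approaching the
    hard indicator 1{mu >= ymin} as epsilon -> 0. Overflow-safe.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if np.isneginf(ymin):
        return np.ones_like(np.asarray(mu, dtype=float))
    return expit((np.asarray(mu, dtype=float) - ymin) / epsilon)


def incumbent_front(model: MISGPModel, cost_fn, objective: ObjectiveSpec) -> np.ndarray:
    """Incumbent objective front: posterior means of observed high-fidelity
    designs paired with their (negated) deterministic costs, non-dominated
    filtered above the reference point. Empty array if no m = 0 data."""
    mask = model.data.m == 0
    if not np.any(mask):
        return np.empty((0, 2))
    X0 = np.unique(model.data.X[mask], axis=0)
    mu = model.posterior(X0, m=0).mu
    pts = np.column_stack([mu, -np.asarray(cost_fn(X0), dtype=float)])
    pts = pts[np.all(pts > np.asarray(objective.ref), axis=1)]
    return pareto_front(pts) if len(pts) else np.empty((0, 2))


def alpha(X: np.ndarray, model: MISGPModel, objective: ObjectiveSpec,
          mc: MCSampleSet, cost_fn, boxes: BoxDecomposition | None = None) -> float:
    """Constrained q-point expected hypervolume improvement of batch X.

    Growth enters through N joint posterior samples at m = 0; cost enters
    deterministically as -c(x). Each candidate subset's improvement term is
    weighted by the product of its members' feasibility scores (evaluated on
    the sampled growth values by default). Always >= 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    q = len(X)
    G = sample_joint_posterior(X, model, mc)            # (N, q)
    cost = np.asarray(cost_fn(X), dtype=float)          # (q,)
    if boxes is None:
        front = incumbent_front(model, cost_fn, objective)
        cap_g = max(G.max(), front[:, 0].max() if len(front) else -np.inf)
        caps = np.array([cap_g + objective.cap_margin,
                         0.0 + objective.cap_margin])
        boxes = box_decompose(front, np.asarray(objective.ref), caps)
    basis = G if objective.feasibility_on_samples \
        else np.broadcast_to(model.posterior(X, m=0).mu[None, :], G.shape)
    w = np.asarray(feasibility(basis, objective.ymin, objective.epsilon))
    if np.isneginf(objective.ymin):
        w = None   # constraint off: unweighted qEHVI
    vals = _qhvi_growth_cost(G, cost, boxes, weights=w)
    return float(np.mean(vals))


def nei(x: np.ndarray, model: MISGPModel, mc: MCSampleSet,
        incumbents: np.ndarray | None = None) -> float:
    """Noisy expected improvement of a single candidate over the incumbents.

    Samples the candidate jointly with the incumbent designs (default: all
    observed high-fidelity designs) from the m = 0 posterior and averages the
    positive part of the candidate's sampled value minus the sampled
    incumbent maximum. Growth only — cost is ignored.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if incumbents is None:
        mask = model.data.m == 0
        incumbents = np.unique(model.data.X[mask], axis=0) if np.any(mask) \
            else np.empty((0, x.shape[1]))
    incumbents = np.atleast_2d(incumbents)
    if len(incumbents) == 0:
        raise ValueError("NEI needs at least one incumbent design")
    joint = np.vstack([x, incumbents])
    Y = sample_joint_posterior(joint, model, mc)        # (N, 1 + n_inc)
    imp = Y[:, 0] - Y[:, 1:].max(axis=1)
    return float(np.mean(np.maximum(imp, 0.0)))


# ---------------------------------------------------------------------------
# Multi-start bounded optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimResult:
    """Best point of a multi-start ascent plus per-start diagnostics."""

    X: np.ndarray
    value: float
    start_values: np.ndarray
    final_values: np.ndarray


def _multistart_maximize(fun, dim: int, restarts: int, seed: int,
                         extra_starts: np.ndarray | None = None,
                         maxiter: int = 100) -> OptimResult:
    """Maximize ``fun`` over [0,1]^dim from random + supplied starts."""
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, 1.0, size=(restarts, dim))
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([starts, np.clip(np.atleast_2d(extra_starts), 0, 1)])
    neg = lambda v: -fun(v)
    bounds = [(0.0, 1.0)] * dim
    best = None
    sv, fv = [], []
    errors = []
    for s in starts:
        try:
            res = minimize(neg, s, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter})
        except Exception as e:
            errors.append(str(e))
            continue
        sv.append(-neg(s))
        fv.append(-res.fun)
        if best is None or -res.fun > best[1]:
            best = (np.clip(res.x, 0.0, 1.0), -res.fun)
    if best is None:
        raise RuntimeError(f"all {len(starts)} optimization starts failed: "
                           f"{errors[:3]}")
    return OptimResult(X=best[0], value=best[1],
                       start_values=np.array(sv), final_values=np.array(fv))


def optimize_acquisition(model: MISGPModel, objective: ObjectiveSpec, q: int,
                         cost_fn, restarts: int = 20, seed: int = 0,
                         mc: MCSampleSet | None = None,
                         n_mc: int = 1000, maxiter: int = 100) -> tuple[np.ndarray, float, OptimResult]:
    """Maximize the batch acquisition over q candidates in the unit box.

    The box decomposition and the MC draws are fixed once, so the surface is
    deterministic for the whole multi-start search (same seed, same result).
    Starts are uniform random plus perturbed observed high-fidelity designs.
    Returns (X*, alpha(X*), diagnostics).
    """
    p = model.data.p
    mc = mc or MCSampleSet(n_mc, seed=seed)
    front = incumbent_front(model, cost_fn, objective)
    mu_all = model.posterior(model.data.X, m=0).mu
    cap_g = max(mu_all.max() + 3.0,
                front[:, 0].max() + 1.0 if len(front) else -np.inf)
    caps = np.array([cap_g + objective.cap_margin, objective.cap_margin])
    boxes = box_decompose(front, np.asarray(objective.ref), caps)

    def fun(flat: np.ndarray) -> float:
        X = flat.reshape(q, p)
        return alpha(X, model, objective, mc, cost_fn, boxes=boxes)

    rng = np.random.default_rng((seed, 17))
    extra = []
    hf = model.data.X[model.data.m == 0]
    for _ in range(min(3, restarts)):
        if len(hf):
            rows = hf[rng.integers(0, len(hf), size=q)]
            extra.append(np.clip(rows + rng.normal(0, 0.05, rows.shape), 0, 1).ravel())
    extra = np.array(extra) if extra else None
    res = _multistart_maximize(fun, q * p, restarts, seed, extra, maxiter=maxiter)
    return res.X.reshape(q, p), res.value, res


def maximize_scalar_field(fun, p: int, restarts: int = 20, seed: int = 0,
                          extra_starts: np.ndarray | None = None,
                          maxiter: int = 100) -> OptimResult:
    """Multi-start L-BFGS-B maximization of a scalar field on [0,1]^p.

    Used for the pure-growth probe (NEI) and for posterior-mean maximization
    in the sensitivity analysis.
    """
    return _multistart_maximize(fun, p, restarts, seed, extra_starts, maxiter)
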