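"""Multi-information-source Gaussian-process surrogate.

Models a high-fidelity growth response jointly with cheaper, biased assays.
Every observation carries a fidelity code ``m`` (0 = the authoritative
high-fidelity source, e.g. a second-passage cell count; 1..M = low-fidelity
assays). The covariance between two observations is

    K((x, m), (x', m')) = S_0(x, x') + 1[m != 0] 1[m = m'] S_m(x, x')

where each ``S_m`` is a squared-exponential kernel with its own amplitude and
per-dimension lengthscales. All sources share the common term ``S_0``; each
low-fidelity source adds its own discrepancy term, so two observations from
the same cheap assay are more correlated with each other than with the
high-fidelity process. Querying at m = 0 predicts the high-fidelity response.

Outputs are standardized (zero mean, unit sd across all sources jointly)
before fitting; hyperparameters are found by maximizing the log marginal
likelihood with multi-start bounded L-BFGS-B over log-parameters, with the
noise variance floored at a configurable minimum for numerical stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "Observation",
    "Dataset",
    "GPHyperparameters",
    "PosteriorPrediction",
    "FitConfig",
    "MISGPModel",
    "se_kernel",
    "mis_kernel",
    "log_marginal_likelihood",
    "fit_hyperparameters",
    "GPNumericalError",
    "GPFitError",
]

_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


class GPNumericalError(RuntimeError):
    """Gram matrix could not be factorized even after jitter escalation."""


class GPFitError(RuntimeError):
    """Hyperparameter optimization failed on all restarts."""

    def __init__(self, msg: str, best_so_far=None):
        super().__init__(msg)
        self.best_so_far = best_so_far


@dataclass(frozen=True)
class Observation:
    """One assay readout: normalized concentrations, fidelity code, value."""

    x: np.ndarray
    m: int
    y: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
            raise ValueError("observation x must lie in [0,1]^p")
        if self.m < 0 or int(self.m) != self.m:
            raise ValueError("fidelity code must be a non-negative integer")
        object.__setattr__(self, "x", np.clip(x, 0.0, 1.0))
        object.__setattr__(self, "m", int(self.m))


@dataclass
class Dataset:
    """Observations in array form plus the output standardization transform.

    ``y`` is stored on the standardized scale when ``y_mean``/``y_sd`` are
    set; :meth:`unstandardize` maps predictions back to the assay scale.
    """

    X: np.ndarray          # (N, p) normalized inputs
    m: np.ndarray          # (N,) fidelity codes
    y: np.ndarray          # (N,) outputs (standardized scale if y_sd != 1)
    y_mean: float = 0.0
    y_sd: float = 1.0

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.m = np.asarray(self.m, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.X) == len(self.m) == len(self.y)):
            raise ValueError("X, m, y must have equal length")

    @classmethod
    def from_observations(cls, obs: Sequence[Observation]) -> "Dataset":
        if len(obs) == 0:
            raise ValueError("empty dataset")
        return cls(
            X=np.stack([o.x for o in obs]),
            m=np.array([o.m for o in obs]),
            y=np.array([o.y for o in obs]),
        )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_sources(self) -> int:
        """Highest fidelity code present plus one (codes are 0..M)."""
        return int(self.m.max()) + 1 if self.n else 1

    def standardize(self) -> "Dataset":
        """Return a copy with y on the zero-mean, unit-sd scale (all sources
        jointly). Raises on fewer than 2 observations or zero spread."""
        if self.n < 2:
            raise ValueError("standardization needs at least 2 observations")
        mu, sd = float(np.mean(self.y)), float(np.std(self.y, ddof=0))
        if sd == 0:
            raise ValueError("cannot standardize constant outputs")
        return Dataset(self.X, self.m, (self.y - mu) / sd, y_mean=mu, y_sd=sd)

    def unstandardize(self, y_std: np.ndarray | float) -> np.ndarray | float:
        return y_std * self.y_sd + self.y_mean

    def append(self, X_new: np.ndarray, m_new: np.ndarray, y_raw: np.ndarray) -> "Dataset":
        """Append raw-scale observations and re-standardize jointly."""
        raw_y = self.unstandardize(self.y)
        merged = Dataset(
            X=np.vstack([self.X, np.atleast_2d(X_new)]),
            m=np.concatenate([self.m, np.asarray(m_new, dtype=int)]),
            y=np.concatenate([np.atleast_1d(raw_y), np.atleast_1d(y_raw)]),
        )
        return merged.standardize()


@dataclass(frozen=True)
class GPHyperparameters:
    """Kernel and noise parameters of the multi-source GP.

    ``amplitudes[m]`` and ``lengthscales[m]`` parameterize source term
    ``S_m`` (m = 0 is the shared high-fidelity term). ``mu0`` is the single
    prior mean shared across fidelities; ``noise_sd`` the homoscedastic
    observation noise.
    """

    mu0: float
    amplitudes: np.ndarray       # (M+1,) sigma_f per source term
    lengthscales: np.ndarray     # (M+1, p)
    noise_sd: float
    sigma_min_sq: float = 0.0    # variance floor applied during fitting

    def __post_init__(self) -> None:
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        ls = np.atleast_2d(np.asarray(self.lengthscales, dtype=float))
        if np.any(amp <= 0) or np.any(ls <= 0):
            raise ValueError("amplitudes and lengthscales must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "lengthscales", ls)

    @property
    def n_sources(self) -> int:
        return len(self.amplitudes)


@dataclass(frozen=True)
class PosteriorPrediction:
    """Posterior mean and variance at queried points/fidelity."""

    mu: np.ndarray
    var: np.ndarray
    fidelity: int


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def se_kernel(x: np.ndarray, x2: np.ndarray, lengthscales: np.ndarray,
              amplitude: float) -> float:
    """Squared-exponential covariance sigma_f^2 exp(-1/2 sum_k d_k^2/l_k^2)."""
    lengthscales = np.asarray(lengthscales, dtype=float)
    if np.any(lengthscales <= 0) or amplitude <= 0:
        raise ValueError("lengthscales and amplitude must be > 0")
    d = (np.asarray(x, float) - np.asarray(x2, float)) / lengthscales
    return float(amplitude**2 * np.exp(-0.5 * np.dot(d, d)))


def _se_gram(A: np.ndarray, B: np.ndarray, lengthscales: np.ndarray,
             amplitude: float) -> np.ndarray:
    """Squared-exponential Gram block between row sets A (n,p) and B (m,p)."""
    As = A / lengthscales
    Bs = B / lengthscales
    sq = (
        np.sum(As**2, axis=1)[:, None]
        + np.sum(Bs**2, axis=1)[None, :]
        - 2.0 * As @ Bs.T
    )
    return amplitude**2 * np.exp(-0.5 * np.maximum(sq, 0.0))


def mis_kernel(x: np.ndarray, m: int, x2: np.ndarray, m2: int,
               hyper: GPHyperparameters) -> float:
    """Multi-source covariance: shared S_0 plus same-source discrepancy S_m."""
    for code in (m, m2):
        if code < 0 or code >= hyper.n_sources:
            raise ValueError(f"unknown fidelity code {code}")
    k = se_kernel(x, x2, hyper.lengthscales[0], hyper.amplitudes[0])
    if m != 0 and m == m2:
        k += se_kernel(x, x2, hyper.lengthscales[m], hyper.amplitudes[m])
    return k


def _mis_gram(X: np.ndarray, m: np.ndarray, X2: np.ndarray, m2: np.ndarray,
              hyper: GPHyperparameters) -> np.ndarray:
    """Multi-source Gram block between (X, m) and (X2, m2)."""
    K = _se_gram(X, X2, hyper.lengthscales[0], hyper.amplitudes[0])
    for code in range(1, hyper.n_sources):
        ia = np.where(m == code)[0]
        ib = np.where(m2 == code)[0]
        if len(ia) and len(ib):
            K[np.ix_(ia, ib)] += _se_gram(
                X[ia], X2[ib], hyper.lengthscales[code], hyper.amplitudes[code]
            )
    return K


def _prior_var(m: np.ndarray, hyper: GPHyperparameters) -> np.ndarray:
    v = np.full(len(m), hyper.amplitudes[0] ** 2)
    for code in range(1, hyper.n_sources):
        v[m == code] += hyper.amplitudes[code] ** 2
    return v


def _chol_with_jitter(K: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, escalating diagonal jitter up to 1e-6."""
    jitter = 0.0
    scale = np.mean(np.diag(K)) or 1.0
    while True:
        try:
            return cholesky(K + jitter * scale * np.eye(len(K)), lower=True)
        except np.linalg.LinAlgError:
            jitter = _JITTER_START if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX:
                raise GPNumericalError(
                    "Gram matrix not positive definite after jitter escalation "
                    f"to {_JITTER_MAX:g} (condition problem)"
                )


# ---------------------------------------------------------------------------
# Posterior and likelihood
# ---------------------------------------------------------------------------

class MISGPModel:
    """Fitted multi-source GP: hyperparameters plus cached factorization."""

    def __init__(self, data: Dataset, hyper: GPHyperparameters):
        if data.n == 0:
            raise ValueError("empty dataset")
        if hyper.n_sources < data.n_sources:
            raise ValueError(
                f"hyperparameters cover {hyper.n_sources} sources but data "
                f"contains code {data.n_sources - 1}"
            )
        self.data = data
        self.hyper = hyper
        K = _mis_gram(data.X, data.m, data.X, data.m, hyper)
        K[np.diag_indices_from(K)] += hyper.noise_sd**2
        self._L = _chol_with_jitter(K)
        resid = data.y - hyper.mu0
        self._alpha = cho_solve((self._L, True), resid)

    def posterior(self, X: np.ndarray, m: int = 0) -> PosteriorPrediction:
        """Posterior mean and variance at rows of X for fidelity ``m``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mq = np.full(len(X), m, dtype=int)
        Ks = _mis_gram(X, mq, self.data.X, self.data.m, self.hyper)
        mu = self.hyper.mu0 + Ks @ self._alpha
        v = solve_triangular(self._L, Ks.T, lower=True)
        var = _prior_var(mq, self.hyper) - np.sum(v**2, axis=0)
        return PosteriorPrediction(mu=mu, var=np.maximum(var, 0.0), fidelity=m)

    def posterior_joint(self, X: np.ndarray, m: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Joint posterior mean vector and covariance matrix at fidelity ``m``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mq = np.full(len(X), m, dtype=int)
        Ks = _mis_gram(X, mq, self.data.X, self.data.m, self.hyper)
        mu = self.hyper.mu0 + Ks @ self._alpha
        v = solve_triangular(self._L, Ks.T, lower=True)
        Kqq = _mis_gram(X, mq, X, mq, self.hyper)
        cov = Kqq - v.T @ v
        return mu, cov

    # -- checkpointing ------------------------------------------------------

    def to_checkpoint(self, space_hash: str = "") -> dict:
        h = self.hyper
        return {
            "mu0": h.mu0,
            "amplitudes": h.amplitudes.tolist(),
            "lengthscales": h.lengthscales.tolist(),
            "noise_sd": h.noise_sd,
            "sigma_min_sq": h.sigma_min_sq,
            "y_mean": self.data.y_mean,
            "y_sd": self.data.y_sd,
            "space_hash": space_hash,
        }

    def save(self, path: str | Path, space_hash: str = "") -> None:
        Path(path).write_text(json.dumps(self.to_checkpoint(space_hash), indent=1))

    @classmethod
    def from_checkpoint(cls, ckpt: dict, data: Dataset,
                        space_hash: str = "") -> "MISGPModel":
        if ckpt.get("space_hash") and space_hash and ckpt["space_hash"] != space_hash:
            raise ValueError("checkpoint was fitted on a different design space")
        hyper = GPHyperparameters(
            mu0=ckpt["mu0"],
            amplitudes=np.array(ckpt["amplitudes"]),
            lengthscales=np.array(ckpt["lengthscales"]),
            noise_sd=ckpt["noise_sd"],
            sigma_min_sq=ckpt.get("sigma_min_sq", 0.0),
        )
        return cls(data, hyper)

    @classmethod
    def load(cls, path: str | Path, data: Dataset, space_hash: str = "") -> "MISGPModel":
        return cls.from_checkpoint(json.loads(Path(path).read_text()), data, space_hash)


def log_marginal_likelihood(data: Dataset, hyper: GPHyperparameters) -> float:
    """Log marginal likelihood of y under N(mu0, K + noise_sd^2 I)."""
    K = _mis_gram(data.X, data.m, data.X, data.m, hyper)
    K[np.diag_indices_from(K)] += hyper.noise_sd**2
    L = _chol_with_jitter(K)
    resid = data.y - hyper.mu0
    alpha = cho_solve((L, True), resid)
    return float(
        -0.5 * resid @ alpha
        - np.sum(np.log(np.diag(L)))
        - 0.5 * data.n * np.log(2 * np.pi)
    )


# ---------------------------------------------------------------------------
# Hyperparameter fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Search box and restart policy for maximum-likelihood fitting.

    Bounds assume standardized outputs and a unit input box: lengthscales in
    [1e-2, 1e2], amplitudes in [1e-2, 1e1], noise sd in [sqrt(sigma_min_sq), 1],
    prior mean in [-10, 10]. ``sigma_min_sq`` floors the noise variance
    (default 0.05) to keep the acquisition surface numerically stable when
    near-duplicate designs enter the data.
    """

    restarts: int = 10
    sigma_min_sq: float = 0.05
    lengthscale_bounds: tuple[float, float] = (1e-2, 1e2)
    amplitude_bounds: tuple[float, float] = (1e-2, 1e1)
    noise_sd_max: float = 1.0
    mu0_bounds: tuple[float, float] = (-10.0, 10.0)
    maxiter: int = 200
    seed: int = 0


def _pack(hyper: GPHyperparameters) -> np.ndarray:
    return np.concatenate(
        [
            [hyper.mu0],
            np.log(hyper.amplitudes),
            np.log(hyper.lengthscales).ravel(),
            [np.log(hyper.noise_sd)],
        ]
    )


def _unpack(theta: np.ndarray, n_sources: int, p: int,
            sigma_min_sq: float) -> GPHyperparameters:
    mu0 = theta[0]
    amps = np.exp(theta[1 : 1 + n_sources])
    ls = np.exp(theta[1 + n_sources : 1 + n_sources + n_sources * p]).reshape(
        n_sources, p
    )
    noise = np.exp(theta[-1])
    return GPHyperparameters(
        mu0=float(mu0), amplitudes=amps, lengthscales=ls,
        noise_sd=float(noise), sigma_min_sq=sigma_min_sq,
    )


def fit_hyperparameters(data: Dataset, config: FitConfig | None = None,
                        n_sources: int | None = None) -> GPHyperparameters:
    """Maximize the log marginal likelihood by multi-start bounded L-BFGS-B.

    Works over log-parameters; the noise sd is bounded below by
    ``sqrt(sigma_min_sq)``. Deterministic given ``config.seed``. Raises
    :class:`GPFitError` carrying the best point seen if every start fails.
    """
    config = config or FitConfig()
    if data.n == 0:
        raise ValueError("empty dataset")
    n_sources = n_sources or data.n_sources
    p = data.p
    rng = np.random.default_rng(config.seed)
    noise_lo = max(np.sqrt(config.sigma_min_sq), 1e-8)

    lb = np.concatenate(
        [
            [config.mu0_bounds[0]],
            np.full(n_sources, np.log(config.amplitude_bounds[0])),
            np.full(n_sources * p, np.log(config.lengthscale_bounds[0])),
            [np.log(noise_lo)],
        ]
    )
    ub = np.concatenate(
        [
            [config.mu0_bounds[1]],
            np.full(n_sources, np.log(config.amplitude_bounds[1])),
            np.full(n_sources * p, np.log(config.lengthscale_bounds[1])),
            [np.log(config.noise_sd_max)],
        ]
    )
    bounds = list(zip(lb, ub))

    def nll(theta: np.ndarray) -> float:
        try:
            h = _unpack(theta, n_sources, p, config.sigma_min_sq)
            return -log_marginal_likelihood(data, h)
        except (GPNumericalError, FloatingPointError):
            return 1e10

    # one informed start (moderate lengthscales, unit amplitude) + random ones
    starts = [
        np.concatenate(
            [
                [float(np.mean(data.y))],
                np.zeros(n_sources),
                np.full(n_sources * p, np.log(0.3)),
                [np.log(max(noise_lo, 0.1))],
            ]
        )
    ]
    for _ in range(max(config.restarts - 1, 0)):
        starts.append(rng.uniform(lb, ub))

    best = None
    failures = []
    for s in starts:
        s = np.clip(s, lb, ub)
        try:
            res = minimize(
                nll, s, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.maxiter},
            )
        except Exception as e:  # pragma: no cover - defensive
            failures.append(str(e))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise GPFitError(
            f"all {len(starts)} restarts failed: {failures[:3]}", best_so_far=None
        )
    return _unpack(best.x, n_sources, p, config.sigma_min_sq)
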