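import numpy as np
import pytest

import mediabo as mb


@pytest.fixture(scope="session")
def media26():
    return mb.media26_design_space()


@pytest.fixture(scope="session")
def toy_space_2d():
    """Unit-box 2-component space with costs (0.5, 0.3)."""
    return mb.DesignSpace(components=(
        mb.ComponentSpec("a", 0.0, 1.0, 0.5),
        mb.ComponentSpec("b", 0.0, 1.0, 0.3),
    ))


@pytest.fixture(scope="session")
def gp_1d_model():
    """Small 1-D single-source GP with fixed hyperparameters."""
    X = np.array([[0.1], [0.45], [0.8]])
    y = np.array([0.2, 1.0, -0.3])
    data = mb.Dataset(X=X, m=np.zeros(3, int), y=y)
    hyper = mb.GPHyperparameters(
        mu0=0.1, amplitudes=np.array([1.2]),
        lengthscales=np.array([[0.3]]), noise_sd=0.1,
    )
    return mb.MISGPModel(data, hyper)


@pytest.fixture(scope="session")
def gp_2d_model():
    """2-D single-source GP fitted shape: unimodal bump centered at (0.6, 0.4)."""
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 1, size=(30, 2))
    f = lambda X: 2.0 * np.exp(-0.5 * np.sum((X - [0.6, 0.4]) ** 2, axis=1) / 0.2**2)
    y = f(X) + rng.normal(0, 0.01, 30)
    data = mb.Dataset(X=X, m=np.zeros(30, int), y=y).standardize()
    hyper = mb.GPHyperparameters(
        mu0=float(np.mean(data.y)), amplitudes=np.array([1.5]),
        lengthscales=np.array([[0.25, 0.25]]), noise_sd=0.05,
    )
    model = mb.MISGPModel(data, hyper)
    model.true_center = np.array([0.6, 0.4])
    return model


class DeterministicModel:
    """Stub posterior with exactly known mean and (near-)zero covariance.

    Mimics the MISGPModel query surface used by the acquisition: a fixed
    mean function and a diagonal covariance, letting tests pin acquisition
    values to closed forms.
    """

    def __init__(self, mean_fn, sd=0.0, p=2, X_hf=None):
        self.mean_fn = mean_fn
        self.sd = sd
        X_hf = np.zeros((1, p)) if X_hf is None else np.atleast_2d(X_hf)
        self.data = mb.Dataset(
            X=X_hf, m=np.zeros(len(X_hf), int),
            y=np.asarray(self.mean_fn(X_hf), float),
        )

    def posterior(self, X, m=0):
        X = np.atleast_2d(X)
        mu = np.asarray(self.mean_fn(X), float)
        return mb.PosteriorPrediction(mu=mu, var=np.full(len(X), self.sd**2),
                                      fidelity=m)

    def posterior_joint(self, X, m=0):
        X = np.atleast_2d(X)
        mu = np.asarray(self.mean_fn(X), float)
        return mu, self.sd**2 * np.eye(len(X))


@pytest.fixture
def deterministic_model_factory():
    return DeterministicModel
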