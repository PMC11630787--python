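"""Cross-sensor observer functions: KNN, geometric harmonics, feed-forward nets.

Once the common variables are identified, any regressor can learn the
map from a set of identifiable coordinates of one sensor to an
identifiable channel of the other — or, in the causality setups, from
present common coordinates to future ones, which is a discrete-time
evolution model.  Three interchangeable regressors are provided:

* ``knn`` — k-nearest-neighbor mean (k = 5 by default, as used for the
  causal maps);
* ``gh`` — geometric harmonics: project the training targets onto the
  leading eigenfunctions of a Gaussian kernel on the training inputs and
  extend out of sample with the Nystrom formula;
* ``ffnn`` — a small multilayer perceptron (2 x 32 tanh units, LBFGS,
  fixed seed), deterministic given its seed.

Accuracy is scored with the maximum-deviation error
``eps = ||truth - predicted||_inf / nsamples`` with nsamples = 200 by
default; the conventional unnormalized L-infinity error is also exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.spatial.distance import cdist
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor

from .spectral import median_pairwise_distance

__all__ = [
    "ObserverModel",
    "ObserverResults",
    "Observer",
    "fit_observer",
    "predict",
    "linf_error",
    "linf_raw",
    "time_split",
]

METHODS = ("knn", "gh", "ffnn")


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


@dataclass
class ObserverModel:
    """A fitted observer function from one coordinate set to target channels."""

    method: str
    hyperparams: dict
    train_inputs: np.ndarray
    train_targets: np.ndarray
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def n_train(self) -> int:
        return self.train_inputs.shape[0]

    def predict(self, new_inputs, return_extrapolation_flags: bool = False):
        return predict(self, new_inputs, return_extrapolation_flags)


def _fit_gh(Z: np.ndarray, W: np.ndarray, epsilon: float | None,
            delta: float) -> dict:
    if epsilon is None:
        epsilon = median_pairwise_distance(Z) ** 2
    K = np.exp(-cdist(Z, Z, "sqeuclidean") / epsilon)
    vals, vecs = sla.eigh(K)
    order = np.argsort(np.abs(vals))[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.abs(vals) >= delta * np.abs(vals[0])
    if not np.any(keep):
        raise ValueError("all geometric-harmonic modes truncated; decrease delta")
    vals, vecs = vals[keep], vecs[:, keep]
    coeffs = vecs.T @ W                      # projection of targets on eigenfunctions
    return {"epsilon": epsilon, "eigvals": vals, "eigvecs": vecs, "coeffs": coeffs}


def fit_observer(inputs, targets, method: str = "knn", **hyperparams
                 ) -> ObserverModel:
    """Fit a KNN, geometric-harmonics or FFNN observer.

    Inputs are standardized with the training statistics before fitting
    (all methods); GH and FFNN targets are additionally centered and
    scaled, with the transform inverted at prediction time.

    Hyperparameters: ``k`` (knn, default 5); ``epsilon`` and ``delta``
    (gh; default squared median pairwise distance of the standardized
    training inputs and 1e-3 relative spectral cutoff); ``hidden``,
    ``seed``, ``max_iter`` (ffnn, default (32, 32), 0, 5000).
    """
    X, Y = _as_2d(inputs), _as_2d(targets)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and targets must share the sample count")
    n = X.shape[0]
    x_mu, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Z = (X - x_mu) / x_sd
    y_mu, y_sd = Y.mean(axis=0), Y.std(axis=0)
    y_sd = np.where(y_sd > 0, y_sd, 1.0)
    state = {"x_mu": x_mu, "x_sd": x_sd, "y_mu": y_mu, "y_sd": y_sd}
    if method == "knn":
        k = int(hyperparams.setdefault("k", 5))
        if k > n:
            raise ValueError(f"k={k} exceeds the training size n={n}")
        state["sk"] = KNeighborsRegressor(n_neighbors=k).fit(Z, Y)
    elif method == "gh":
        if n < 2:
            raise ValueError("need at least 2 training samples")
        W = (Y - y_mu) / y_sd
        state.update(_fit_gh(Z, W, hyperparams.setdefault("epsilon", None),
                             hyperparams.setdefault("delta", 1e-3)))
        hyperparams["epsilon"] = state["epsilon"]
    elif method == "ffnn":
        hidden = tuple(hyperparams.setdefault("hidden", (32, 32)))
        seed = int(hyperparams.setdefault("seed", 0))
        max_iter = int(hyperparams.setdefault("max_iter", 5000))
        W = (Y - y_mu) / y_sd
        state["sk"] = MLPRegressor(hidden_layer_sizes=hidden, activation="tanh",
                                   solver="lbfgs", max_iter=max_iter,
                                   random_state=seed
                                   ).fit(Z, W if W.shape[1] > 1 else W.ravel())
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return ObserverModel(method=method, hyperparams=dict(hyperparams),
                         train_inputs=X, train_targets=Y, _state=state)


def predict(model: ObserverModel, new_inputs,
            return_extrapolation_flags: bool = False):
    """Evaluate a fitted observer at new inputs.

    Geometric harmonics use the Nystrom out-of-sample extension
    ``psi_l(x) = (1/sigma_l) sum_j w(x, x_j) psi_l(x_j)``.  When
    ``return_extrapolation_flags`` is true, also returns a boolean mask
    of points farther from every training point than the training-set
    diameter (predictions there are extrapolations).
    """
    Xn = _as_2d(new_inputs)
    if Xn.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"input dimension {Xn.shape[1]} does not match training dimension "
            f"{model.train_inputs.shape[1]}")
    st = model._state
    Zn = (Xn - st["x_mu"]) / st["x_sd"]
    if model.method == "knn":
        out = _as_2d(st["sk"].predict(Zn))
    elif model.method == "ffnn":
        out = _as_2d(st["sk"].predict(Zn)) * st["y_sd"] + st["y_mu"]
    else:
        Ztr = (model.train_inputs - st["x_mu"]) / st["x_sd"]
        Kx = np.exp(-cdist(Zn, Ztr, "sqeuclidean") / st["epsilon"])
        psi_x = Kx @ st["eigvecs"] / st["eigvals"]
        out = _as_2d(psi_x @ st["coeffs"]) * st["y_sd"] + st["y_mu"]
    if model.train_targets.shape[1] == 1:
        out = out.reshape(-1, 1)
    if not return_extrapolation_flags:
        return out
    d_near = cdist(Xn, model.train_inputs).min(axis=1)
    diam = cdist(model.train_inputs, model.train_inputs).max()
    return out, d_near > diam


def linf_error(truth, predicted, nsamples: int = 200) -> float:
    """Maximum absolute deviation divided by ``nsamples``.

    This is the normalized maximum-error score used throughout the
    experiment reports; see :func:`linf_raw` for the conventional
    unnormalized L-infinity error.
    """
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.size != p.size:
        raise ValueError("truth and predicted must have the same size")
    if nsamples <= 0:
        raise ValueError("nsamples must be > 0")
    return float(np.max(np.abs(t - p.reshape(t.shape))) / nsamples)


def linf_raw(truth, predicted) -> float:
    """Conventional (unnormalized) L-infinity error ``max_i |t_i - p_i|``."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.size != p.size:
        raise ValueError("truth and predicted must have the same size")
    return float(np.max(np.abs(t - p.reshape(t.shape))))


def time_split(n_total: int, n_train: int = 50, n_test: int = 200):
    """Index arrays for a time-ordered train/test split (no shuffling)."""
    if n_train + n_test > n_total:
        raise ValueError(f"n_train + n_test = {n_train + n_test} exceeds "
                         f"{n_total} samples")
    return np.arange(n_train), np.arange(n_train, n_train + n_test)


@dataclass
class ObserverResults:
    """Fitted observer plus its train/test evaluation."""

    model_spec: "Observer"
    observer: ObserverModel
    test_inputs: np.ndarray
    test_targets: np.ndarray
    predictions: np.ndarray
    extrapolation_flags: np.ndarray

    @property
    def error(self) -> float:
        """Normalized maximum-deviation error on the test set."""
        return linf_error(self.test_targets, self.predictions,
                          self.model_spec.nsamples)

    @property
    def error_linf(self) -> float:
        return linf_raw(self.test_targets, self.predictions)

    def summary(self) -> str:
        m = self.observer
        return "\n".join([
            f"Observer ({m.method})",
            "=" * 47,
            f"training samples      : {m.n_train}",
            f"test samples          : {len(self.test_targets)}",
            f"hyperparameters       : {m.hyperparams}",
            f"max-dev error (/n)    : {self.error:.6g}",
            f"L_inf error           : {self.error_linf:.6g}",
            f"extrapolating points  : {int(self.extrapolation_flags.sum())}",
        ])


class Observer:
    """Observer model with a time-ordered train/test protocol.

    Fits on the first ``n_train`` samples (default 50) and evaluates on
    the following ``n_test`` (default 200) with the normalized
    maximum-deviation error (``nsamples`` = 200).
    """

    def __init__(self, inputs, targets, method: str = "knn", *,
                 n_train: int = 50, n_test: int = 200, nsamples: int = 200,
                 **hyperparams):
        self.inputs = _as_2d(inputs)
        self.targets = _as_2d(targets)
        self.method = method
        self.n_train = n_train
        self.n_test = n_test
        self.nsamples = nsamples
        self.hyperparams = hyperparams

    def fit(self) -> ObserverResults:
        tr, te = time_split(self.inputs.shape[0], self.n_train, self.n_test)
        obs = fit_observer(self.inputs[tr], self.targets[tr], self.method,
                           **self.hyperparams)
        pred, flags = predict(obs, self.inputs[te], return_extrapolation_flags=True)
        return ObserverResults(model_spec=self, observer=obs,
                               test_inputs=self.inputs[te],
                               test_targets=self.targets[te],
                               predictions=pred, extrapolation_flags=flags)
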