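"""Local linear regression (LLR) residuals for manifold parsimony and identifiability.

Two questions keep recurring in the common-variable pipeline and both
reduce to "is this function predictable from those coordinates?":

* *Parsimony* — successive diffusion eigenvectors often repeat
  information (harmonics of earlier ones).  An eigenvector whose
  leave-one-out LLR residual against the previously retained unique
  eigenvectors is high carries a genuinely new direction; one with a
  low residual is a harmonic.  The unique set is the parsimonious
  embedding.
* *Identifiability* — a sensor channel with a low LLR residual against
  the common embedding is a function of the common variables (it can be
  observed from the other sensor); a high residual marks a channel
  carrying sensor-specific information.

The residual of a target y given predictors x_1..x_n is::

    r = sqrt( sum_i (y_i - yhat_{-i}(x_i))^2 / sum_i (y_i - ybar)^2 )

where yhat_{-i} is a weighted linear fit with Gaussian weights of scale
``bandwidth``, refit leaving sample i out.  With no predictors the
residual is defined as 1, which makes the first nontrivial eigenvector's
residual exactly 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .spectral import DiffusionEmbedding

__all__ = [
    "LLRReport",
    "IllConditionedWarning",
    "default_bandwidth",
    "llr_residual",
    "select_parsimonious",
    "channel_identifiability",
]


class IllConditionedWarning(UserWarning):
    """Too few effective neighbors at some points; a ridge fallback was used."""


@dataclass
class LLRReport:
    """Residuals and retained indices from parsimonious eigenvector selection."""

    residuals: dict = field(default_factory=dict)   # eigvec index -> residual
    selected_indices: list = field(default_factory=list)
    bandwidths: dict = field(default_factory=dict)
    threshold: float = 0.5

    @property
    def dimension(self) -> int:
        """Number of unique (non-harmonic) nontrivial eigenvectors."""
        return len(self.selected_indices)

    def to_dict(self) -> dict:
        return {
            "residuals": {str(k): float(v) for k, v in self.residuals.items()},
            "selected_indices": [int(i) for i in self.selected_indices],
            "bandwidths": {str(k): float(v) for k, v in self.bandwidths.items()},
            "threshold": float(self.threshold),
            "dimension": self.dimension,
        }


def default_bandwidth(predictors: np.ndarray) -> float:
    """One third of the median pairwise distance in predictor space."""
    predictors = np.asarray(predictors, dtype=float)
    if predictors.ndim == 1:
        predictors = predictors[:, None]
    d = pdist(predictors)
    med = float(np.median(d))
    if med == 0.0:
        raise ValueError("degenerate predictors: median pairwise distance is 0")
    return med / 3.0


def llr_residual(predictors: np.ndarray | None, target: np.ndarray,
                 bandwidth: float | None = None, *,
                 ridge: float = 1e-8) -> float:
    """Normalized leave-one-out local-linear-regression residual.

    Returns a value near 0 when ``target`` is a smooth function of the
    predictors, near 1 (the residual of predicting the mean) when it is
    unrelated.  ``predictors=None`` or zero columns returns exactly 1.
    """
    target = np.asarray(target, dtype=float).ravel()
    n = len(target)
    denom = float(np.sum((target - target.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("target is constant; residual undefined")
    if predictors is None:
        return 1.0
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return 1.0
    if X.shape[0] != n:
        raise ValueError("predictors and target must have matching length")
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p+1 samples (n={n}, p={p})")
    if bandwidth is None:
        bandwidth = default_bandwidth(X)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")

    sq = squareform(pdist(X, "sqeuclidean"))
    W = np.exp(-sq / bandwidth**2)
    np.fill_diagonal(W, 0.0)              # leave-one-out

    eff = W.sum(axis=1) / W.max(axis=1).clip(min=1e-300)
    if np.any(eff < p + 2):
        warnings.warn(
            "fewer than p+2 effective neighbors at some points; relying on the "
            "ridge term", IllConditionedWarning, stacklevel=2)

    D = np.column_stack([np.ones(n), X])          # n x (p+1)
    # batched weighted normal equations: A_i = D^T diag(W_i) D, b_i = D^T W_i y
    A = np.einsum("ij,jk,jl->ikl", W, D, D, optimize=True)
    b = np.einsum("ij,jk,j->ik", W, D, target, optimize=True)
    tr = np.einsum("ikk->i", A) / (p + 1)
    A = A + (ridge * tr.clip(min=1e-300))[:, None, None] * np.eye(p + 1)
    beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    fit = np.einsum("ik,ik->i", D, beta)
    return float(np.sqrt(np.sum((target - fit) ** 2) / denom))


def _nontrivial_indices(embedding: DiffusionEmbedding,
                        eigenvalue_floor: float) -> list[int]:
    """Indices of usable eigenvectors: skip the constant leading one,
    complex-flagged pairs, and eigenvectors whose eigenvalue modulus has
    decayed below ``eigenvalue_floor`` times the first nontrivial one
    (those vectors sit at the numerical noise floor and carry no
    geometry, so they would trivially look "unique" to LLR)."""
    lam = np.abs(embedding.eigenvalues)
    ref = lam[1] if len(lam) > 1 else 1.0
    idx = []
    for j in range(1, embedding.n_eigenvectors):
        if embedding.real_mask is not None and not embedding.real_mask[j]:
            continue
        if lam[j] < eigenvalue_floor * ref:
            continue
        idx.append(j)
    return idx


def select_parsimonious(embedding: DiffusionEmbedding | np.ndarray,
                        max_k: int | None = None,
                        uniqueness_threshold: float = 0.5,
                        bandwidth: float | None = None,
                        eigenvalue_floor: float = 1e-2) -> LLRReport:
    """Select the unique (non-harmonic) eigenvectors of an embedding.

    Walks the nontrivial eigenvectors in spectral order, regressing each
    on the unique ones retained so far.  The first nontrivial eigenvector
    has no predictors, hence residual 1, and is always retained; later
    ones are retained when their residual exceeds
    ``uniqueness_threshold``.  The retained set is the parsimonious
    embedding and its size the manifold dimension estimate.  Candidates
    are restricted to eigenvectors whose |eigenvalue| is at least
    ``eigenvalue_floor`` times the first nontrivial one.
    """
    if isinstance(embedding, DiffusionEmbedding):
        candidates = _nontrivial_indices(embedding, eigenvalue_floor)
        vecs = embedding.eigenvectors
    else:
        vecs = np.asarray(embedding, dtype=float)
        candidates = list(range(1, vecs.shape[1]))
    if vecs.shape[1] < 3:
        raise ValueError("need at least 3 eigenvectors (one trivial, two candidates)")
    if max_k is not None:
        candidates = candidates[:max_k]

    report = LLRReport(threshold=uniqueness_threshold)
    retained: list[int] = []
    for j in candidates:
        y = vecs[:, j]
        if not retained:
            r = llr_residual(None, y)
            bw = np.nan
        else:
            X = vecs[:, retained]
            bw = bandwidth if bandwidth is not None else default_bandwidth(X)
            r = llr_residual(X, y, bw)
        report.residuals[j] = r
        report.bandwidths[j] = bw
        if r > uniqueness_threshold:
            retained.append(j)
    report.selected_indices = retained
    return report


def channel_identifiability(coords: np.ndarray, channel: np.ndarray,
                            bandwidth: float | None = None) -> float:
    """LLR residual of a (standardized) channel against embedding coordinates.

    Low residual: the channel is a function of those coordinates (it is
    identifiable from them); high residual: it carries independent
    information.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    std = channel.std()
    if std == 0:
        raise ValueError("constant channel; identifiability undefined")
    z = (channel - channel.mean()) / std
    return llr_residual(coords, z, bandwidth)
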