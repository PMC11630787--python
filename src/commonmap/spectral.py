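"""Kernels, Markov normalization and diffusion-map eigendecompositions.

The building blocks here follow the standard diffusion-maps recipe: a
Gaussian affinity ``W_ij = exp(-||x_i - x_j||^2 / eps)``, the
density-correcting alpha-normalization ``W~ = D^-a W D^-a``, row
normalization to a Markov matrix ``P``, and the leading eigenpairs of
``P``.  Two extensions are provided: an *output-informed* kernel that
sharpens the affinity along input directions that change a designated
output response, and support for nonsymmetric operators (products of two
Markov matrices, as used by alternating diffusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "KernelSpec",
    "DiffusionEmbedding",
    "IsolatedSampleError",
    "ComplexSpectrumWarning",
    "median_pairwise_distance",
    "standardize_channels",
    "gaussian_kernel",
    "output_informed_kernel",
    "markov_normalize",
    "spectral_embed",
]


class IsolatedSampleError(ValueError):
    """A kernel row is identically zero: that sample is disconnected."""


class ComplexSpectrumWarning(UserWarning):
    """Retained eigenvalues of a nonsymmetric operator have sizeable imaginary parts."""


@dataclass(frozen=True)
class KernelSpec:
    """Provenance of a kernel: kind, bandwidth and normalization exponent."""

    kind: str = "gaussian"            # "gaussian" | "output_informed"
    epsilon: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be > 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class DiffusionEmbedding:
    """Leading eigenpairs of a diffusion operator.

    Eigenvalues are sorted by descending modulus with ``lambda_1 = 1``
    and the first eigenvector constant; eigenvector signs are fixed so
    the largest-magnitude entry is positive.  ``real_mask`` flags
    eigenpairs whose imaginary part was negligible (always true for
    symmetric-similar operators); complex-flagged eigenvectors should be
    excluded from downstream regression.
    """

    eigenvalues: np.ndarray          # real parts, descending |lambda|
    eigenvectors: np.ndarray         # n x m, unit-norm columns
    kernel: KernelSpec | None = None
    operator_kind: str = "plain"     # "plain" | "alternating" | "output_informed"
    real_mask: np.ndarray | None = None
    tags: list[str] | None = None    # optional per-eigenvector labels
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.real_mask is None:
            self.real_mask = np.ones(len(self.eigenvalues), dtype=bool)

    @property
    def n_eigenvectors(self) -> int:
        return self.eigenvectors.shape[1]

    def coordinates(self, indices) -> np.ndarray:
        """Eigenvector columns at the given indices as an n x k matrix."""
        return self.eigenvectors[:, list(indices)]

    def save(self, csv_path, json_path=None) -> None:
        import json as _json
        import pandas as pd
        csv_path = str(csv_path)
        if json_path is None:
            json_path = csv_path[:-4] + ".meta.json" if csv_path.endswith(".csv") \
                else csv_path + ".meta.json"
        pd.DataFrame(self.eigenvectors,
                     columns=[f"phi{i+1}" for i in range(self.n_eigenvectors)]
                     ).to_csv(csv_path, index=False, float_format="%.17g")
        meta = {
            "eigenvalues": self.eigenvalues.tolist(),
            "operator_kind": self.operator_kind,
            "real_mask": np.asarray(self.real_mask).astype(int).tolist(),
            "tags": self.tags,
            "kernel": None if self.kernel is None else {
                "kind": self.kernel.kind, "epsilon": self.kernel.epsilon,
                "alpha": self.kernel.alpha},
            "provenance": self.provenance,
        }
        with open(json_path, "w") as fh:
            _json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, csv_path, json_path=None) -> "DiffusionEmbedding":
        import json as _json
        import pandas as pd
        csv_path = str(csv_path)
        if json_path is None:
            json_path = csv_path[:-4] + ".meta.json" if csv_path.endswith(".csv") \
                else csv_path + ".meta.json"
        vecs = pd.read_csv(csv_path, float_precision="round_trip").to_numpy()
        with open(json_path) as fh:
            meta = _json.load(fh)
        k = meta.get("kernel")
        return cls(eigenvalues=np.asarray(meta["eigenvalues"]),
                   eigenvectors=vecs,
                   kernel=None if k is None else KernelSpec(**k),
                   operator_kind=meta["operator_kind"],
                   real_mask=np.asarray(meta["real_mask"], dtype=bool),
                   tags=meta.get("tags"),
                   provenance=meta.get("provenance", {}))


def _as_samples(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def standardize_channels(data: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling per channel (constant channels kept).

    Heterogeneous sensor channels can differ in scale by orders of
    magnitude (surface coverages are O(0.01); a Lorenz coordinate spans
    tens of units); Euclidean kernels on raw channels would see only the
    largest one.  Standardization puts every channel on an equal
    footing before kernels are built.
    """
    data = _as_samples(data)
    std = data.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (data - data.mean(axis=0)) / std


def median_pairwise_distance(data: np.ndarray) -> float:
    """Median Euclidean pairwise distance (the default bandwidth scale)."""
    d = pdist(_as_samples(data))
    m = float(np.median(d))
    if m == 0.0:
        raise ValueError("median pairwise distance is zero (degenerate data)")
    return m


def gaussian_kernel(data: np.ndarray, epsilon: float | None = None) -> np.ndarray:
    """Gaussian affinity ``W_ij = exp(-||x_i - x_j||^2 / epsilon)``.

    ``epsilon`` defaults to the square of the median pairwise distance.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if not np.all(np.isfinite(data)):
        raise ValueError("data contain non-finite values")
    if epsilon is None:
        epsilon = median_pairwise_distance(data) ** 2
    if not (epsilon > 0):
        raise ValueError("epsilon must be > 0")
    sq = squareform(pdist(data, "sqeuclidean"))
    return np.exp(-sq / epsilon)


def output_informed_kernel(inputs: np.ndarray, outputs: np.ndarray,
                           epsilon: float) -> np.ndarray:
    """Output-informed affinity emphasizing input directions that move the output.

    ``w(y_i, y_j) = exp(-||f(y_i)-f(y_j)||^2 / eps^2 - ||y_i-y_j||^2 / eps)``

    with the output term carrying the *squared* bandwidth and the input
    term the plain one.  For eps < 1 the output mismatch dominates, so
    level sets of the output response are resolved first.  Inputs are
    expected pre-scaled to order-one pairwise distances.
    """
    inputs = _as_samples(inputs)
    outputs = _as_samples(outputs)
    if outputs.shape[0] != inputs.shape[0]:
        raise ValueError("inputs and outputs must have the same number of rows")
    if not (epsilon > 0):
        raise ValueError("epsilon must be > 0")
    if not (np.all(np.isfinite(inputs)) and np.all(np.isfinite(outputs))):
        raise ValueError("non-finite values in inputs or outputs")
    sq_in = squareform(pdist(inputs, "sqeuclidean"))
    sq_out = squareform(pdist(outputs, "sqeuclidean"))
    return np.exp(-sq_out / epsilon**2 - sq_in / epsilon)


def markov_normalize(W: np.ndarray, alpha: float = 1.0,
                     return_degrees: bool = False):
    """Density-corrected row normalization of a nonnegative kernel.

    Applies ``W~ = D^-alpha W D^-alpha`` then row-normalizes to a Markov
    matrix P.  With ``alpha=1`` the operator approximates the
    Laplace--Beltrami generator regardless of the sampling density —
    appropriate for attractor data, which is never uniformly sampled.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("kernel must be nonnegative")
    d = W.sum(axis=1)
    if np.any(d == 0):
        row = int(np.argmax(d == 0))
        raise IsolatedSampleError(f"kernel row {row} sums to zero (isolated sample)")
    if alpha != 0.0:
        inv = d ** (-alpha)
        W = W * np.outer(inv, inv)
    d2 = W.sum(axis=1)
    P = W / d2[:, None]
    if return_degrees:
        return P, d2
    return P


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    j = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[j, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def spectral_embed(P: np.ndarray, n_eigenvectors: int = 20, *,
                   degrees: np.ndarray | None = None,
                   kernel: KernelSpec | None = None,
                   operator_kind: str = "plain",
                   imag_tol: float = 1e-6) -> DiffusionEmbedding:
    """Leading eigenpairs of a row-stochastic operator, sorted by |lambda|.

    If ``degrees`` (the row sums of the symmetric affinity that P was
    normalized from) are supplied, P is symmetric-similar and the
    decomposition runs on the symmetrized conjugate
    ``S = D^1/2 P D^-1/2`` for numerical stability; otherwise a dense
    nonsymmetric solver is used and eigenpairs whose relative imaginary
    part exceeds ``imag_tol`` are flagged in ``real_mask``.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    m = min(n_eigenvectors, n)
    if degrees is not None:
        sq = np.sqrt(np.asarray(degrees, dtype=float))
        S = (P * sq[:, None]) / sq[None, :]
        S = 0.5 * (S + S.T)
        if m < n // 4 and n > 400:
            vals, vecs = eigsh(S, k=m, which="LA")
            order = np.argsort(vals)[::-1]
        else:
            vals, vecs = sla.eigh(S)
            order = np.argsort(vals)[::-1][:m]
        vals, vecs = vals[order], vecs[:, order]
        vecs = vecs / sq[:, None]
        vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
        real_mask = np.ones(m, dtype=bool)
    else:
        vals_c, vecs_c = sla.eig(P)
        order = np.argsort(-np.abs(vals_c))[:m]
        vals_c, vecs_c = vals_c[order], vecs_c[:, order]
        rel_imag = np.abs(vals_c.imag) / np.maximum(np.abs(vals_c), 1e-300)
        real_mask = rel_imag <= imag_tol
        if not np.all(real_mask):
            warnings.warn(
                f"eigenvalues at positions {np.flatnonzero(~real_mask).tolist()} "
                f"have relative imaginary parts above {imag_tol:g}; flagged in "
                f"real_mask", ComplexSpectrumWarning, stacklevel=2)
        vals = vals_c.real
        vecs = np.real(vecs_c)
        norms = np.linalg.norm(vecs, axis=0)
        norms[norms == 0] = 1.0
        vecs = vecs / norms
    vecs = _fix_signs(np.ascontiguousarray(vecs))
    if abs(vals[0] - 1.0) > 1e-8:
        warnings.warn(f"leading eigenvalue {vals[0]:.3e} deviates from 1",
                      UserWarning, stacklevel=2)
    return DiffusionEmbedding(eigenvalues=vals, eigenvectors=vecs,
                              kernel=kernel, operator_kind=operator_kind,
                              real_mask=real_mask)
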