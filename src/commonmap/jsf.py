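"""Jointly smooth functions (JSF): common variables via shared smooth subspaces.

Where alternating diffusion composes the two sensors' diffusion
operators, the JSF construction compares their spaces of smooth
functions directly.  For each sensor, the leading ``d`` diffusion
eigenfunctions span a subspace of functions that vary slowly over that
sensor's geometry.  Concatenating the two orthonormal bases into
``[U1 U2]`` and taking its SVD yields functions (the left singular
vectors) ordered by how well they can be represented in *both*
subspaces: a singular value of sqrt(2) means the function lies exactly
in the intersection — it is smooth with respect to both sensors — while
smaller values mark functions only one sensor considers smooth.

Joint smoothness is classified by the largest gap in the singular-value
sequence (jointly smooth functions cluster at sqrt(2) and the rest fall
off sharply).  Each candidate's roughness is additionally reported as
the normalized graph Dirichlet energy ``f^T (D - W) f / f^T D f``
against both sensors' kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .llr import LLRReport
from .sensing import SensorStream
from .spectral import (
    KernelSpec,
    gaussian_kernel,
    markov_normalize,
    median_pairwise_distance,
    spectral_embed,
    standardize_channels,
)

__all__ = [
    "JSFSet",
    "kernel_eigenbasis",
    "extract_jsf",
    "dirichlet_energy",
    "JointlySmoothFunctions",
    "JSFResults",
]


def _samples(s) -> np.ndarray:
    return s.samples if isinstance(s, SensorStream) else np.asarray(s, dtype=float)


def dirichlet_energy(f: np.ndarray, W: np.ndarray) -> float:
    """Normalized graph Dirichlet energy ``f^T(D-W)f / f^T D f``.

    Zero for constant f, invariant to rescaling f; larger values mean the
    function varies faster across strongly connected sample pairs.
    """
    f = np.asarray(f, dtype=float).ravel()
    if np.all(f == 0):
        raise ValueError("Dirichlet energy of the zero vector is undefined")
    if W.shape[0] != len(f):
        raise ValueError("kernel size does not match function length")
    d = W.sum(axis=1)
    num = float(f @ (d * f) - f @ (W @ f))
    den = float(f @ (d * f))
    return max(num / den, 0.0)


def kernel_eigenbasis(S, epsilon: float | None = None, d: int = 50,
                      alpha: float = 1.0, standardize: bool = True):
    """Orthonormal basis of the d smoothest functions of one sensor's geometry.

    Takes the leading eigenvectors of the sensor's (symmetrized)
    diffusion operator, maps them back to diffusion-map eigenfunctions
    (so the first is constant for a connected kernel) and re-orthonormalizes
    by QR.  Returns ``(U, W)`` with U the n x d basis and W the kernel it
    was built from.
    """
    X = _samples(S)
    if standardize:
        X = standardize_channels(X)
    n = X.shape[0]
    if d >= n:
        raise ValueError(f"basis size d={d} must be smaller than n={n}")
    if epsilon is None:
        epsilon = median_pairwise_distance(X) ** 2
    W = gaussian_kernel(X, epsilon)
    P, deg = markov_normalize(W, alpha, return_degrees=True)
    emb = spectral_embed(P, d, degrees=deg,
                         kernel=KernelSpec("gaussian", epsilon, alpha))
    U, _ = np.linalg.qr(emb.eigenvectors)
    # QR can flip signs; fix so the first basis vector is positive-constant
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    return U * signs, W


@dataclass
class JSFSet:
    """Candidate jointly smooth functions with scores and Dirichlet energies."""

    functions: np.ndarray          # n x m, orthonormal columns
    scores: np.ndarray             # singular values, non-increasing, <= sqrt(2)
    energies: np.ndarray           # m x 2, Dirichlet energy vs each sensor kernel
    smooth: np.ndarray             # boolean, jointly smooth per the gap rule
    score_threshold: float
    d1: int = 0
    d2: int = 0

    @property
    def n_smooth(self) -> int:
        return int(self.smooth.sum())

    def save(self, csv_path, json_path=None) -> None:
        import json as _json
        import pandas as pd
        csv_path = str(csv_path)
        if json_path is None:
            json_path = csv_path[:-4] + ".meta.json" if csv_path.endswith(".csv") \
                else csv_path + ".meta.json"
        pd.DataFrame(self.functions,
                     columns=[f"jsf{i}" for i in range(self.functions.shape[1])]
                     ).to_csv(csv_path, index=False, float_format="%.17g")
        with open(json_path, "w") as fh:
            _json.dump({"scores": self.scores.tolist(),
                        "energies": self.energies.tolist(),
                        "smooth": self.smooth.astype(int).tolist(),
                        "score_threshold": self.score_threshold,
                        "d1": self.d1, "d2": self.d2}, fh, indent=1)


def _score_gap_split(scores: np.ndarray, min_gap: float = 1e-3):
    """Smooth/rough split at the largest drop in the singular-value scores.

    A score of sqrt(2) means the function lies in both sensors' smooth
    subspaces; jointly smooth functions cluster there and the rest fall
    off sharply, so the largest consecutive drop separates the groups.
    If no drop exceeds ``min_gap`` (e.g. identical sensors, where every
    score is sqrt(2)) all functions count as smooth.
    """
    drops = -np.diff(scores)
    if len(drops) == 0 or drops.max() < min_gap:
        return np.ones(len(scores), dtype=bool), float(scores[-1] - min_gap)
    g = int(np.argmax(drops))
    thr = float(0.5 * (scores[g] + scores[g + 1]))
    return scores > thr, thr


def extract_jsf(S1, S2, d1: int = 50, d2: int = 50, n_functions: int = 10,
                eps1: float | None = None, eps2: float | None = None,
                alpha: float = 1.0, standardize: bool = True) -> JSFSet:
    """Extract candidate JSFs from two sensor streams.

    Concatenates the two sensors' d-dimensional smooth-function bases and
    takes the SVD; left singular vectors are the candidates, singular
    values (at most sqrt(2)) the joint-smoothness scores.  The first
    ``n_functions`` candidates are kept; those above the largest gap in
    the score sequence are classified jointly smooth.  Dirichlet
    energies against both sensors' kernels are reported alongside.
    """
    X1, X2 = _samples(S1), _samples(S2)
    n = X1.shape[0]
    if X2.shape[0] != n:
        raise ValueError("sensors must share the sample count")
    if d1 + d2 >= n:
        warnings.warn("d1 + d2 >= n: concatenated basis cannot have full rank",
                      UserWarning, stacklevel=2)
    U1, W1 = kernel_eigenbasis(X1, eps1, d1, alpha, standardize)
    U2, W2 = kernel_eigenbasis(X2, eps2, d2, alpha, standardize)
    F, s, _ = sla.svd(np.hstack([U1, U2]), full_matrices=False)
    m = min(n_functions, len(s))
    F, s = F[:, :m], s[:m]
    # sign convention: largest-magnitude entry positive
    signs = np.sign(F[np.argmax(np.abs(F), axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    F = F * signs

    energies = np.column_stack([
        [dirichlet_energy(F[:, j], W1) for j in range(m)],
        [dirichlet_energy(F[:, j], W2) for j in range(m)],
    ])
    smooth, thr = _score_gap_split(s)
    return JSFSet(functions=F, scores=s, energies=energies,
                  smooth=smooth, score_threshold=thr, d1=d1, d2=d2)


@dataclass
class JSFResults:
    """Fitted JSF model: functions, scores, energies, parsimony over smooth JSFs."""

    model: "JointlySmoothFunctions"
    jsf: JSFSet
    llr_report: LLRReport

    @property
    def n_smooth(self) -> int:
        return self.jsf.n_smooth

    @property
    def common_indices(self) -> list[int]:
        """Indices (into the JSF columns) of the unique smooth functions."""
        return list(self.llr_report.selected_indices)

    @property
    def common_coordinates(self) -> np.ndarray:
        return self.jsf.functions[:, self.common_indices]

    def summary(self) -> str:
        lines = [
            "Jointly-smooth-function model",
            "=" * 47,
            f"samples            : {self.jsf.functions.shape[0]}",
            f"basis sizes        : d1={self.jsf.d1}, d2={self.jsf.d2}",
            f"jointly smooth     : {self.n_smooth} of "
            f"{self.jsf.functions.shape[1]} (score gap at "
            f"{self.jsf.score_threshold:.3e})",
            f"parsimonious set   : {[f'jsf{j}' for j in self.common_indices]}",
            "",
            "  jsf   score    E(sensor1)   E(sensor2)   smooth",
        ]
        for j in range(self.jsf.functions.shape[1]):
            lines.append(
                f"  {j:3d} {self.jsf.scores[j]:7.4f}  {self.jsf.energies[j,0]:11.3e}"
                f"  {self.jsf.energies[j,1]:11.3e}   "
                f"{'yes' if self.jsf.smooth[j] else ''}")
        return "\n".join(lines)


class JointlySmoothFunctions:
    """JSF common-variable model for two simultaneous sensor streams.

    ``fit()`` extracts the candidate functions, classifies joint
    smoothness by the Dirichlet-energy gap, and runs LLR parsimony
    selection over the smooth ones (skipping the leading constant-like
    function) to find the minimal common parameterization.
    """

    def __init__(self, sensor1, sensor2, *, d1=50, d2=50, n_functions=10,
                 eps1=None, eps2=None, alpha=1.0, uniqueness_threshold=0.5):
        self.sensor1 = sensor1
        self.sensor2 = sensor2
        self.d1 = d1
        self.d2 = d2
        self.n_functions = n_functions
        self.eps1 = eps1
        self.eps2 = eps2
        self.alpha = alpha
        self.uniqueness_threshold = uniqueness_threshold

    def fit(self) -> JSFResults:
        jsf = extract_jsf(self.sensor1, self.sensor2, self.d1, self.d2,
                          self.n_functions, self.eps1, self.eps2, self.alpha)
        smooth_cols = np.flatnonzero(jsf.smooth)
        report = _parsimony_over(jsf.functions, smooth_cols,
                                 self.uniqueness_threshold)
        return JSFResults(model=self, jsf=jsf, llr_report=report)


def _parsimony_over(functions: np.ndarray, columns: np.ndarray,
                    threshold: float) -> LLRReport:
    """LLR parsimony over a chosen subset of JSF columns.

    The leading jointly smooth function is constant-like (both kernels'
    smoothest function); it plays the role of the trivial eigenvector and
    is skipped, exactly as in diffusion-map parsimony.
    """
    from .llr import llr_residual, default_bandwidth

    report = LLRReport(threshold=threshold)
    retained: list[int] = []
    candidates = [int(j) for j in columns
                  if np.std(functions[:, j]) > 1e-10 * np.abs(functions[:, j]).max()
                  and j != 0]
    for j in candidates:
        y = functions[:, j]
        if not retained:
            r, bw = llr_residual(None, y), np.nan
        else:
            X = functions[:, retained]
            bw = default_bandwidth(X)
            r = llr_residual(X, y, bw)
        report.residuals[j] = r
        report.bandwidths[j] = bw
        if r > threshold:
            retained.append(j)
    report.selected_indices = retained
    return report
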