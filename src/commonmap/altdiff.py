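"""Alternating diffusion: extracting the common variables of two sensor streams.

Each sensor induces a diffusion operator on the shared sample set from
the Euclidean geometry of its own observations.  Their matrix product —
the alternating-diffusion operator — damps sensor-specific directions
(each sensor's private variables look like fast-mixing noise to the
other) while directions shared by both sensors survive.  The leading
eigenvectors of the product therefore parameterize exactly the common
system, and LLR parsimony selection on them yields its dimension.

The product can be taken in either order.  Right eigenvectors of
``P1 @ P2`` lie in the range of ``P1`` — they are smooth with respect to
sensor 1's geometry — and vice versa.  Both orders parameterize the same
common structure, but when testing whether a *channel of sensor k* is a
function of the common variables, coordinates smoothed along sensor k's
own geometry are biased (they carry a trace of that sensor's private
directions).  The model therefore fits both orders and scores each
channel against the embedding smoothed by the *other* sensor.

`AlternatingDiffusionMaps` wraps this in a fit/results pattern:
construct it from two `SensorStream`s (or plain arrays), call ``fit()``,
and read the common dimension, coordinates and per-channel
identifiability off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .llr import LLRReport, channel_identifiability, select_parsimonious
from .sensing import SensorStream
from .spectral import (
    DiffusionEmbedding,
    gaussian_kernel,
    markov_normalize,
    median_pairwise_distance,
    spectral_embed,
    standardize_channels,
)

__all__ = [
    "AlternatingOperator",
    "alternating_operator",
    "common_embedding",
    "AlternatingDiffusionMaps",
    "AlternatingDiffusionResults",
]


def _samples(s) -> np.ndarray:
    return s.samples if isinstance(s, SensorStream) else np.asarray(s, dtype=float)


@dataclass
class AlternatingOperator:
    """Product of the two per-sensor Markov operators."""

    P_alt: np.ndarray
    eps1: float
    eps2: float
    alpha: float
    order: str = "P1@P2"

    def __post_init__(self) -> None:
        rs = self.P_alt.sum(axis=1)
        if np.max(np.abs(rs - 1.0)) > 1e-10:
            raise ValueError("alternating operator rows must sum to 1")
        if np.any(self.P_alt < -1e-15):
            raise ValueError("alternating operator entries must be nonnegative")


def _sensor_markov_pair(S1, S2, eps1, eps2, alpha, standardize):
    X1, X2 = _samples(S1), _samples(S2)
    if X1.shape[0] != X2.shape[0]:
        raise ValueError(
            f"sensors must share the sample grid (n1={X1.shape[0]}, "
            f"n2={X2.shape[0]})")
    if isinstance(S1, SensorStream) and isinstance(S2, SensorStream):
        if not np.array_equal(S1.sample_times, S2.sample_times):
            raise ValueError("sensor streams do not share sample_times")
    if standardize:
        X1, X2 = standardize_channels(X1), standardize_channels(X2)
    if eps1 is None:
        eps1 = median_pairwise_distance(X1) ** 2
    if eps2 is None:
        eps2 = median_pairwise_distance(X2) ** 2
    P1 = markov_normalize(gaussian_kernel(X1, eps1), alpha)
    P2 = markov_normalize(gaussian_kernel(X2, eps2), alpha)
    return P1, P2, float(eps1), float(eps2)


def alternating_operator(S1, S2, eps1: float | None = None,
                         eps2: float | None = None,
                         alpha: float = 1.0,
                         standardize: bool = True,
                         order: str = "P1@P2") -> AlternatingOperator:
    """Build the alternating operator from the two sensors' diffusions.

    Channels are standardized per sensor by default (heterogeneous
    channels can differ in scale by orders of magnitude); bandwidths then
    default per sensor to the square of that sensor's median pairwise
    distance.
    """
    if order not in ("P1@P2", "P2@P1"):
        raise ValueError("order must be 'P1@P2' or 'P2@P1'")
    P1, P2, eps1, eps2 = _sensor_markov_pair(S1, S2, eps1, eps2, alpha,
                                             standardize)
    P = P1 @ P2 if order == "P1@P2" else P2 @ P1
    return AlternatingOperator(P_alt=P, eps1=eps1, eps2=eps2, alpha=alpha,
                               order=order)


def common_embedding(op: AlternatingOperator,
                     n_eigenvectors: int = 20) -> DiffusionEmbedding:
    """Leading eigenpairs of the alternating operator (dense nonsymmetric solve).

    The product of two Markov matrices is not symmetric-similar in
    general, so a dense nonsymmetric eigensolver is used; eigenpairs with
    non-negligible imaginary parts are flagged and later excluded from
    LLR selection (on these data the leading spectrum is empirically
    real).
    """
    emb = spectral_embed(op.P_alt, n_eigenvectors, operator_kind="alternating")
    emb.provenance.update(eps1=op.eps1, eps2=op.eps2, alpha=op.alpha,
                          order=op.order)
    return emb


@dataclass
class AlternatingDiffusionResults:
    """Fitted common-variable model: embeddings for both operator orders.

    ``embedding``/``llr_report`` belong to the primary order (default
    ``P1@P2``); ``mirror_embedding``/``mirror_report`` to the reversed
    product.  Channel identifiability automatically picks the unbiased
    embedding for the channel's sensor.
    """

    model: "AlternatingDiffusionMaps"
    operator: AlternatingOperator
    embedding: DiffusionEmbedding
    llr_report: LLRReport
    mirror_operator: AlternatingOperator
    mirror_embedding: DiffusionEmbedding
    mirror_report: LLRReport

    @property
    def common_dimension(self) -> int:
        return self.llr_report.dimension

    @property
    def common_indices(self) -> list[int]:
        """Eigenvector column indices of the unique common directions."""
        return list(self.llr_report.selected_indices)

    @property
    def common_coordinates(self) -> np.ndarray:
        """n x d matrix of the parsimonious common embedding (primary order)."""
        return self.embedding.coordinates(self.common_indices)

    @property
    def mirror_coordinates(self) -> np.ndarray:
        return self.mirror_embedding.coordinates(self.mirror_report.selected_indices)

    def coordinates_for_sensor(self, sensor: int | None):
        """Coordinates smoothed by the *other* sensor's operator.

        Right eigenvectors of P1@P2 are sensor-1-smooth, hence unbiased
        for sensor-2 channels; the reversed product serves sensor 1.
        """
        primary_is_12 = self.operator.order == "P1@P2"
        if sensor == 1:
            return self.mirror_coordinates if primary_is_12 else self.common_coordinates
        if sensor == 2:
            return self.common_coordinates if primary_is_12 else self.mirror_coordinates
        return None

    def channel_identifiability(self, channel: np.ndarray,
                                sensor: int | None = None,
                                bandwidth: float | None = None) -> float:
        """LLR residual of a channel against the common coordinates.

        Near 0: the channel is a function of the common variables and is
        observable from the other sensor.  Near 1: it is dominated by
        sensor-specific dynamics.  Pass ``sensor=1`` or ``2`` for a
        channel measured by that sensor so the unbiased (cross-smoothed)
        embedding is used; with ``sensor=None`` (an external reference
        variable) the smaller residual over the two orders is returned.
        """
        coords = self.coordinates_for_sensor(sensor)
        if coords is not None:
            return channel_identifiability(coords, channel, bandwidth)
        return min(
            channel_identifiability(self.common_coordinates, channel, bandwidth),
            channel_identifiability(self.mirror_coordinates, channel, bandwidth))

    def identifiability_table(self, channels: dict[str, np.ndarray],
                              sensor: int | None = None) -> dict[str, float]:
        return {name: self.channel_identifiability(col, sensor)
                for name, col in channels.items()}

    def summary(self) -> str:
        lines = [
            "Alternating-diffusion common-variable model",
            "=" * 47,
            f"samples                 : {self.embedding.eigenvectors.shape[0]}",
            f"kernel bandwidths       : eps1={self.operator.eps1:.6g}, "
            f"eps2={self.operator.eps2:.6g} (alpha={self.operator.alpha:g})",
            f"primary order           : {self.operator.order}",
            f"common dimension (LLR)  : {self.common_dimension}"
            f"  (reversed order: {self.mirror_report.dimension})",
            f"unique eigenvectors     : "
            f"{[f'phi{j+1}' for j in self.common_indices]}",
            "",
            "  eigvec   |lambda|   LLR residual   unique",
        ]
        for j in sorted(self.llr_report.residuals):
            r = self.llr_report.residuals[j]
            mark = "yes" if j in self.llr_report.selected_indices else ""
            lines.append(f"  phi{j+1:<4d} {abs(self.embedding.eigenvalues[j]):9.4f}"
                         f"   {r:12.4f}   {mark}")
        return "\n".join(lines)


class AlternatingDiffusionMaps:
    """Common-variable discovery model for two simultaneous sensor streams.

    Parameters
    ----------
    sensor1, sensor2 : SensorStream or array-like (n x c)
        Simultaneous observations on a shared sample grid.
    eps1, eps2 : float, optional
        Gaussian-kernel bandwidths; default = squared median pairwise
        distance per (standardized) sensor.
    alpha : float
        Density-normalization exponent (1 = density invariant).
    standardize : bool
        Standardize channels per sensor before kernel construction.
    n_eigenvectors : int
        Number of leading eigenpairs to compute.
    uniqueness_threshold : float
        LLR residual above which an eigenvector counts as a new direction.
    order : str
        Primary product order, "P1@P2" (default) or "P2@P1"; the reversed
        order is fitted alongside for unbiased channel identifiability.
    """

    def __init__(self, sensor1, sensor2, *, eps1=None, eps2=None, alpha=1.0,
                 standardize=True, n_eigenvectors=20, uniqueness_threshold=0.5,
                 llr_bandwidth=None, max_k=None, order="P1@P2"):
        if order not in ("P1@P2", "P2@P1"):
            raise ValueError("order must be 'P1@P2' or 'P2@P1'")
        self.sensor1 = sensor1
        self.sensor2 = sensor2
        self.eps1 = eps1
        self.eps2 = eps2
        self.alpha = alpha
        self.standardize = standardize
        self.n_eigenvectors = n_eigenvectors
        self.uniqueness_threshold = uniqueness_threshold
        self.llr_bandwidth = llr_bandwidth
        self.max_k = max_k
        self.order = order

    def fit(self) -> AlternatingDiffusionResults:
        P1, P2, eps1, eps2 = _sensor_markov_pair(
            self.sensor1, self.sensor2, self.eps1, self.eps2, self.alpha,
            self.standardize)
        prod = {"P1@P2": P1 @ P2, "P2@P1": P2 @ P1}
        mirror_order = "P2@P1" if self.order == "P1@P2" else "P1@P2"
        ops, embs, reps = {}, {}, {}
        for o in (self.order, mirror_order):
            ops[o] = AlternatingOperator(P_alt=prod[o], eps1=eps1, eps2=eps2,
                                         alpha=self.alpha, order=o)
            embs[o] = common_embedding(ops[o], self.n_eigenvectors)
            reps[o] = select_parsimonious(
                embs[o], max_k=self.max_k,
                uniqueness_threshold=self.uniqueness_threshold,
                bandwidth=self.llr_bandwidth)
        return AlternatingDiffusionResults(
            model=self, operator=ops[self.order], embedding=embs[self.order],
            llr_report=reps[self.order], mirror_operator=ops[mirror_order],
            mirror_embedding=embs[mirror_order], mirror_report=reps[mirror_order])
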