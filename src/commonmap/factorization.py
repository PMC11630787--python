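"""Factoring one sensor's geometry into common and uncommon coordinates.

Alternating diffusion (or JSF) recovers the *common* variables, but each
sensor also carries private state — and when channels are mixed, no
individual channel is a function of the common variables at all.  The
remedy is to re-embed a single sensor with the *output-informed* kernel,
using the common embedding as the designated output response.  The
kernel resolves, in order, the input directions that move the output
(the common system) and only then the directions along its level sets
(the sensor-specific system).  Running LLR parsimony on the resulting
eigenvectors and testing each unique one for predictability from the
common coordinates tags it ``common`` or ``uncommon``; harmonics are
tagged ``harmonic``.  The uncommon-tagged eigenvectors parameterize the
level sets of consistent measurements — the sensor-specific state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .llr import LLRReport, channel_identifiability, select_parsimonious
from .sensing import SensorStream
from .spectral import (
    DiffusionEmbedding,
    KernelSpec,
    gaussian_kernel,
    markov_normalize,
    median_pairwise_distance,
    output_informed_kernel,
    spectral_embed,
    standardize_channels,
)

__all__ = [
    "DegenerateOutputWarning",
    "factor_common_uncommon",
    "SensorFactorization",
    "SensorFactorizationResults",
]


class DegenerateOutputWarning(UserWarning):
    """The output response is (nearly) constant; fell back to plain diffusion."""


def _samples(s) -> np.ndarray:
    return s.samples if isinstance(s, SensorStream) else np.asarray(s, dtype=float)


def _coords(c) -> np.ndarray:
    if isinstance(c, DiffusionEmbedding):
        raise TypeError("pass the selected common coordinate matrix, not the "
                        "full embedding")
    c = np.asarray(c, dtype=float)
    return c[:, None] if c.ndim == 1 else c


def factor_common_uncommon(sensor, common_coords, epsilon: float = 0.5,
                           n_eigenvectors: int = 20, alpha: float = 1.0,
                           uniqueness_threshold: float = 0.5,
                           identifiability_threshold: float = 0.5,
                           standardize: bool = True
                           ) -> tuple[DiffusionEmbedding, LLRReport]:
    """Output-informed embedding of one sensor, tagged common/uncommon.

    Sensor samples and the common coordinates are each rescaled to unit
    median pairwise distance, the output-informed kernel is built with
    the common coordinates as the output response, and the resulting
    diffusion eigenvectors are classified:

    * ``harmonic`` — repeats an earlier unique direction (low LLR
      residual against the retained set);
    * ``common`` — unique and predictable from the common coordinates;
    * ``uncommon`` — unique and *not* predictable: a sensor-specific
      direction along the common level sets.

    Returns the tagged embedding and the parsimony report.
    """
    Y = _samples(sensor)
    f = _coords(common_coords)
    if Y.shape[0] != f.shape[0]:
        raise ValueError("sensor and common coordinates must share sample count")

    if standardize:
        Y = standardize_channels(Y)
    Y = Y / median_pairwise_distance(Y)
    f_scale = np.ptp(f, axis=0).max()
    if f_scale < 1e-12 or f.std(axis=0).max() < 1e-12:
        warnings.warn("common coordinates are degenerate (constant); using a "
                      "plain Gaussian kernel instead", DegenerateOutputWarning,
                      stacklevel=2)
        W = gaussian_kernel(Y, epsilon)
        kind = "gaussian"
    else:
        f = f / median_pairwise_distance(f)
        W = output_informed_kernel(Y, f, epsilon)
        kind = "output_informed"
    P, deg = markov_normalize(W, alpha, return_degrees=True)
    emb = spectral_embed(P, n_eigenvectors, degrees=deg,
                         kernel=KernelSpec(kind, epsilon, alpha),
                         operator_kind="output_informed")

    report = select_parsimonious(emb, uniqueness_threshold=uniqueness_threshold)
    tags = ["trivial"] + ["harmonic"] * (emb.n_eigenvectors - 1)
    if kind == "gaussian":
        # no output response: nothing can be tagged common
        for j in report.selected_indices:
            tags[j] = "uncommon"
    else:
        for j in report.selected_indices:
            r = channel_identifiability(f, emb.eigenvectors[:, j])
            tags[j] = "common" if r < identifiability_threshold else "uncommon"
    emb.tags = tags
    return emb, report


@dataclass
class SensorFactorizationResults:
    """Tagged output-informed embedding of a single sensor."""

    model: "SensorFactorization"
    embedding: DiffusionEmbedding
    llr_report: LLRReport

    @property
    def common_indices(self) -> list[int]:
        return [j for j, t in enumerate(self.embedding.tags) if t == "common"]

    @property
    def uncommon_indices(self) -> list[int]:
        return [j for j, t in enumerate(self.embedding.tags) if t == "uncommon"]

    @property
    def uncommon_coordinates(self) -> np.ndarray:
        """Parameterization of the sensor-specific level sets."""
        return self.embedding.coordinates(self.uncommon_indices)

    def summary(self) -> str:
        lines = [
            "Output-informed sensor factorization",
            "=" * 47,
            f"common eigenvectors   : {[f'phi{j+1}' for j in self.common_indices]}",
            f"uncommon eigenvectors : {[f'phi{j+1}' for j in self.uncommon_indices]}",
            "",
            "  eigvec   |lambda|   LLR residual   tag",
        ]
        for j in range(1, self.embedding.n_eigenvectors):
            r = self.llr_report.residuals.get(j, float("nan"))
            lines.append(f"  phi{j+1:<4d} {abs(self.embedding.eigenvalues[j]):9.4f}"
                         f"   {r:12.4f}   {self.embedding.tags[j]}")
        return "\n".join(lines)


class SensorFactorization:
    """Model: factor one sensor's geometry against a given common embedding.

    Parameters mirror :func:`factor_common_uncommon`; ``fit()`` returns a
    results object exposing the common/uncommon coordinate split.
    """

    def __init__(self, sensor, common_coords, *, epsilon=0.5, n_eigenvectors=20,
                 alpha=1.0, uniqueness_threshold=0.5,
                 identifiability_threshold=0.5, standardize=True):
        self.sensor = sensor
        self.common_coords = common_coords
        self.epsilon = epsilon
        self.n_eigenvectors = n_eigenvectors
        self.alpha = alpha
        self.uniqueness_threshold = uniqueness_threshold
        self.identifiability_threshold = identifiability_threshold
        self.standardize = standardize

    def fit(self) -> SensorFactorizationResults:
        emb, report = factor_common_uncommon(
            self.sensor, self.common_coords, self.epsilon, self.n_eigenvectors,
            self.alpha, self.uniqueness_threshold, self.identifiability_threshold,
            self.standardize)
        return SensorFactorizationResults(model=self, embedding=emb,
                                          llr_report=report)
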