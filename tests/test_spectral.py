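"""Kernel and eigendecomposition tests, incl. analytic circle eigenfunctions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commonmap.spectral import (
    DiffusionEmbedding,
    IsolatedSampleError,
    KernelSpec,
    gaussian_kernel,
    markov_normalize,
    median_pairwise_distance,
    output_informed_kernel,
    spectral_embed,
    standardize_channels,
)


@st.composite
def point_clouds(draw):
    n = draw(st.integers(5, 30))
    d = draw(st.integers(1, 4))
    data = draw(st.lists(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=d, max_size=d),
        min_size=n, max_size=n))
    x = np.asarray(data)
    # jitter guarantees distinct points (degenerate clouds have no bandwidth)
    return x + np.linspace(0.0, 1.0, n)[:, None]


class TestGaussianKernel:
    @settings(max_examples=25, deadline=None)
    @given(point_clouds())
    def test_symmetric_unit_diagonal_bounded(self, x):
        W = gaussian_kernel(x)
        assert np.allclose(np.diag(W), 1.0)
        assert np.allclose(W, W.T)
        # entries in (0, 1]; far pairs may underflow to exactly 0
        assert W.min() >= 0 and W.max() <= 1.0 + 1e-12

    def test_entries_decrease_with_distance(self):
        x = np.arange(6.0)[:, None]
        W = gaussian_kernel(x, epsilon=2.0)
        row = W[0]
        assert np.all(np.diff(row) < 0)

    def test_default_bandwidth_is_squared_median_distance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 2))
        eps = median_pairwise_distance(x) ** 2
        np.testing.assert_allclose(gaussian_kernel(x), gaussian_kernel(x, eps))


class TestOutputInformedKernel:
    def test_constant_output_reduces_to_gaussian(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 3))
        f = np.ones((30, 2))
        np.testing.assert_allclose(output_informed_kernel(x, f, 0.7),
                                   gaussian_kernel(x, 0.7))

    def test_identical_points_and_outputs_give_unit_affinity(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        f = np.array([[3.0], [3.0], [1.0]])
        W = output_informed_kernel(x, f, 0.5)
        assert W[0, 1] == pytest.approx(1.0)

    def test_printed_scale_convention(self):
        # eps = 0.5, ||df|| = 0.5, ||dy||^2 = 0.5: exponent -1 - 1 -> e^-2
        x = np.array([[0.0], [np.sqrt(0.5)]])
        f = np.array([[0.0], [0.5]])
        W = output_informed_kernel(x, f, 0.5)
        assert W[0, 1] == pytest.approx(np.exp(-2.0))

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        W = output_informed_kernel(rng.standard_normal((20, 2)),
                                   rng.standard_normal((20, 1)), 0.5)
        assert np.allclose(W, W.T)


class TestMarkovNormalize:
    @settings(max_examples=25, deadline=None)
    @given(point_clouds(), st.sampled_from([0.0, 0.5, 1.0]))
    def test_rows_sum_to_one(self, x, alpha):
        P = markov_normalize(gaussian_kernel(x), alpha)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_vector_is_unit_eigenvector(self):
        rng = np.random.default_rng(3)
        P = markov_normalize(gaussian_kernel(rng.standard_normal((25, 2))), 1.0)
        np.testing.assert_allclose(P @ np.ones(25), np.ones(25), atol=1e-12)

    def test_alpha_zero_is_plain_row_normalization(self):
        rng = np.random.default_rng(4)
        W = gaussian_kernel(rng.standard_normal((20, 2)))
        P = markov_normalize(W, 0.0)
        np.testing.assert_allclose(P, W / W.sum(axis=1, keepdims=True))

    def test_isolated_sample_raises(self):
        W = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(IsolatedSampleError, match="row 1"):
            markov_normalize(W, 1.0)


class TestSpectralEmbed:
    def test_leading_pair_is_trivial(self):
        rng = np.random.default_rng(5)
        P, deg = markov_normalize(gaussian_kernel(rng.standard_normal((60, 2))),
                                  1.0, return_degrees=True)
        emb = spectral_embed(P, 5, degrees=deg)
        assert emb.eigenvalues[0] == pytest.approx(1.0, abs=1e-8)
        phi1 = emb.eigenvectors[:, 0]
        assert np.ptp(phi1) < 1e-6 * np.abs(phi1).max()

    def test_eigenvalues_sorted_by_modulus(self):
        rng = np.random.default_rng(6)
        P = markov_normalize(gaussian_kernel(rng.standard_normal((40, 3))), 1.0)
        emb = spectral_embed(P, 10)
        assert np.all(np.diff(np.abs(emb.eigenvalues)) <= 1e-12)

    def test_symmetric_and_dense_paths_agree(self):
        """Symmetrized-conjugate solve matches brute-force dense eig (n<=200)."""
        rng = np.random.default_rng(7)
        for n in (50, 200):
            x = rng.standard_normal((n, 2))
            P, deg = markov_normalize(gaussian_kernel(x), 1.0,
                                      return_degrees=True)
            sym = spectral_embed(P, 8, degrees=deg)
            dense = spectral_embed(P, 8)
            np.testing.assert_allclose(sym.eigenvalues, dense.eigenvalues,
                                       atol=1e-8)
            overlap = np.abs(np.einsum("ij,ij->j", sym.eigenvectors,
                                       dense.eigenvectors))
            np.testing.assert_allclose(overlap, 1.0, atol=1e-6)

    def test_circle_embedding_recovers_angle(self, circle_points):
        """(phi2, phi3) reproduce the Fourier eigenfunctions of the circle.

        The diffusion eigenfunctions of a uniform circle are
        cos(k*theta), sin(k*theta); the leading nontrivial pair must
        recover the angle up to rotation/reflection, i.e. preserve the
        circular ordering exactly.
        """
        theta, pts = circle_points
        P, deg = markov_normalize(gaussian_kernel(pts, 0.1), 1.0,
                                  return_degrees=True)
        emb = spectral_embed(P, 5, degrees=deg)
        phi = standardize_channels(emb.eigenvectors[:, 1:3])
        rec = np.arctan2(phi[:, 1], phi[:, 0])
        # align: rotate recovered angle, fix orientation
        rec = np.mod(rec - rec[0], 2 * np.pi)
        if rec[1] > np.pi:
            rec = np.mod(-rec, 2 * np.pi)
        # points are in increasing true angle; recovered must be monotone
        assert np.all(np.diff(rec) > 0)
        # and uniformly spread, as for the analytic eigenfunctions
        assert np.corrcoef(theta, rec)[0, 1] > 0.9999


class TestEmbeddingIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        P, deg = markov_normalize(gaussian_kernel(rng.standard_normal((30, 2))),
                                  1.0, return_degrees=True)
        emb = spectral_embed(P, 6, degrees=deg,
                             kernel=KernelSpec("gaussian", 1.5, 1.0))
        emb.save(tmp_path / "emb.csv")
        back = DiffusionEmbedding.load(tmp_path / "emb.csv")
        np.testing.assert_allclose(back.eigenvectors, emb.eigenvectors,
                                   rtol=1e-14)
        np.testing.assert_allclose(back.eigenvalues, emb.eigenvalues)
        assert back.kernel == emb.kernel
        assert back.operator_kind == emb.operator_kind
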