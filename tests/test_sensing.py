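"""Sensor assembly tests: delays, shifts, mixing, stream IO."""

import numpy as np
import pytest

from commonmap.dynamics import Trajectory
from commonmap.sensing import (
    MIXING_SENSOR1,
    MIXING_SENSOR2,
    ChannelSpec,
    CoverageError,
    RankDeficientWarning,
    SensorStream,
    StreamConfig,
    apply_mixing,
    assemble_sensor,
    make_experiment_streams,
)
from commonmap.spectral import standardize_channels


@pytest.fixture()
def toy_trajectory():
    t = np.arange(0.0, 100.0, 1.0)
    states = np.column_stack([np.sin(0.1 * t), np.cos(0.1 * t)])
    return {"X": Trajectory(times=t, states=states, labels=["a", "b"])}


class TestAssembly:
    def test_zero_delay_channel_is_raw_variable(self, toy_trajectory):
        grid = np.arange(10.0, 50.0, 1.0)
        s = assemble_sensor(toy_trajectory, [ChannelSpec("X", "a")], grid)
        np.testing.assert_array_equal(
            s.samples[:, 0], toy_trajectory["X"].column("a")[10:50])

    def test_delayed_channel_is_shifted_copy(self, toy_trajectory):
        grid = np.arange(10.0, 50.0, 1.0)
        s = assemble_sensor(toy_trajectory,
                            [ChannelSpec("X", "a"),
                             ChannelSpec("X", "a", delay=5.0)], grid)
        np.testing.assert_array_equal(s.samples[5:, 1], s.samples[:-5, 0])

    def test_shifted_channel_reads_the_future(self, toy_trajectory):
        grid = np.arange(10.0, 50.0, 1.0)
        now = assemble_sensor(toy_trajectory, [ChannelSpec("X", "a")], grid)
        fut = assemble_sensor(toy_trajectory,
                              [ChannelSpec("X", "a", shift=7.0)], grid)
        later = assemble_sensor(toy_trajectory, [ChannelSpec("X", "a")],
                                grid + 7.0)
        np.testing.assert_array_equal(fut.samples, later.samples)
        assert not np.array_equal(fut.samples, now.samples)

    def test_delay_and_shift_compose(self, toy_trajectory):
        grid = np.arange(20.0, 60.0, 1.0)
        combo = assemble_sensor(toy_trajectory,
                                [ChannelSpec("X", "a", delay=4.0, shift=9.0)],
                                grid)
        manual = assemble_sensor(toy_trajectory, [ChannelSpec("X", "a")],
                                 grid - 4.0 + 9.0)
        np.testing.assert_array_equal(combo.samples, manual.samples)

    def test_coverage_error_names_channel(self, toy_trajectory):
        grid = np.arange(0.0, 40.0, 1.0)
        with pytest.raises(CoverageError, match=r"a\(X\)"):
            assemble_sensor(toy_trajectory,
                            [ChannelSpec("X", "a", delay=5.0)], grid)

    def test_off_grid_delay_rejected(self, toy_trajectory):
        grid = np.arange(10.0, 50.0, 1.0)
        with pytest.raises(ValueError, match="integer multiples"):
            assemble_sensor(toy_trajectory,
                            [ChannelSpec("X", "a", delay=0.5)], grid)


class TestMixing:
    def test_identity_mixing_is_noop(self, toy_trajectory):
        grid = np.arange(10.0, 50.0, 1.0)
        s = assemble_sensor(toy_trajectory,
                            [ChannelSpec("X", "a"), ChannelSpec("X", "b")], grid)
        mixed = apply_mixing(s, np.eye(2))
        np.testing.assert_array_equal(mixed.samples, s.samples)
        assert mixed.mixed

    def test_mixing_inverts_exactly(self, toy_trajectory):
        grid = np.arange(10.0, 50.0, 1.0)
        s = assemble_sensor(toy_trajectory,
                            [ChannelSpec("X", "a"), ChannelSpec("X", "b")], grid)
        M = np.array([[1.0, 2.0], [0.5, -1.0]])
        mixed = apply_mixing(s, M)
        np.testing.assert_allclose(mixed.samples @ np.linalg.inv(M), s.samples,
                                   atol=1e-12)

    def test_mixing_is_linear(self):
        rng = np.random.default_rng(3)
        A, B = rng.standard_normal((2, 30, 4))
        M = rng.standard_normal((4, 4))
        np.testing.assert_allclose((2.0 * A + 3.0 * B) @ M,
                                   2.0 * (A @ M) + 3.0 * (B @ M), atol=1e-12)

    def test_rank_deficient_mixing_warns(self, toy_trajectory):
        grid = np.arange(10.0, 50.0, 1.0)
        s = assemble_sensor(toy_trajectory,
                            [ChannelSpec("X", "a"), ChannelSpec("X", "b")], grid)
        with pytest.warns(RankDeficientWarning):
            apply_mixing(s, np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_printed_mixing_matrices_have_full_rank(self):
        assert np.linalg.matrix_rank(MIXING_SENSOR1) == 4
        assert np.linalg.matrix_rank(MIXING_SENSOR2) == 4
        assert MIXING_SENSOR1[0] == pytest.approx([0.3637, -0.0173, -0.3701,
                                                   0.1013])


class TestExperimentStreams:
    @pytest.fixture(scope="class")
    def tiny(self):
        return make_experiment_streams("clean", StreamConfig(n_samples=400))

    def test_streams_share_sample_times(self, tiny):
        s1, s2, gt = tiny
        np.testing.assert_array_equal(s1.sample_times, s2.sample_times)
        np.testing.assert_array_equal(s1.sample_times, gt["time"])

    def test_clean_channel_lists(self, tiny):
        s1, s2, _ = tiny
        assert [c.name for c in s1.channel_meta] == [
            "theta_A(X)(t)", "theta_A(Y)(t)", "theta_A(X)(t-200)",
            "theta_A(Y)(t-200)"]
        assert [c.name for c in s2.channel_meta] == [
            "theta_B(X)(t)", "y(Z)(t)", "theta_B(X)(t-200)", "y(Z)(t-200)"]

    def test_clean_delay_channels_are_lagged_copies(self, tiny):
        s1, _, _ = tiny
        lag = 20                         # 200 time units / step 10
        np.testing.assert_array_equal(s1.samples[lag:, 2], s1.samples[:-lag, 0])

    def test_clean_channels_match_ground_truth(self, tiny):
        s1, s2, gt = tiny
        np.testing.assert_array_equal(s1.samples[:, 0], gt["theta_A(X)"])
        np.testing.assert_array_equal(s2.samples[:, 1], gt["y(Z)"])

    def test_causal1_sensor2_sees_future_common_system(self):
        s1, s2, gt = make_experiment_streams("causal1",
                                             StreamConfig(n_samples=300))
        shift = 20                       # tau = 200 / step 10
        np.testing.assert_allclose(s2.samples[:-shift, 0],
                                   gt["theta_A(X)"][shift:], atol=1e-12)
        np.testing.assert_array_equal(s1.samples[:, 0], gt["theta_A(X)"])

    def test_mixed_streams_apply_printed_matrices(self):
        s1, s2, gt = make_experiment_streams("mixed",
                                             StreamConfig(n_samples=300))
        assert s1.mixed and s2.mixed
        clean1 = standardize_channels(np.column_stack(
            [gt["theta_A(X)"], gt["theta_B(X)"], gt["theta_A(Y)"],
             gt["theta_B(Y)"]]))
        np.testing.assert_allclose(s1.samples, clean1 @ MIXING_SENSOR1,
                                   atol=1e-12)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown experiment"):
            make_experiment_streams("bogus", StreamConfig(n_samples=300))


class TestStreamIO:
    def test_round_trip_preserves_samples_and_provenance(self, tmp_path):
        rng = np.random.default_rng(0)
        s = SensorStream(samples=rng.standard_normal((50, 3)),
                         channel_meta=[ChannelSpec("X", "theta_A"),
                                       ChannelSpec("Y", "theta_A", delay=20.0),
                                       ChannelSpec("Z", "y", shift=10.0)],
                         sample_times=np.arange(50.0))
        s.save(tmp_path / "s.csv")
        back = SensorStream.load(tmp_path / "s.csv")
        np.testing.assert_allclose(back.samples, s.samples, rtol=1e-15)
        assert back.channel_meta == s.channel_meta
        assert not back.mixed
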