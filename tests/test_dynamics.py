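"""Simulator tests: vector fields, attractor properties, period estimation."""

import numpy as np
import pytest

from commonmap.dynamics import (
    AperiodicWarning,
    ForcingParams,
    LorenzParams,
    NotPeriodicError,
    ReactionParams,
    Trajectory,
    estimate_period,
    lorenz_rhs,
    reaction_rhs,
    simulate_forced_reaction,
    simulate_lorenz,
    simulate_reaction,
)


class TestVectorFields:
    def test_empty_surface_rates_are_adsorption_constants(self):
        # with nothing adsorbed, coverage grows at the bare adsorption rates
        p = ReactionParams()
        assert reaction_rhs((0.0, 0.0), p) == pytest.approx([p.alpha1, p.alpha2])

    def test_lorenz_origin_is_fixed_point(self):
        assert lorenz_rhs((0.0, 0.0, 0.0)) == pytest.approx([0.0, 0.0, 0.0])

    def test_lorenz_nontrivial_equilibria(self):
        p = LorenzParams()
        c = np.sqrt(p.beta * (p.rho - 1))
        for s in (+1, -1):
            assert lorenz_rhs((s * c, s * c, p.rho - 1), p) == pytest.approx(
                [0.0, 0.0, 0.0], abs=1e-12)

    def test_lorenz_divergence_is_constant(self):
        # div F = -(sigma + 1 + beta) independently of the state
        p = LorenzParams()
        rng = np.random.default_rng(7)
        h = 1e-6
        for state in rng.uniform(-20, 20, size=(10, 3)):
            div = sum(
                (lorenz_rhs(state + h * e, p)[i] - lorenz_rhs(state - h * e, p)[i])
                / (2 * h)
                for i, e in enumerate(np.eye(3)))
            assert div == pytest.approx(-(p.sigma + 1 + p.beta), rel=1e-5)


class TestReactionSimulation:
    def test_sustained_oscillation_on_limit_cycle(self, x_trajectory):
        th = x_trajectory.column("theta_A")
        assert np.ptp(th) > 0.01                        # non-constant
        # recurrent: some later sample returns to the initial post-burn-in state
        d = np.abs(th[100:] - th[0])
        assert d.min() < 1e-3 * np.ptp(th)

    def test_coverages_stay_physical(self, x_trajectory):
        # >= 10 periods sampled; coverages remain in the simplex
        tA = x_trajectory.column("theta_A")
        tB = x_trajectory.column("theta_B")
        assert tA.min() > -1e-9 and tB.min() > -1e-9
        assert (tA + tB).max() <= 1.0 + 1e-9

    def test_invalid_initial_coverage_rejected(self):
        with pytest.raises(ValueError, match="initial coverages"):
            simulate_reaction(initial_state=(0.8, 0.8), t_end=100, burn_in=0)

    def test_zero_amplitude_forcing_matches_autonomous(self):
        f = ForcingParams(A=0.0)
        p = ReactionParams(alpha1=0.019)
        forced = simulate_forced_reaction(p, f, t_end=3000, dt_out=10, burn_in=0)
        auto = simulate_reaction(ReactionParams(alpha1=0.019, alpha2=f.A0),
                                 t_end=3000, dt_out=10, burn_in=0)
        np.testing.assert_allclose(forced.states, auto.states, atol=1e-7)

    def test_forced_dynamics_quasiperiodic(self):
        """Power spectrum has two incommensurate basic frequencies.

        The dominant peak is the oscillation fundamental; harmonics of it
        are excluded, and the strongest remaining peak (the forcing
        response) must not be a small-integer fraction of it.
        """
        traj = simulate_forced_reaction(ReactionParams(alpha1=0.019),
                                        t_end=8000 + 4096 * 10, dt_out=10.0,
                                        burn_in=8000.0)
        y = traj.column("theta_A")
        y = (y - y.mean()) * np.hanning(len(y))
        power = np.abs(np.fft.rfft(y)) ** 2
        freq = np.fft.rfftfreq(len(y), d=10.0)
        f1 = freq[np.argmax(power[1:]) + 1]
        # strongest peak that is not a near-multiple of f1
        mask = np.ones_like(power, dtype=bool)
        mask[0] = False
        mult = freq / f1
        mask &= np.abs(mult - np.round(mult)) > 0.03
        f2 = freq[mask][np.argmax(power[mask])]
        ratio = max(f1, f2) / min(f1, f2)
        for q in range(1, 5):
            assert abs(ratio - round(ratio * q) / q) > 1e-2, \
                f"ratio {ratio} commensurate with denominator {q}"


class TestPeriodEstimation:
    def test_recovers_known_sine_period(self):
        t = np.arange(0, 50, 0.01)
        traj = Trajectory(times=t, states=np.sin(2 * np.pi * t / 7.3),
                          labels=["s"])
        est = estimate_period(traj, ("s", 0.0, +1))
        assert est.period == pytest.approx(7.3, rel=1e-3)
        assert est.cv < 1e-6

    def test_limit_cycle_period_near_four_tau(self, x_trajectory):
        # tau = 200 time units is about a quarter of the cycle
        est = estimate_period(x_trajectory)
        assert 0.22 <= 200.0 / est.period <= 0.28
        assert est.cv < 1e-3

    def test_period_invariant_to_section_level(self, x_trajectory):
        th = x_trajectory.column("theta_A")
        ref = estimate_period(x_trajectory, (0, None, +1)).period
        for level in (th.mean() - 0.3 * th.std(), th.mean() + 0.3 * th.std()):
            p = estimate_period(x_trajectory, (0, level, +1)).period
            assert p == pytest.approx(ref, rel=5e-3)

    def test_refining_output_step_preserves_period(self):
        periods = []
        for dt in (10.0, 5.0):
            traj = simulate_reaction(t_end=28000, dt_out=dt, burn_in=8000)
            periods.append(estimate_period(traj).period)
        assert periods[0] == pytest.approx(periods[1], rel=1e-3)

    def test_lorenz_flagged_aperiodic(self):
        traj = simulate_lorenz(t_end=250, dt_out=0.05, burn_in=50)
        with pytest.warns(AperiodicWarning):
            estimate_period(traj, ("x", 0.0, +1))

    def test_too_few_crossings_raises(self):
        t = np.arange(0, 3, 0.01)
        traj = Trajectory(times=t, states=np.sin(2 * np.pi * t / 10.0),
                          labels=["s"])
        with pytest.raises(NotPeriodicError):
            estimate_period(traj, ("s", 0.0, +1))


class TestTrajectoryIO:
    def test_csv_round_trip_lossless(self, tmp_path, x_trajectory):
        path = tmp_path / "traj.csv"
        x_trajectory.save(path)
        back = Trajectory.load(path)
        np.testing.assert_allclose(back.states, x_trajectory.states, rtol=1e-15)
        np.testing.assert_allclose(back.times, x_trajectory.times, rtol=1e-15)
        assert back.labels == x_trajectory.labels

    def test_npz_round_trip(self, tmp_path, x_trajectory):
        path = tmp_path / "traj.npz"
        x_trajectory.save_npz(path)
        back = Trajectory.load_npz(path)
        np.testing.assert_array_equal(back.states, x_trajectory.states)
        assert back.labels == x_trajectory.labels
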