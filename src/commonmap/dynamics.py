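"""Benchmark dynamical systems: periodic, quasiperiodic and chaotic responses.

Three ODE systems provide the test bed for cross-sensor common-variable
discovery:

* ``X`` — a nondimensionalized two-species surface-reaction model (a
  Langmuir--Hinshelwood variant requiring two empty sites in the surface
  step) whose state is the pair of fractional coverages ``(theta_A,
  theta_B)``.  At the default rate constants it settles onto a stable
  limit cycle.
* ``Y`` — the same reaction model with the ``alpha2`` rate replaced by a
  sinusoidal forcing ``A0 + A*cos(omega*t)`` (a periodic perturbation of
  the gas-phase pressure of species B), producing quasiperiodic long-term
  dynamics at the default parameters.
* ``Z`` — the Lorenz system at the classical chaotic parameter values.

All simulators integrate with a stiff-capable adaptive method (LSODA,
``rtol=1e-8``, ``atol=1e-10``) and return the post-burn-in trajectory
resampled onto a uniform output grid, so that sensor streams built from
different systems share one sampling step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ReactionParams",
    "ForcingParams",
    "LorenzParams",
    "Trajectory",
    "PeriodEstimate",
    "IntegrationError",
    "NotPeriodicError",
    "AperiodicWarning",
    "simulate_reaction",
    "simulate_forced_reaction",
    "simulate_lorenz",
    "estimate_period",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite state."""


class NotPeriodicError(ValueError):
    """Raised when a trajectory has too few section crossings to define a period."""


class AperiodicWarning(UserWarning):
    """Emitted when return-time variability is too large for a meaningful period."""


@dataclass(frozen=True)
class ReactionParams:
    """Rate constants of the surface-reaction model (all dimensionless, >= 0).

    Defaults are the limit-cycle parameter set of the common system X.
    """

    alpha1: float = 0.016
    alpha2: float = 0.0278
    gamma1: float = 0.001
    gamma2: float = 0.002

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "gamma1", "gamma2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ForcingParams:
    """Sinusoidal forcing of the ``alpha2`` rate: ``alpha2(t) = A0 + A*cos(omega*t)``.

    Defaults produce quasiperiodic dynamics when combined with
    ``ReactionParams(alpha1=0.019)``.
    """

    A0: float = 0.028
    A: float = 0.002097
    omega: float = 0.01722

    def __post_init__(self) -> None:
        if not (self.A0 > 0):
            raise ValueError("A0 must be > 0")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if not (self.omega > 0):
            raise ValueError("omega must be > 0")


@dataclass(frozen=True)
class LorenzParams:
    """Lorenz system parameters; defaults are the classical chaotic set."""

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.sigma, self.rho, self.beta])):
            raise ValueError("Lorenz parameters must be finite")
        if not (self.beta > 0):
            raise ValueError("beta must be > 0")


@dataclass
class Trajectory:
    """Uniformly sampled trajectory of one system.

    Attributes
    ----------
    times : ndarray, shape (n,)
        Strictly increasing sample times (absolute model time; burn-in is
        not subtracted, so forcing phases remain referenced to t=0).
    states : ndarray, shape (n, n_vars)
    labels : list of str
        Per-column variable names.
    """

    times: np.ndarray
    states: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have matching length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain non-finite values")
        if not self.labels:
            self.labels = [f"x{i}" for i in range(self.states.shape[1])]

    @property
    def dt(self) -> float:
        """Sampling step (uniform grids only)."""
        return float(self.times[1] - self.times[0])

    def column(self, label: str) -> np.ndarray:
        """Return the state column with the given variable name."""
        try:
            j = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no variable {label!r}; have {self.labels}") from None
        return self.states[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.labels)
        df.insert(0, "time", self.times)
        return df

    def save(self, path) -> None:
        """Write CSV (header = labels, first column = time), lossless to 15+ digits."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def load(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times=df["time"].to_numpy(),
            states=df.drop(columns="time").to_numpy(),
            labels=[c for c in df.columns if c != "time"],
        )

    def save_npz(self, path) -> None:
        np.savez(path, times=self.times, states=self.states,
                 labels=np.array(self.labels))

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as z:
            return cls(times=z["times"], states=z["states"],
                       labels=[str(s) for s in z["labels"]])


@dataclass
class PeriodEstimate:
    """Mean Poincare-section return time and its variability."""

    period: float
    cv: float                    # coefficient of variation of return intervals
    n_crossings: int
    crossing_times: np.ndarray


def _integrate(rhs, initial_state, t_end, dt_out, burn_in, labels,
               rtol=1e-8, atol=1e-10, t_eval=None):
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if t_eval is None:
        n_out = int(np.floor((t_end - burn_in) / dt_out)) + 1
        if n_out < 1:
            raise ValueError("t_end must exceed burn_in by at least one step")
        t_eval = burn_in + dt_out * np.arange(n_out)
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), list(initial_state),
                    method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0:g}: {sol.message}")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = np.argmax(~np.all(np.isfinite(states), axis=1))
        raise IntegrationError(f"non-finite state at t={sol.t[bad]:g}")
    return Trajectory(times=sol.t.copy(), states=states, labels=labels)


def _check_reaction_initial(initial_state):
    tA, tB = initial_state
    if tA < 0 or tB < 0 or tA + tB > 1:
        raise ValueError(
            f"initial coverages must satisfy thetaA,thetaB>=0 and thetaA+thetaB<=1, "
            f"got ({tA}, {tB})")


def simulate_reaction(params: ReactionParams = ReactionParams(),
                      initial_state=(0.3, 0.3),
                      t_end: float = 28000.0,
                      dt_out: float = 10.0,
                      burn_in: float = 8000.0,
                      *, rtol: float = 1e-8, atol: float = 1e-10,
                      t_eval=None) -> Trajectory:
    """Integrate the autonomous surface-reaction model (system X).

    The rate equations for the fractional coverages are::

        d(theta_A)/dt = alpha1*(1-theta_A-theta_B) - gamma1*theta_A - R
        d(theta_B)/dt = alpha2*(1-theta_A-theta_B) - gamma2*theta_B - R
        R = theta_A*theta_B*(1-theta_A-theta_B)**2

    Returns the post-burn-in trajectory on a uniform grid of step ``dt_out``
    (absolute times; the grid starts at ``burn_in``).
    """
    _check_reaction_initial(initial_state)
    a1, a2, g1, g2 = params.alpha1, params.alpha2, params.gamma1, params.gamma2

    def rhs(t, s):
        tA, tB = s
        empty = 1.0 - tA - tB
        r = tA * tB * empty * empty
        return (a1 * empty - g1 * tA - r, a2 * empty - g2 * tB - r)

    return _integrate(rhs, initial_state, t_end, dt_out, burn_in,
                      ["theta_A", "theta_B"], rtol=rtol, atol=atol, t_eval=t_eval)


def simulate_forced_reaction(params: ReactionParams,
                             forcing: ForcingParams = ForcingParams(),
                             initial_state=(0.3, 0.3),
                             t_end: float = 28000.0,
                             dt_out: float = 10.0,
                             burn_in: float = 8000.0,
                             *, rtol: float = 1e-8, atol: float = 1e-10,
                             t_eval=None) -> Trajectory:
    """Integrate the periodically forced reaction model (system Y).

    Identical to :func:`simulate_reaction` with ``alpha2`` replaced by
    ``A0 + A*cos(omega*t)``; ``params.alpha2`` is ignored.  The forcing
    phase is referenced to absolute time, so burn-in does not reset it.
    """
    _check_reaction_initial(initial_state)
    a1, g1, g2 = params.alpha1, params.gamma1, params.gamma2
    A0, A, omega = forcing.A0, forcing.A, forcing.omega

    def rhs(t, s):
        tA, tB = s
        empty = 1.0 - tA - tB
        r = tA * tB * empty * empty
        a2t = A0 + A * np.cos(omega * t)
        return (a1 * empty - g1 * tA - r, a2t * empty - g2 * tB - r)

    return _integrate(rhs, initial_state, t_end, dt_out, burn_in,
                      ["theta_A", "theta_B"], rtol=rtol, atol=atol, t_eval=t_eval)


def simulate_lorenz(params: LorenzParams = LorenzParams(),
                    initial_state=(1.0, 1.0, 1.0),
                    t_end: float = 1050.0,
                    dt_out: float = 0.05,
                    burn_in: float = 50.0,
                    *, rtol: float = 1e-8, atol: float = 1e-10,
                    t_eval=None) -> Trajectory:
    """Integrate the Lorenz system (system Z) onto its attractor.

    The default burn-in of 50 time units is ample for the initial
    condition to be forgotten (the attractor is reached within a few
    Lyapunov times).
    """
    s, r, b = params.sigma, params.rho, params.beta

    def rhs(t, st):
        x, y, z = st
        return (s * (y - x), x * (r - z) - y, x * y - b * z)

    return _integrate(rhs, initial_state, t_end, dt_out, burn_in,
                      ["x", "y", "z"], rtol=rtol, atol=atol, t_eval=t_eval)


def reaction_rhs(state, params: ReactionParams = ReactionParams(),
                 alpha2: float | None = None):
    """Reaction vector field at ``state`` (convenience for closed-form checks).

    ``alpha2`` overrides the parameter value (e.g. an instantaneous
    forced value A0 + A*cos(omega*t)).
    """
    tA, tB = state
    a2 = params.alpha2 if alpha2 is None else alpha2
    empty = 1.0 - tA - tB
    r = tA * tB * empty * empty
    return np.array([params.alpha1 * empty - params.gamma1 * tA - r,
                     a2 * empty - params.gamma2 * tB - r])


def lorenz_rhs(state, params: LorenzParams = LorenzParams()):
    """Lorenz vector field at ``state`` (convenience for closed-form checks)."""
    x, y, z = state
    return np.array([params.sigma * (y - x),
                     x * (params.rho - z) - y,
                     x * y - params.beta * z])


def estimate_period(traj: Trajectory,
                    section: tuple = (0, None, +1),
                    *, cv_threshold: float = 0.05) -> PeriodEstimate:
    """Estimate the period from Poincare-section return times.

    Parameters
    ----------
    traj : Trajectory
    section : (variable, level, direction)
        ``variable`` is a column index or label; ``level`` the crossing
        level (defaults to the variable's mean); ``direction`` +1 for
        upward crossings, -1 for downward.
    cv_threshold : float
        If the coefficient of variation of return intervals exceeds this,
        an :class:`AperiodicWarning` is emitted (expected for chaotic
        signals).

    Returns the mean inter-crossing interval, refined below the sampling
    step by linear interpolation between the bracketing samples.
    """
    var, level, direction = section
    y = traj.column(var) if isinstance(var, str) else traj.states[:, var]
    t = traj.times
    if level is None:
        level = float(y.mean())
    if direction >= 0:
        mask = (y[:-1] < level) & (y[1:] >= level)
    else:
        mask = (y[:-1] > level) & (y[1:] <= level)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise NotPeriodicError(
            f"only {len(idx)} section crossings; need >= 3 for a period estimate")
    frac = (level - y[idx]) / (y[idx + 1] - y[idx])
    crossing_times = t[idx] + frac * (t[idx + 1] - t[idx])
    intervals = np.diff(crossing_times)
    period = float(intervals.mean())
    cv = float(intervals.std() / period)
    if cv > cv_threshold:
        warnings.warn(
            f"return-interval coefficient of variation {cv:.3g} exceeds "
            f"{cv_threshold:g}; the signal looks aperiodic", AperiodicWarning,
            stacklevel=2)
    return PeriodEstimate(period=period, cv=cv, n_crossings=len(idx) + 1,
                          crossing_times=crossing_times)
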