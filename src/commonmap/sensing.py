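"""Sensor-stream assembly: channel selection, delay coordinates, time shifts, mixing.

A *sensor stream* is an ``n_samples x n_channels`` matrix sampled on a
shared uniform grid.  Each channel is one variable of one simulated
system evaluated at ``t - delay + shift``: delays build Takens-style
delay coordinates, positive shifts let a sensor look "into the future"
of the common system (the causality setups), and a linear mixing matrix
turns clean per-system channels into "dirty" channels that blend the
common and sensor-specific systems.

Provenance (source system, variable, delay, shift, mixing matrix) is
retained on the stream, but only for ground-truth evaluation — none of
the analysis algorithms read it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dynamics import (
    ForcingParams,
    LorenzParams,
    ReactionParams,
    Trajectory,
    simulate_forced_reaction,
    simulate_lorenz,
    simulate_reaction,
)

__all__ = [
    "ChannelSpec",
    "SensorStream",
    "CoverageError",
    "RankDeficientWarning",
    "assemble_sensor",
    "apply_mixing",
    "make_experiment_streams",
    "MIXING_SENSOR1",
    "MIXING_SENSOR2",
    "EXPERIMENT_TAGS",
]

# 4x4 mixing matrices of the "dirty channel" setup: each output channel is a
# linear combination (samples @ M) of the four clean channels of that sensor.
MIXING_SENSOR1 = np.array([
    [0.3637, -0.0173, -0.3701, 0.1013],
    [-0.5068, -0.4513, 0.1470, -0.2041],
    [0.0888, -0.1818, 0.3284, 0.3344],
    [0.0407, -0.3496, -0.1545, 0.3602],
])
MIXING_SENSOR2 = np.array([
    [-0.1394, -0.0597, 0.0828, 0.3847],
    [-0.3803, -0.3576, -0.3440, -0.0628],
    [-0.1010, -0.5259, -0.2147, -0.3981],
    [-0.3793, -0.0568, 0.3585, -0.1544],
])

EXPERIMENT_TAGS = ("clean", "causal1", "causal2", "mixed")


class CoverageError(ValueError):
    """A channel requests samples outside its source trajectory's support."""


class RankDeficientWarning(UserWarning):
    """Mixing matrix is rank deficient; information is lost but mixing proceeds."""


@dataclass(frozen=True)
class ChannelSpec:
    """One sensor channel: a system variable read at ``t - delay + shift``."""

    source_system: str          # "X" | "Y" | "Z"
    variable: str               # column label in the source Trajectory
    delay: float = 0.0          # >= 0, Takens delay
    shift: float = 0.0          # > 0 looks into the future

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    @property
    def name(self) -> str:
        off = self.shift - self.delay
        suffix = "t" if off == 0 else (f"t+{off:g}" if off > 0 else f"t-{-off:g}")
        return f"{self.variable}({self.source_system})({suffix})"


@dataclass
class SensorStream:
    """Simultaneously sampled multichannel measurements on a shared grid."""

    samples: np.ndarray                      # n x c
    channel_meta: list[ChannelSpec]
    sample_times: np.ndarray                 # shared grid, length n
    mixed: bool = False
    mixing_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        n, c = self.samples.shape
        if len(self.sample_times) != n:
            raise ValueError("sample_times length must match sample count")
        if len(self.channel_meta) != c:
            raise ValueError("channel_meta length must match channel count")
        if n <= c:
            raise ValueError(f"need more samples than channels (n={n}, c={c})")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channel_meta]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.channel_names)
        df.insert(0, "time", self.sample_times)
        return df

    def save(self, csv_path, meta_path=None) -> None:
        """CSV of samples plus a JSON sidecar holding channel provenance."""
        csv_path = str(csv_path)
        if meta_path is None:
            meta_path = csv_path[:-4] + ".meta.json" if csv_path.endswith(".csv") \
                else csv_path + ".meta.json"
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        meta = {
            "channels": [asdict(c) for c in self.channel_meta],
            "mixed": self.mixed,
            "mixing_matrix": None if self.mixing_matrix is None
            else self.mixing_matrix.tolist(),
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, csv_path, meta_path=None) -> "SensorStream":
        csv_path = str(csv_path)
        if meta_path is None:
            meta_path = csv_path[:-4] + ".meta.json" if csv_path.endswith(".csv") \
                else csv_path + ".meta.json"
        df = pd.read_csv(csv_path, float_precision="round_trip")
        with open(meta_path) as fh:
            meta = json.load(fh)
        M = meta.get("mixing_matrix")
        return cls(
            samples=df.drop(columns="time").to_numpy(),
            channel_meta=[ChannelSpec(**c) for c in meta["channels"]],
            sample_times=df["time"].to_numpy(),
            mixed=bool(meta.get("mixed", False)),
            mixing_matrix=None if M is None else np.asarray(M),
        )


def _sample_at(traj: Trajectory, times: np.ndarray, channel: ChannelSpec) -> np.ndarray:
    """Read a trajectory column at the requested times (must lie on its grid)."""
    dt = traj.dt
    idx_f = (times - traj.times[0]) / dt
    idx = np.rint(idx_f).astype(int)
    if np.any(np.abs(idx_f - idx) > 1e-9 * max(1.0, abs(idx_f).max())):
        raise ValueError(
            f"channel {channel.name}: requested times do not lie on the "
            f"trajectory grid (step {dt:g}); delays/shifts must be integer "
            f"multiples of the sampling step")
    if idx.min() < 0 or idx.max() >= len(traj.times):
        t_bad = times[np.argmin(idx)] if idx.min() < 0 else times[np.argmax(idx)]
        raise CoverageError(
            f"channel {channel.name} needs t={t_bad:g}, outside trajectory "
            f"support [{traj.times[0]:g}, {traj.times[-1]:g}]")
    return traj.column(channel.variable)[idx]


def assemble_sensor(trajectories: dict[str, Trajectory],
                    channels: list[ChannelSpec],
                    grid: np.ndarray) -> SensorStream:
    """Build a sensor stream: column j at time t is variable_j(t - delay_j + shift_j)."""
    grid = np.asarray(grid, dtype=float)
    cols = []
    for ch in channels:
        if ch.source_system not in trajectories:
            raise CoverageError(f"no trajectory supplied for system {ch.source_system}")
        traj = trajectories[ch.source_system]
        cols.append(_sample_at(traj, grid - ch.delay + ch.shift, ch))
    return SensorStream(samples=np.column_stack(cols), channel_meta=list(channels),
                        sample_times=grid)


def apply_mixing(stream: SensorStream, M: np.ndarray) -> SensorStream:
    """Replace channels by linear combinations: ``samples_out = samples_in @ M``."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] != stream.n_channels:
        raise ValueError(
            f"mixing matrix has {M.shape[0]} rows but stream has "
            f"{stream.n_channels} channels")
    if np.linalg.matrix_rank(M) < M.shape[1]:
        warnings.warn("mixing matrix is rank deficient: mixed channels lose "
                      "information", RankDeficientWarning, stacklevel=2)
    return SensorStream(samples=stream.samples @ M,
                        channel_meta=list(stream.channel_meta),
                        sample_times=stream.sample_times,
                        mixed=True, mixing_matrix=M)


@dataclass
class StreamConfig:
    """Simulation settings shared by all experiment setups."""

    n_samples: int = 2000
    step: float = 10.0           # shared sampling step, time units
    delta_t: float | None = None  # Takens delay; None = setup default
    tau: float | None = None      # future shift; None = setup default
    burn_in_xy: float = 8000.0
    burn_in_z: float = 50.0
    x_initial: tuple = (0.3, 0.3)
    y_initial: tuple = (0.3, 0.3)
    z_initial: tuple = (1.0, 1.0, 1.0)
    reaction_params: ReactionParams = field(default_factory=ReactionParams)
    forced_params: ReactionParams = field(
        default_factory=lambda: ReactionParams(alpha1=0.019))
    forcing: ForcingParams = field(default_factory=ForcingParams)
    lorenz_params: LorenzParams = field(default_factory=LorenzParams)


# Channel lists of the four experiment setups.  ``dt`` is the Takens delay,
# ``tau`` the future shift of sensor 2.
def _setup_channels(tag: str, dt: float, tau: float):
    if tag == "clean":
        s1 = [ChannelSpec("X", "theta_A"), ChannelSpec("Y", "theta_A"),
              ChannelSpec("X", "theta_A", delay=dt), ChannelSpec("Y", "theta_A", delay=dt)]
        s2 = [ChannelSpec("X", "theta_B"), ChannelSpec("Z", "y"),
              ChannelSpec("X", "theta_B", delay=dt), ChannelSpec("Z", "y", delay=dt)]
    elif tag == "causal1":
        s1 = [ChannelSpec("X", "theta_A"), ChannelSpec("X", "theta_B"),
              ChannelSpec("Y", "theta_A"), ChannelSpec("Y", "theta_B")]
        s2 = [ChannelSpec("X", "theta_A", shift=tau), ChannelSpec("X", "theta_B", shift=tau),
              ChannelSpec("Z", "x", shift=tau), ChannelSpec("Z", "y", shift=tau)]
    elif tag == "causal2":
        s1 = [ChannelSpec("X", "theta_A"), ChannelSpec("X", "theta_A", delay=dt),
              ChannelSpec("Y", "theta_A"), ChannelSpec("Y", "theta_A", delay=dt)]
        s2 = [ChannelSpec("X", "theta_B", shift=tau),
              ChannelSpec("X", "theta_B", delay=dt, shift=tau),
              ChannelSpec("Z", "y", shift=tau),
              ChannelSpec("Z", "y", delay=dt, shift=tau)]
    elif tag == "mixed":
        s1 = [ChannelSpec("X", "theta_A"), ChannelSpec("X", "theta_B"),
              ChannelSpec("Y", "theta_A"), ChannelSpec("Y", "theta_B")]
        s2 = [ChannelSpec("X", "theta_A", shift=dt), ChannelSpec("X", "theta_B", shift=dt),
              ChannelSpec("Z", "x", shift=dt), ChannelSpec("Z", "y", shift=dt)]
    else:
        raise ValueError(f"unknown experiment tag {tag!r}; expected one of "
                         f"{EXPERIMENT_TAGS}")
    return s1, s2


def _snap(value: float, step: float) -> float:
    k = round(value / step)
    if abs(value - k * step) > 1e-9 * step:
        raise ValueError(f"delay/shift {value:g} is not a multiple of the "
                         f"sampling step {step:g}")
    return k * step


def make_experiment_streams(experiment: str, config: StreamConfig | None = None):
    """Simulate X, Y, Z and assemble the two sensor streams of one setup.

    Setups
    ------
    clean
        S1 = [thA(X)(t), thA(Y)(t), thA(X)(t-dt), thA(Y)(t-dt)],
        S2 = [thB(X)(t), y(Z)(t), thB(X)(t-dt), y(Z)(t-dt)], dt = 200.
    causal1
        S1 sees (thA, thB) of X and Y now; S2 sees (thA, thB) of X and
        (x, y) of Z at t + tau, tau = 200 (~25% of the X period).
    causal2
        Delay pairs: S1 = thA(X), thA(Y) at t and t-dt; S2 = thB(X),
        y(Z) at t+tau and t+tau-dt, with dt = 100, tau = 250.
    mixed
        causal-style clean channels (S2 shifted by dt = 200) multiplied by
        fixed 4x4 mixing matrices, making every channel "dirty".

    Returns ``(S1, S2, ground_truth)`` where ground_truth maps variable
    names (e.g. ``"theta_A(X)"``) to their unshifted values on the grid.
    """
    cfg = config or StreamConfig()
    defaults = {"clean": (200.0, 0.0), "causal1": (0.0, 200.0),
                "causal2": (100.0, 250.0), "mixed": (200.0, 0.0)}
    if experiment not in defaults:
        raise ValueError(f"unknown experiment tag {experiment!r}; expected one "
                         f"of {EXPERIMENT_TAGS}")
    dt = _snap(defaults[experiment][0] if cfg.delta_t is None else cfg.delta_t, cfg.step)
    tau = _snap(defaults[experiment][1] if cfg.tau is None else cfg.tau, cfg.step)
    ch1, ch2 = _setup_channels(experiment, dt, tau)

    max_delay = max([c.delay for c in ch1 + ch2], default=0.0)
    max_shift = max([c.shift for c in ch1 + ch2], default=0.0)
    t0 = cfg.burn_in_xy + max_delay
    grid = t0 + cfg.step * np.arange(cfg.n_samples)
    t_end = grid[-1] + max_shift

    x = simulate_reaction(cfg.reaction_params, cfg.x_initial, t_end=t_end,
                          dt_out=cfg.step, burn_in=cfg.burn_in_xy)
    y = simulate_forced_reaction(cfg.forced_params, cfg.forcing, cfg.y_initial,
                                 t_end=t_end, dt_out=cfg.step, burn_in=cfg.burn_in_xy)
    # Lorenz evolves on a much faster time scale; only its values at the
    # sensor sampling times are needed, offset so delayed/shifted channels
    # stay inside the integrated span.
    z_eval = cfg.burn_in_z + cfg.step * np.arange(
        cfg.n_samples + int(round((max_delay + max_shift) / cfg.step)) + 1)
    z = simulate_lorenz(cfg.lorenz_params, cfg.z_initial, t_end=z_eval[-1],
                        dt_out=cfg.step, burn_in=cfg.burn_in_z, t_eval=z_eval)
    # re-express the Lorenz trajectory on the sensor clock (same step, offset grid)
    z = Trajectory(times=z.times - cfg.burn_in_z + (t0 - max_delay),
                   states=z.states, labels=z.labels)
    trajs = {"X": x, "Y": y, "Z": z}

    s1 = assemble_sensor(trajs, ch1, grid)
    s2 = assemble_sensor(trajs, ch2, grid)
    if experiment == "mixed":
        # standardize the clean channels before mixing so every mixed channel
        # is a genuine blend of the common and sensor-specific systems; on raw
        # scales a Lorenz coordinate (tens of units) would swamp a surface
        # coverage (hundredths) and the mixture would carry no common signal
        from .spectral import standardize_channels
        s1 = SensorStream(standardize_channels(s1.samples), s1.channel_meta,
                          s1.sample_times)
        s2 = SensorStream(standardize_channels(s2.samples), s2.channel_meta,
                          s2.sample_times)
        s1 = apply_mixing(s1, MIXING_SENSOR1)
        s2 = apply_mixing(s2, MIXING_SENSOR2)

    ground_truth = {}
    for sys_name, traj in trajs.items():
        for lab in traj.labels:
            ch = ChannelSpec(sys_name, lab)
            ground_truth[f"{lab}({sys_name})"] = _sample_at(traj, grid, ch)
    ground_truth["time"] = grid
    return s1, s2, ground_truth
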