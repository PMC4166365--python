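"""Gamma-discretized temporal-sequence (TS) input generation.

A TS network emits one "event" per channel: a transient elevation of firing
rate whose onset is targeted at the middle of an assigned gamma cycle and
jittered by Gaussian noise.  The sharpness of the gamma discretization is
controlled entirely by the onset jitter standard deviation.  Both downstream
models consume these inputs: the spiking model reads the continuous rate
trajectories, the binary model reads per-cycle binary activation patterns.

Units: times in ms, rates in Hz throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GammaTiming",
    "TSChannel",
    "RateTrajectory",
    "BinaryInputSequence",
    "assign_event_times",
    "rate_trajectory",
    "binary_pattern_sequence",
    "gamma_phases",
    "write_event_table",
    "read_event_table",
    "write_rate_trajectory",
]

#: Default peak firing rate added at the event time (Hz).
PEAK_RATE = 200.0
#: Default baseline firing rate (Hz).
BASELINE_RATE = 20.0
#: Default decay time constant of the event rate transient (ms).
DECAY_TAU = 10.0


@dataclass(frozen=True)
class GammaTiming:
    """Timing layout of the gamma-discretized sequence.

    Parameters
    ----------
    t_gamma : float
        Gamma cycle length in ms (default 30).
    onset_noise_sd : float
        Standard deviation of the Gaussian onset jitter in ms.  0 places
        every event exactly at its cycle midpoint.
    n_prf : int
        Number of channels whose events fall in each gamma cycle.
    """

    t_gamma: float = 30.0
    onset_noise_sd: float = 0.0
    n_prf: int = 100

    def __post_init__(self) -> None:
        if self.t_gamma <= 0:
            raise ValueError(f"t_gamma must be positive, got {self.t_gamma}")
        if self.onset_noise_sd < 0:
            raise ValueError(
                f"onset_noise_sd must be non-negative, got {self.onset_noise_sd}"
            )
        if self.n_prf <= 0:
            raise ValueError(f"n_prf must be positive, got {self.n_prf}")


@dataclass(frozen=True)
class TSChannel:
    """One TS channel: an indexed event with its rate dynamics parameters."""

    index: int
    event_time: float
    assigned_cycle: int
    baseline_rate: float = BASELINE_RATE
    peak_rate: float = PEAK_RATE
    decay_tau: float = DECAY_TAU


@dataclass(frozen=True)
class RateTrajectory:
    """Per-channel firing-rate grid.

    ``rates[c, k]`` is the rate of channel ``c`` at time ``k * dt`` (Hz).
    """

    rates: np.ndarray
    dt: float
    duration: float

    def __post_init__(self) -> None:
        n_steps = int(round(self.duration / self.dt))
        if self.rates.ndim != 2 or self.rates.shape[1] != n_steps:
            raise ValueError(
                f"rates grid {self.rates.shape} inconsistent with "
                f"dt={self.dt}, duration={self.duration}"
            )

    @property
    def n_channels(self) -> int:
        return self.rates.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.rates.shape[1]) * self.dt


@dataclass(frozen=True)
class BinaryInputSequence:
    """Per-cycle sets of active channels, disjoint across cycles."""

    n_channels: int
    n_cycles: int
    active_sets: tuple[frozenset[int], ...]
    active_fraction: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s in self.active_sets:
            if seen & s:
                raise ValueError("active sets overlap across cycles")
            seen |= s

    def as_matrix(self) -> np.ndarray:
        """Return a (n_cycles, n_channels) 0/1 activation matrix."""
        m = np.zeros((self.n_cycles, self.n_channels), dtype=np.int8)
        for c, s in enumerate(self.active_sets):
            m[c, sorted(s)] = 1
        return m


def assign_event_times(
    n_channels: int,
    timing: GammaTiming,
    seed: int | np.random.Generator | None = None,
) -> list[TSChannel]:
    """Assign each channel an event time at the (jittered) middle of a cycle.

    Channel ``i`` targets cycle ``floor(i / n_prf)``; its event time is the
    midpoint of that cycle plus Gaussian jitter of standard deviation
    ``timing.onset_noise_sd``.  Channels are then sorted by event time and
    re-indexed; ``assigned_cycle`` keeps the targeted cycle from before the
    sort, so index blocks no longer map onto cycles once jitter is large.

    Returns the channels in sorted (re-indexed) order.
    """
    if n_channels <= 0:
        raise ValueError(f"n_channels must be positive, got {n_channels}")
    if timing.n_prf > n_channels:
        raise ValueError(
            f"n_prf={timing.n_prf} exceeds n_channels={n_channels}"
        )
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    cycles = i // timing.n_prf
    t_sp = cycles * timing.t_gamma + timing.t_gamma / 2.0
    if timing.onset_noise_sd > 0:
        t_sp = t_sp + rng.normal(0.0, timing.onset_noise_sd, size=n_channels)
    # events cannot precede the start of the simulation
    t_sp = np.clip(t_sp, 0.0, None)
    order = np.argsort(t_sp, kind="stable")
    return [
        TSChannel(index=new_i, event_time=float(t_sp[old_i]),
                  assigned_cycle=int(cycles[old_i]))
        for new_i, old_i in enumerate(order)
    ]


def rate_trajectory(
    channels: Sequence[TSChannel],
    dt: float,
    duration: float,
    rate_noise_hz_per_ms: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> RateTrajectory:
    """Integrate the per-channel firing-rate dynamics on a regular grid.

    Each channel relaxes toward its baseline rate with time constant
    ``decay_tau`` and receives a one-step impulse of ``peak_rate`` at the
    step containing its event time (the discrete realization of a Dirac
    delta).  Optional per-step additive Gaussian noise has standard
    deviation ``rate_noise_hz_per_ms * dt``; rates are clamped at zero.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    n_ch = len(channels)
    rates = np.empty((n_ch, n_steps), dtype=np.float64)

    r_base = np.array([c.baseline_rate for c in channels])
    peak = np.array([c.peak_rate for c in channels])
    tau = np.array([c.decay_tau for c in channels])
    event_step = np.array(
        [int(np.floor(c.event_time / dt)) for c in channels]
    )

    sd = rate_noise_hz_per_ms * dt
    r = r_base.copy()
    for k in range(n_steps):
        hit = event_step == k
        if np.any(hit):
            r = r + np.where(hit, peak, 0.0)
        rates[:, k] = r
        dr = -(r - r_base) * dt / tau
        if sd > 0:
            dr = dr + rng.normal(0.0, sd, size=n_ch)
        r = np.maximum(r + dr, 0.0)
    return RateTrajectory(rates=rates, dt=dt, duration=duration)


def binary_pattern_sequence(
    n_channels: int = 100,
    n_cycles: int = 3,
    active_fraction: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> BinaryInputSequence:
    """Draw disjoint random active channel sets, one per gamma cycle.

    ``round(active_fraction * n_channels)`` channels are active per cycle
    and no channel is active in more than one cycle.
    """
    if not 0 <= active_fraction <= 1:
        raise ValueError(f"active_fraction must be in [0, 1], got {active_fraction}")
    n_active = int(round(active_fraction * n_channels))
    if n_cycles * n_active > n_channels:
        raise ValueError(
            f"cannot draw {n_cycles} disjoint sets of {n_active} from "
            f"{n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_channels)
    sets = tuple(
        frozenset(int(x) for x in perm[c * n_active : (c + 1) * n_active])
        for c in range(n_cycles)
    )
    return BinaryInputSequence(
        n_channels=n_channels,
        n_cycles=n_cycles,
        active_sets=sets,
        active_fraction=active_fraction,
    )


def gamma_phases(event_times: np.ndarray | Sequence[float], t_gamma: float) -> np.ndarray:
    """Phase of each event within its gamma cycle, on [0, 1).

    0.5 is the cycle midpoint; the cycle boundary wraps to 0.
    """
    if t_gamma <= 0:
        raise ValueError(f"t_gamma must be positive, got {t_gamma}")
    t = np.asarray(event_times, dtype=np.float64)
    return np.mod(t, t_gamma) / t_gamma


# ---------------------------------------------------------------------------
# file I/O

def write_event_table(channels: Sequence[TSChannel], path: str | Path) -> None:
    """Write the TS event table as CSV (channel, t_sp_ms, assigned_cycle)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "t_sp_ms", "assigned_cycle"])
        for c in channels:
            w.writerow([c.index, repr(c.event_time), c.assigned_cycle])


def read_event_table(path: str | Path) -> list[TSChannel]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        TSChannel(index=int(r["channel"]), event_time=float(r["t_sp_ms"]),
                  assigned_cycle=int(r["assigned_cycle"]))
        for r in rows
    ]


def write_rate_trajectory(traj: RateTrajectory, path: str | Path) -> None:
    """Write a rate trajectory as CSV (``# dt_ms=..`` header) or HDF5.

    The format is chosen by extension: ``.h5``/``.hdf5`` stores the matrix
    as a dataset with ``dt_ms`` and ``duration_ms`` attributes, anything
    else is written as a CSV matrix with a comment header.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("rates_hz", data=traj.rates)
            d.attrs["dt_ms"] = traj.dt
            d.attrs["duration_ms"] = traj.duration
    else:
        with open(path, "w") as fh:
            fh.write(f"# dt_ms={traj.dt} duration_ms={traj.duration}\n")
            np.savetxt(fh, traj.rates, delimiter=",")
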