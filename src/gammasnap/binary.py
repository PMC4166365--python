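"""Generic sequence decoder built of intrinsically bistable binary units.

Three modules of threshold units receive sparse random input from the TS
channels.  Modules differ only in an excitability offset (a threshold
gradient): the first module can be driven over the activation threshold by
TS input alone, later modules additionally require feedforward excitation
from already-active earlier modules ("priming").  Once active, a unit stays
active over the bistable input range; strong recurrent inhibition recruited
by the active population prevents later TS input from activating further
units, so each module keeps a persistent snapshot of exactly one gamma
cycle.

The input variable of unit *i* follows

.. math:: \\tau \\dot u_i = -u_i + \\sum_j W^{ex}_{ij} f_j
          + \\sum_j W^{in}_{ij} f_j - \\Delta_i

with hysteretic activation: :math:`f_i` switches to 1 when :math:`u_i`
exceeds :math:`u_+`, to 0 when it falls below :math:`u_-`, and otherwise
retains its previous value.  Time is in the model's dimensionless units
(:math:`\\tau = 20`); a gamma cycle is 16 units, split into an 8-unit input
half (TS activations applied) and an 8-unit silent half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gammasnap.ts_input import BinaryInputSequence

__all__ = [
    "BinaryNetwork",
    "BinaryTrajectory",
    "build_binary_network",
    "hysteretic_activation",
    "simulate_binary",
    "final_pattern",
]


@dataclass(frozen=True)
class BinaryNetwork:
    """Weights and unit parameters of the binary model.

    ``w_rec`` combines within-module excitation and inhibition and
    module-to-next-module feedforward excitation into a single (units x
    units) matrix; ``w_ts`` is the (units x channels) TS input matrix.
    ``module_of[i]`` is the module index of unit ``i``.
    """

    n_ts: int
    module_sizes: tuple[int, ...]
    w_ts: np.ndarray
    w_rec: np.ndarray
    offsets: np.ndarray
    module_of: np.ndarray
    tau: float = 20.0
    u_plus: float = 1.0
    u_minus: float = -10.0

    @property
    def n_units(self) -> int:
        return int(sum(self.module_sizes))

    def module_slice(self, m: int) -> slice:
        start = int(sum(self.module_sizes[:m]))
        return slice(start, start + self.module_sizes[m])


def build_binary_network(
    seed: int | np.random.Generator | None = None,
    n_ts: int = 100,
    module_sizes: tuple[int, ...] = (300, 300, 300),
    p_ts: float = 0.01,
    w_ts: float = 2.0,
    p_ex_rec: float = 0.01,
    w_ex_rec: float = 0.1,
    p_in_rec: float = 0.30,
    w_in_rec: float = -1.5,
    p_ff: float = 0.01,
    w_ff: float = 4.0,
    module_offsets: tuple[float, ...] = (0.5, 2.5, 4.5),
    tau: float = 20.0,
    u_plus: float = 1.0,
    u_minus: float = -10.0,
) -> BinaryNetwork:
    """Draw the sparse random connectivity of the binary model.

    Every potential edge is drawn independently with its class probability
    and, if present, takes exactly the class weight.  Feedforward edges run
    only from module *m* to module *m+1*; self-connections are excluded
    from the recurrent classes.
    """
    if len(module_offsets) != len(module_sizes):
        raise ValueError("one offset per module required")
    if u_minus >= u_plus:
        raise ValueError("u_minus must be below u_plus")
    rng = np.random.default_rng(seed)
    n_units = int(sum(module_sizes))
    module_of = np.concatenate(
        [np.full(sz, m, dtype=np.int64) for m, sz in enumerate(module_sizes)]
    )

    wts = np.where(rng.random((n_units, n_ts)) < p_ts, w_ts, 0.0)

    w = np.zeros((n_units, n_units))
    same = module_of[:, None] == module_of[None, :]
    ff = module_of[:, None] == module_of[None, :] + 1  # post is next module
    draw = rng.random((n_units, n_units))
    w += np.where(same & (draw < p_ex_rec), w_ex_rec, 0.0)
    draw = rng.random((n_units, n_units))
    w += np.where(same & (draw < p_in_rec), w_in_rec, 0.0)
    draw = rng.random((n_units, n_units))
    w += np.where(ff & (draw < p_ff), w_ff, 0.0)
    np.fill_diagonal(w, 0.0)

    offsets = np.array([module_offsets[m] for m in module_of], dtype=np.float64)
    return BinaryNetwork(
        n_ts=n_ts, module_sizes=tuple(module_sizes), w_ts=wts, w_rec=w,
        offsets=offsets, module_of=module_of, tau=tau,
        u_plus=u_plus, u_minus=u_minus,
    )


def hysteretic_activation(
    u: np.ndarray | float,
    f_prev: np.ndarray | float,
    u_plus: float = 1.0,
    u_minus: float = -10.0,
) -> np.ndarray:
    """Bistable activation: 1 above ``u_plus``, 0 below ``u_minus``,
    otherwise the previous value.  Ties keep the previous value (the
    inequalities are strict)."""
    if u_minus >= u_plus:
        raise ValueError("u_minus must be below u_plus")
    u = np.asarray(u, dtype=np.float64)
    f_prev = np.asarray(f_prev, dtype=np.float64)
    return np.where(u > u_plus, 1.0, np.where(u < u_minus, 0.0, f_prev))


@dataclass
class BinaryTrajectory:
    """State history of a binary-model run (one row per RK4 step)."""

    times: np.ndarray
    u: np.ndarray
    f: np.ndarray
    network: BinaryNetwork
    half_cycle: float
    n_cycles: int
    #: step index at which each unit first switched on (-1 = never)
    first_activation_step: np.ndarray

    def activation_cycle(self) -> np.ndarray:
        """Gamma cycle during which each unit first activated (-1 = never)."""
        cyc = np.full(self.network.n_units, -1, dtype=np.int64)
        on = self.first_activation_step >= 0
        cycle_len = 2.0 * self.half_cycle
        cyc[on] = (self.times[self.first_activation_step[on]] // cycle_len).astype(np.int64)
        return cyc


def simulate_binary(
    network: BinaryNetwork,
    input_seq: BinaryInputSequence,
    dt: float = 0.2,
    half_cycle: float = 8.0,
) -> BinaryTrajectory:
    """Integrate the binary model over ``input_seq.n_cycles`` gamma cycles.

    Classic fourth-order Runge-Kutta on the input variables ``u`` with the
    activations (SP and TS) held constant within each step; the hysteretic
    activations are recomputed from ``u`` after each full step.  TS channel
    activations equal the cycle's input pattern during the first half of
    the cycle and are zero during the second half.

    Units start from the resting fixed point of the no-input dynamics,
    ``u(0) = -offset``, ``f(0) = 0``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if input_seq.n_channels != network.n_ts:
        raise ValueError(
            f"input has {input_seq.n_channels} channels, network expects {network.n_ts}"
        )
    n_steps = int(round(2 * half_cycle * input_seq.n_cycles / dt))
    n = network.n_units
    tau = network.tau

    ts_patterns = input_seq.as_matrix().astype(np.float64)

    u = -network.offsets.copy()
    f = np.zeros(n)
    times = np.arange(n_steps + 1) * dt
    u_hist = np.empty((n_steps + 1, n))
    f_hist = np.empty((n_steps + 1, n))
    u_hist[0], f_hist[0] = u, f
    first_on = np.full(n, -1, dtype=np.int64)

    cycle_len = 2.0 * half_cycle
    for k in range(n_steps):
        t = k * dt
        cycle = int(t // cycle_len)
        in_first_half = (t - cycle * cycle_len) < half_cycle
        f_ts = ts_patterns[cycle] if in_first_half else np.zeros(network.n_ts)
        # drive is constant within the step, so the RK4 stages only vary in u
        drive = network.w_rec @ f + network.w_ts @ f_ts - network.offsets

        def rhs(u_):
            return (-u_ + drive) / tau

        k1 = rhs(u)
        k2 = rhs(u + 0.5 * dt * k1)
        k3 = rhs(u + 0.5 * dt * k2)
        k4 = rhs(u + dt * k3)
        u = u + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        f_new = hysteretic_activation(u, f, network.u_plus, network.u_minus)
        newly_on = (f_new == 1.0) & (f == 0.0) & (first_on < 0)
        first_on[newly_on] = k + 1
        f = f_new
        u_hist[k + 1], f_hist[k + 1] = u, f

    return BinaryTrajectory(
        times=times, u=u_hist, f=f_hist, network=network,
        half_cycle=half_cycle, n_cycles=input_seq.n_cycles,
        first_activation_step=first_on,
    )


def final_pattern(trajectory: BinaryTrajectory) -> list[set[int]]:
    """Active units at the final step, grouped by module.

    Unit indices are module-local (0-based within each module).
    """
    if trajectory.f.shape[0] == 0:
        raise ValueError("empty trajectory")
    net = trajectory.network
    f_end = trajectory.f[-1]
    out = []
    for m in range(len(net.module_sizes)):
        sl = net.module_slice(m)
        out.append({int(i) for i in np.nonzero(f_end[sl] == 1.0)[0]})
    return out
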