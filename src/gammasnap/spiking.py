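"""Conductance-based spiking model of gamma-cycle snapshot modules.

Three biophysically identical modules of Hodgkin-Huxley-type neurons (320
two-compartment excitatory cells, 80 single-compartment interneurons each)
decode a gamma-discretized temporal sequence.  Bistability of the excitatory
dendrite arises from the voltage dependence of two opposing synaptic
conductances:

* **NMDA** (feedforward from the previous module plus recurrent), whose
  magnesium block passes current only at depolarized voltages, sustains a
  stable depolarized ("up") dendritic state once the cell is primed;
* **GABA-B-activated KIR** (inward-rectifier potassium), which conducts only
  at hyperpolarized voltages, deepens the resting ("down") state as slow
  GABA-B activation builds up in the module's interneurons.

A module passes through three stages: *unprimed* (no NMDA -- any TS input
produces only transient firing), *primed* (NMDA active, GABA-B still low --
TS input during this one gamma cycle can switch cells to the up state) and
*locked* (GABA-B/KIR built up -- later TS input cannot switch cells).  Since
priming is handed forward module to module, module *m* stores a persistent
snapshot of gamma cycle *m*.

The spike-generating soma, leak conductances, soma-dendrite coupling and
interneuron kinetics are a standard substituted parameterization (Wang-
Buzsaki-style spike currents; sigmoidal magnesium block
``1/(1 + exp(-0.062 V) [Mg]/3.57)``); every constant is exposed on
:class:`SpikingParams`.  Integration is forward Euler at ``dt = 0.025`` ms.

Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from gammasnap.ts_input import RateTrajectory

__all__ = [
    "SpikingParams",
    "SpikeRaster",
    "SpikingResult",
    "DendriticDrive",
    "EnergyLandscape",
    "NumericalDivergence",
    "synaptic_update",
    "steady_state_activation",
    "kir_current",
    "ts_input_current",
    "start_signal",
    "simulate_spiking",
    "simulate_single_cell",
    "energy_landscape",
    "active_cells",
    "write_raster",
    "read_raster",
]


class NumericalDivergence(RuntimeError):
    """Raised when a membrane voltage leaves the plausible range."""


# ---------------------------------------------------------------------------
# parameters

_NP = 320
_NI = 80


@dataclass
class SpikingParams:
    """All constants of the spiking network.

    Synaptic maximal conductances are *per presynaptic source* (channel or
    cell); pool conductances scale inversely with the presynaptic pool size,
    which is why the defaults carry explicit ``/320`` and ``/80`` divisors.
    The per-synapse values follow the consistency relations of the sweep
    grids: ``g_ampa_ee = g_ampa_ei = g_nmda_ee / 4``.
    """

    # -- architecture
    n_modules: int = 3
    n_exc: int = _NP
    n_inh: int = _NI

    # -- synaptic maximal conductances (mS/cm^2 per synapse)
    g_ampa_ee: float = 82.0 / (80 * _NP)
    g_ampa_ei: float = 82.0 / (80 * _NP)
    g_nmda_ee: float = 82.0 / (20 * _NP)
    g_nmda_ei: float = 0.3 / _NP
    g_ts_e: float = 0.4          # one TS channel per E cell, taken as printed
    g_ts_i: float = 0.2 / _NP    # every TS channel onto every I cell
    g_gabaa_e: float = 2.5 / (10 * _NI)
    g_gabab: float = 130.0 / _NI

    # -- reversal potentials (mV)
    e_exc: float = 0.0
    e_gabaa: float = -70.0
    e_gabab_kir: float = -90.0

    # -- synaptic kinetics
    tau_ampa: float = 2.0
    tau_nmda: float = 100.0
    #: rise time constant of the NMDA conductance (dual-exponential
    #: kinetics: the gating variable jumps per spike and decays with
    #: tau_nmda, while the conductance relaxes toward it with this rise
    #: constant) -- the slow rise delays the effectiveness of feedforward
    #: priming toward the end of the gamma cycle in which it starts
    tau_nmda_rise: float = 0.5
    alpha_ampa: float = 0.9
    alpha_nmda: float = 0.5
    tau_gabaa: float = 6.0
    alpha_gabaa: float = 0.9
    # GABA-B/KIR gating is a cooperative, use-dependent G-protein cascade
    # (Destexhe-style kinetics with facilitating transmitter pooling): each
    # interneuron spike increments the receptor gate x by
    # alpha * exp(-ISI/tau_facil) * (1 - x) -- only high-frequency firing
    # releases enough pooled GABA to reach the extrasynaptic receptors --
    # x decays with tau_x, and the G-protein level G relaxes toward the
    # Hill function x^n / (x^n + K^n) with time constant tau_s.  The
    # combination yields the slow sigmoidal KIR rise that follows sustained
    # fast interneuron firing but ignores sparse spiking.
    alpha_gabab: float = 0.4517069358755932
    tau_gabab_facil: float = 5.0
    tau_gabab_x: float = 60.0
    tau_gabab_s: float = 5.0
    gabab_hill: float = 4.0
    gabab_k: float = 0.1856863422881734
    #: recruitment starts only after this many consecutive inter-spike
    #: intervals at most gabab_isi_cut (sustained fast firing, as opposed
    #: to brief volley-driven doublets)
    gabab_min_run: int = 1
    gabab_isi_cut: float = 6.0
    kir_basal_frac: float = 0.05  # constitutively active share of KIR
    #: number of synapses whose constitutive KIR share is summed into the
    #: basal conductance (the gated share always sums over all synapses)
    kir_basal_synapses: float = 142.5
    s_input_slope: float = 0.00175  # synaptic activation per Hz of TS rate
    #: compartment receiving the TS input conductance on excitatory cells;
    #: "soma" separates the input/spike pathway from the bistable dendrite,
    #: whose deep (KIR-locked) state then vetoes somatic firing through the
    #: coupling conductance
    ts_target: str = "dend"
    mg_mm: float = 1.0

    # -- excitatory cell compartments
    c_m: float = 1.0
    g_na_e: float = 100.0
    g_kdr_e: float = 40.0
    e_na: float = 55.0
    e_k: float = -90.0
    g_leak_s: float = 0.3
    e_leak_s: float = -70.0
    g_leak_d: float = 0.1
    e_leak_d: float = -70.0
    g_c: float = 0.1            # soma-dendrite coupling conductance
    p_soma: float = 0.5          # somatic share of membrane area
    phi_e: float = 1.0

    # -- interneuron
    g_na_i: float = 45.0
    g_k_i: float = 18.0
    g_leak_i: float = 0.3
    e_leak_i: float = -68.0
    phi_i: float = 5.0

    # -- integration, input and readout
    dt: float = 0.025
    duration: float = 150.0
    t_gamma: float = 30.0
    spike_threshold: float = -20.0
    refractory: float = 1.0
    start_t_min: float = 15.0
    start_t_max: float = 30.0
    start_period: float = 10.0
    readout_window: float = 50.0
    readout_min_spikes: int = 2
    rate_noise_hz_per_ms: float = 5.0
    #: membrane current noise intensity (uA/cm^2 sqrt(ms)); desynchronizes
    #: the otherwise identical cells of a module
    noise_sd: float = 2.5
    #: coefficient of variation of per-cell multiplicative jitter on the
    #: somatic leak and coupling conductances of excitatory cells; breaks
    #: the artificial synchrony of identical cells
    het_cv: float = 0.0
    v_abort: float = 200.0

    @property
    def n_per_module(self) -> int:
        return self.n_exc + self.n_inh

    @classmethod
    def defaults(cls) -> "SpikingParams":
        """The package's reference parameterization (snapshot-decoding
        configuration; see docs/methods.md for the tuning rationale)."""
        return cls()

    @classmethod
    def table1(cls) -> "SpikingParams":
        """The reference conductance table with the excitatory NMDA/AMPA
        values at the top of their grid range (the default parameterization
        uses a mid-range value; see docs/methods.md)."""
        return cls(g_nmda_ee=4.5 / _NP, g_ampa_ee=1.125 / _NP,
                   g_ampa_ei=1.125 / _NP, g_gabaa_e=0.2 / _NI)

    def with_sweep_point(self, nmda_numerator: float, gabaa_numerator: float,
                         gabab_numerator: float) -> "SpikingParams":
        """Conductances of one sweep grid point.

        ``g_NMDA,EE = nmda / (20 N_P)``; ``g_AMPA,EE = g_AMPA,EI =
        g_NMDA,EE / 4``; ``g_GABA_A = gabaa / (10 N_I)``; ``g_GABA_B =
        gabab / (10 N_I)``.
        """
        g_nmda = nmda_numerator / (20.0 * self.n_exc)
        return replace(
            self,
            g_nmda_ee=g_nmda,
            g_ampa_ee=g_nmda / 4.0,
            g_ampa_ei=g_nmda / 4.0,
            g_gabaa_e=gabaa_numerator / (10.0 * self.n_inh),
            g_gabab=gabab_numerator / (10.0 * self.n_inh),
        )


# ---------------------------------------------------------------------------
# elementary operations

def synaptic_update(s, spiked, tau: float, alpha: float, dt: float):
    """One time step of a saturating synaptic activation variable.

    Exponential decay ``s <- s exp(-dt/tau)`` followed, where the
    presynaptic cell spiked, by the saturating increment
    ``s <- s + alpha (1 - s)``.  The result stays in [0, 1].
    """
    s = np.asarray(s, dtype=np.float64) * np.exp(-dt / tau)
    return np.where(spiked, s + alpha * (1.0 - s), s)


def steady_state_activation(r, tau: float = 2.0, alpha: float = 0.9):
    """Time-averaged synaptic activation of a synapse driven at rate ``r``.

    For periodic presynaptic spiking at ``r`` Hz the activation cycles
    between a post-spike value and its decayed remnant; averaging over the
    inter-spike interval gives

    .. math:: s(r) = \\frac{\\tau r}{1000}
        \\frac{\\alpha(e^{1000/(\\tau r)} - 1)}{e^{1000/(\\tau r)} - (1-\\alpha)}

    which is practically linear with slope ~0.00175 per Hz for rates below
    150 Hz (tau = 2 ms, alpha = 0.9).  Non-positive rates return 0.
    """
    r = np.atleast_1d(np.asarray(r, dtype=np.float64))
    out = np.zeros_like(r)
    pos = r > 0
    x = 1000.0 / (tau * r[pos])  # inter-spike interval in units of tau
    with np.errstate(over="ignore", invalid="ignore"):
        val = (tau * r[pos] / 1000.0) * alpha * np.expm1(x) / (np.exp(x) - (1.0 - alpha))
    # for very low rates the exponentials overflow; the ratio tends to 1
    val = np.where(x > 500.0, tau * r[pos] / 1000.0 * alpha, val)
    out[pos] = val
    if out.size == 1 and np.isscalar(tau):
        return float(out[0])
    return out


def kir_current(v_d, s_gabab_sum, g: float = 130.0 / _NI,
                e_rev: float = -90.0):
    """GABA-B/KIR current through one synapse's conductance.

    ``I = g (0.05 + 0.95 s) (V_d - E) / (1 + exp(0.1 (V_d - E + 10)))``:
    5% of the conductance is constitutively active, 95% gated by the summed
    GABA-B activation; the sigmoidal factor is the inward rectification,
    shutting the channel at depolarized voltages.
    """
    v_d = np.asarray(v_d, dtype=np.float64)
    cond = g * (0.05 + 0.95 * np.asarray(s_gabab_sum, dtype=np.float64))
    rect = 1.0 / (1.0 + np.exp(0.1 * (v_d - e_rev + 10.0)))
    out = cond * (v_d - e_rev) * rect
    return float(out) if out.ndim == 0 else out


def ts_input_current(s_input, g_input: float, v, e_syn: float = 0.0):
    """External TS synaptic current ``I = s_input g_input (V - E_syn)``
    with ``s_input = 0.00175 r`` the linearized activation of a channel
    firing at ``r`` Hz."""
    out = np.asarray(s_input, dtype=np.float64) * g_input * (np.asarray(v) - e_syn)
    return float(out) if out.ndim == 0 else out


def mg_block(v, mg_mm: float = 1.0):
    """NMDA magnesium-block factor ``1/(1 + exp(-0.062 V) [Mg]/3.57)``."""
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(v, dtype=np.float64)) * mg_mm / 3.57)


def start_signal(seed, duration: float, n_channels: int = _NP,
                 t_min: float = 15.0, t_max: float = 30.0,
                 period: float = 10.0) -> list[np.ndarray]:
    """Sequence start signal: per channel, one spike at U(t_min, t_max)
    then strictly periodic spikes every ``period`` ms until ``duration``.

    The start signal drives AMPA and NMDA on every cell of the first
    module at the feedforward conductances, standing in for an upstream
    "sequence begins" volley that primes module 1.
    """
    if duration <= t_max:
        raise ValueError(f"duration must exceed {t_max} ms")
    rng = np.random.default_rng(seed)
    first = rng.uniform(t_min, t_max, size=n_channels)
    return [np.arange(f, duration, period) for f in first]


# ---------------------------------------------------------------------------
# rasters and results

@dataclass
class SpikeRaster:
    """Flat spike table: parallel arrays of time (ms), module, within-class
    cell index and excitatory/inhibitory flag."""

    times: np.ndarray
    module: np.ndarray
    cell: np.ndarray
    is_exc: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def select(self, module: int | None = None, exc: bool | None = None,
               t_min: float | None = None, t_max: float | None = None) -> "SpikeRaster":
        m = np.ones(self.times.size, dtype=bool)
        if module is not None:
            m &= self.module == module
        if exc is not None:
            m &= self.is_exc == exc
        if t_min is not None:
            m &= self.times >= t_min
        if t_max is not None:
            m &= self.times <= t_max
        return SpikeRaster(self.times[m], self.module[m], self.cell[m], self.is_exc[m])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "cell_id": self.cell,
            "module": self.module,
            "cell_class": np.where(self.is_exc, "E", "I"),
            "t_ms": self.times,
        })


@dataclass
class SpikingResult:
    """Output of one network simulation."""

    raster: SpikeRaster
    params: SpikingParams
    #: per-module synaptic pool sums over time, keys:
    #: sum_ampa, sum_nmda, sum_gabaa, sum_gabab (shape (n_rec, n_modules)),
    #: start_ampa, start_nmda, ts_total (shape (n_rec,))
    pools: dict[str, np.ndarray]
    pool_times: np.ndarray
    voltage_times: np.ndarray | None = None
    v_dend: np.ndarray | None = None   # (n_recorded_cells, n_rec)
    v_soma: np.ndarray | None = None
    recorded_cells: list[tuple[int, int]] | None = None

    def drive_at(self, t: float, module: int) -> "DendriticDrive":
        """Synaptic pool sums seen by an excitatory dendrite of ``module``
        at simulation time ``t`` (for energy-landscape evaluation)."""
        k = int(np.argmin(np.abs(self.pool_times - t)))
        p = self.pools
        ff_a = p["start_ampa"][k] if module == 0 else p["sum_ampa"][k, module - 1]
        ff_n = p["start_nmda"][k] if module == 0 else p["sum_nmda"][k, module - 1]
        return DendriticDrive(
            ampa_sum=float(p["sum_ampa"][k, module] + ff_a),
            nmda_sum=float(p["sum_nmda"][k, module] + ff_n),
            ts_s_input=0.0,
            gabaa_sum=float(p["sum_gabaa"][k, module]),
            gabab_sum=float(p["sum_gabab"][k, module]),
        )


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    """Spike raster as CSV (cell_id, module, cell_class, t_ms)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "module", "cell_class", "t_ms"])
        for t, m, c, e in zip(raster.times, raster.module, raster.cell, raster.is_exc):
            w.writerow([int(c), int(m), "E" if e else "I", repr(float(t))])


def read_raster(path: str | Path) -> SpikeRaster:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return SpikeRaster(
        times=np.array([float(r["t_ms"]) for r in rows]),
        module=np.array([int(r["module"]) for r in rows]),
        cell=np.array([int(r["cell_id"]) for r in rows]),
        is_exc=np.array([r["cell_class"] == "E" for r in rows]),
    )


def active_cells(raster: SpikeRaster, duration: float, n_modules: int = 3,
                 window: float = 50.0, min_spikes: int = 2) -> list[set[int]]:
    """Excitatory cells with >= ``min_spikes`` spikes in the last ``window``
    ms, per module -- the persistent "snapshot" readout."""
    if duration < window:
        raise ValueError("raster shorter than readout window")
    sel = raster.select(exc=True, t_min=duration - window)
    out: list[set[int]] = []
    for m in range(n_modules):
        cells = sel.cell[sel.module == m]
        if cells.size == 0:
            out.append(set())
            continue
        ids, counts = np.unique(cells, return_counts=True)
        out.append({int(i) for i, c in zip(ids, counts) if c >= min_spikes})
    return out


# ---------------------------------------------------------------------------
# gating kinetics (Wang-Buzsaki-style rate functions)

def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the x -> 0 limit handled."""
    x = np.asarray(x, dtype=np.float64)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    return np.where(small, y, safe / (1.0 - np.exp(-safe / y)))


def _alpha_m(v):
    return 0.1 * _vtrap(v + 35.0, 10.0)


def _beta_m(v):
    return 4.0 * np.exp(-(v + 60.0) / 18.0)


def _alpha_h(v):
    return 0.07 * np.exp(-(v + 58.0) / 20.0)


def _beta_h(v):
    return 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))


def _alpha_n(v):
    return 0.01 * _vtrap(v + 34.0, 10.0)


def _beta_n(v):
    return 0.125 * np.exp(-(v + 44.0) / 80.0)


def _m_inf(v):
    a, b = _alpha_m(v), _beta_m(v)
    return a / (a + b)


def _gate_inf(alpha, beta, v):
    a, b = alpha(v), beta(v)
    return a / (a + b)


# ---------------------------------------------------------------------------
# the network simulation

def simulate_spiking(
    params: SpikingParams,
    ts_input: RateTrajectory,
    seed: int | np.random.Generator | None = None,
    record_cells: Sequence[tuple[int, int]] | None = None,
    record_every: int = 20,
) -> SpikingResult:
    """Euler-integrate the full network driven by a TS rate trajectory.

    Architecture: within each module every E cell synapses on every other E
    cell (AMPA + NMDA) and on every I cell; the same weights feed forward
    onto the next module's E and I cells; I cells inhibit the E cells of
    their own module (GABA-A and slow GABA-B/KIR).  TS channel ``i`` drives
    E cell ``i`` of every module and every I cell; module 1 additionally
    receives the sequence start signal.

    ``record_cells`` is a list of ``(module, e_cell_index)`` whose dendritic
    and somatic voltages are stored every ``record_every`` steps.

    Raises :class:`NumericalDivergence` if any voltage magnitude exceeds
    ``params.v_abort``.
    """
    p = params
    if ts_input.n_channels != p.n_exc:
        raise ValueError(
            f"TS trajectory has {ts_input.n_channels} channels, need {p.n_exc}"
        )
    if abs(ts_input.dt - p.dt) > 1e-12:
        raise ValueError("TS trajectory dt must match integration dt")
    n_steps = int(round(p.duration / p.dt))
    if ts_input.rates.shape[1] < n_steps:
        raise ValueError("TS trajectory shorter than the simulation")
    rng = np.random.default_rng(seed)
    dt, M, NP, NI = p.dt, p.n_modules, p.n_exc, p.n_inh

    # TS synaptic activation (linearized in rate), per channel and summed
    s_in = p.s_input_slope * ts_input.rates[:, :n_steps]
    s_in_total = s_in.sum(axis=0)

    # start-signal spike schedule
    first = rng.uniform(p.start_t_min, p.start_t_max, size=NP)
    first_step = np.round(first / dt).astype(np.int64)
    period_steps = int(round(p.start_period / dt))

    # per-cell heterogeneity of the excitatory somatic parameters
    if p.het_cv > 0:
        fac_gls = np.clip(1 + p.het_cv * rng.standard_normal((M, NP)), 0.6, 1.4)
        fac_gc = np.clip(1 + p.het_cv * rng.standard_normal((M, NP)), 0.6, 1.4)
    else:
        fac_gls = fac_gc = np.ones((M, NP))
    gls_e = p.g_leak_s * fac_gls
    gc_s_e = (p.g_c / p.p_soma) * fac_gc
    gc_d_e = (p.g_c / (1.0 - p.p_soma)) * fac_gc

    # state -- excitatory cells
    vd = np.full((M, NP), p.e_leak_d)
    vs = np.full((M, NP), p.e_leak_s)
    h_e = _gate_inf(_alpha_h, _beta_h, vs)
    n_e = _gate_inf(_alpha_n, _beta_n, vs)
    sa_e = np.zeros((M, NP))
    sn_e = np.zeros((M, NP))
    gn_e = np.zeros((M, NP))   # risen NMDA conductance gate
    refr_e = np.zeros((M, NP), dtype=np.int64)
    # interneurons
    vi = np.full((M, NI), p.e_leak_i)
    h_i = _gate_inf(_alpha_h, _beta_h, vi)
    n_i = _gate_inf(_alpha_n, _beta_n, vi)
    sga = np.zeros((M, NI))
    xb = np.zeros((M, NI))
    gb = np.zeros((M, NI))  # G-protein level of the GABA-B cascade
    refr_i = np.zeros((M, NI), dtype=np.int64)
    last_spike_i = np.full((M, NI), -np.inf)
    run_i = np.zeros((M, NI), dtype=np.int64)  # consecutive short-ISI count
    # start-signal synapses
    sa_st = np.zeros(NP)
    sn_st = np.zeros(NP)
    gn_st = np.zeros(NP)

    refr_steps = max(int(round(p.refractory / dt)), 1)
    dec_a = np.exp(-dt / p.tau_ampa)
    dec_n = np.exp(-dt / p.tau_nmda)
    dec_ga = np.exp(-dt / p.tau_gabaa)
    dec_x = np.exp(-dt / p.tau_gabab_x)
    gc_s = p.g_c / p.p_soma
    gc_d = p.g_c / (1.0 - p.p_soma)

    # recording
    rec_stride = max(record_every, 1)
    n_rec = n_steps // rec_stride + 1
    pools = {
        "sum_ampa": np.zeros((n_rec, M)),
        "sum_nmda": np.zeros((n_rec, M)),
        "sum_gabaa": np.zeros((n_rec, M)),
        "sum_gabab": np.zeros((n_rec, M)),
        "start_ampa": np.zeros(n_rec),
        "start_nmda": np.zeros(n_rec),
        "ts_total": np.zeros(n_rec),
        "n_up": np.zeros((n_rec, M), dtype=np.int64),
    }
    pool_times = np.zeros(n_rec)
    if record_cells:
        v_dend = np.zeros((len(record_cells), n_rec))
        v_soma = np.zeros((len(record_cells), n_rec))
        rc_m = np.array([c[0] for c in record_cells])
        rc_i = np.array([c[1] for c in record_cells])
    else:
        v_dend = v_soma = None

    spk_t: list[np.ndarray] = []
    spk_m: list[np.ndarray] = []
    spk_c: list[np.ndarray] = []
    spk_e: list[np.ndarray] = []

    for k in range(n_steps):
        # ---- pool sums at time t
        sum_a = sa_e.sum(axis=1)
        sum_n = gn_e.sum(axis=1)
        sum_ga = sga.sum(axis=1)
        sum_b = gb.sum(axis=1)
        st_a = sa_st.sum()
        st_n = gn_st.sum()
        ff_a = np.concatenate(([st_a], sum_a[:-1]))
        ff_n = np.concatenate(([st_n], sum_n[:-1]))

        if k % rec_stride == 0:
            j = k // rec_stride
            pool_times[j] = k * dt
            pools["sum_ampa"][j] = sum_a
            pools["sum_nmda"][j] = sum_n
            pools["sum_gabaa"][j] = sum_ga
            pools["sum_gabab"][j] = sum_b
            pools["start_ampa"][j] = st_a
            pools["start_nmda"][j] = st_n
            pools["ts_total"][j] = s_in_total[k]
            pools["n_up"][j] = (vd > -40.0).sum(axis=1)
            if record_cells:
                v_dend[:, j] = vd[rc_m, rc_i]
                v_soma[:, j] = vs[rc_m, rc_i]

        # ---- excitatory dendrite currents (outward positive)
        g_a = p.g_ampa_ee * ((sum_a + ff_a)[:, None] - sa_e)
        g_n = p.g_nmda_ee * ((sum_n + ff_n)[:, None] - gn_e)
        b_d = mg_block(vd, p.mg_mm)
        i_d = p.g_leak_d * (vd - p.e_leak_d)
        i_d += g_a * (vd - p.e_exc)
        i_d += g_n * b_d * (vd - p.e_exc)
        if p.ts_target == "dend":
            i_d += p.g_ts_e * s_in[:, k][None, :] * (vd - p.e_exc)
        i_d += p.g_gabaa_e * sum_ga[:, None] * (vd - p.e_gabaa)
        kir_cond = p.g_gabab * (p.kir_basal_frac * p.kir_basal_synapses
                                + (1 - p.kir_basal_frac) * sum_b[:, None])
        i_d += kir_cond * (vd - p.e_gabab_kir) / (
            1.0 + np.exp(0.1 * (vd - p.e_gabab_kir + 10.0)))
        i_d += gc_d_e * (vd - vs)

        # ---- excitatory soma currents
        m_s = _m_inf(vs)
        i_s = gls_e * (vs - p.e_leak_s)
        i_s += p.g_na_e * m_s ** 3 * h_e * (vs - p.e_na)
        i_s += p.g_kdr_e * n_e ** 4 * (vs - p.e_k)
        i_s += gc_s_e * (vs - vd)
        if p.ts_target == "soma":
            i_s += p.g_ts_e * s_in[:, k][None, :] * (vs - p.e_exc)

        # ---- interneuron currents
        g_a_i = p.g_ampa_ei * (sum_a + ff_a)
        g_n_i = p.g_nmda_ei * (sum_n + ff_n)
        b_i = mg_block(vi, p.mg_mm)
        i_i = p.g_leak_i * (vi - p.e_leak_i)
        i_i += g_a_i[:, None] * (vi - p.e_exc)
        i_i += g_n_i[:, None] * b_i * (vi - p.e_exc)
        i_i += p.g_ts_i * s_in_total[k] * (vi - p.e_exc)
        m_i = _m_inf(vi)
        i_i += p.g_na_i * m_i ** 3 * h_i * (vi - p.e_na)
        i_i += p.g_k_i * n_i ** 4 * (vi - p.e_k)

        # ---- Euler update (Euler-Maruyama for the current noise)
        vs_prev = vs.copy()
        vi_prev = vi.copy()
        vd = vd - dt / p.c_m * i_d
        vs = vs - dt / p.c_m * i_s
        vi = vi - dt / p.c_m * i_i
        if p.noise_sd > 0:
            amp = p.noise_sd * np.sqrt(dt) / p.c_m
            vd = vd + amp * rng.standard_normal(vd.shape)
            vs = vs + amp * rng.standard_normal(vs.shape)
            vi = vi + amp * rng.standard_normal(vi.shape)
        h_e = h_e + dt * p.phi_e * (_alpha_h(vs_prev) * (1 - h_e) - _beta_h(vs_prev) * h_e)
        n_e = n_e + dt * p.phi_e * (_alpha_n(vs_prev) * (1 - n_e) - _beta_n(vs_prev) * n_e)
        h_i = h_i + dt * p.phi_i * (_alpha_h(vi_prev) * (1 - h_i) - _beta_h(vi_prev) * h_i)
        n_i = n_i + dt * p.phi_i * (_alpha_n(vi_prev) * (1 - n_i) - _beta_n(vi_prev) * n_i)

        # ---- spike detection (upward somatic threshold crossing)
        spike_e = (vs_prev < p.spike_threshold) & (vs >= p.spike_threshold) & (refr_e <= 0)
        spike_i = (vi_prev < p.spike_threshold) & (vi >= p.spike_threshold) & (refr_i <= 0)
        refr_e = np.where(spike_e, refr_steps, refr_e - 1)
        refr_i = np.where(spike_i, refr_steps, refr_i - 1)
        spike_st = (k >= first_step) & ((k - first_step) % period_steps == 0)

        # ---- synaptic updates: decay, then saturating spike increment
        sa_e *= dec_a
        sn_e *= dec_n
        gn_e = gn_e + dt / p.tau_nmda_rise * (sn_e - gn_e)
        sga *= dec_ga
        xb *= dec_x
        sa_st *= dec_a
        sn_st *= dec_n
        gn_st = gn_st + dt / p.tau_nmda_rise * (sn_st - gn_st)
        if spike_e.any():
            sa_e = np.where(spike_e, sa_e + p.alpha_ampa * (1 - sa_e), sa_e)
            sn_e = np.where(spike_e, sn_e + p.alpha_nmda * (1 - sn_e), sn_e)
        if spike_i.any():
            t_now = (k + 1) * dt
            sga = np.where(spike_i, sga + p.alpha_gabaa * (1 - sga), sga)
            isi = t_now - last_spike_i
            run_i = np.where(spike_i,
                             np.where(isi <= p.gabab_isi_cut, run_i + 1, 0),
                             run_i)
            recruit = spike_i & (run_i >= p.gabab_min_run)
            facil = np.exp(-isi / p.tau_gabab_facil)
            xb = np.where(recruit, xb + p.alpha_gabab * facil * (1 - xb), xb)
            last_spike_i = np.where(spike_i, t_now, last_spike_i)
        xbn = xb ** p.gabab_hill
        gb = gb + dt / p.tau_gabab_s * (
            xbn / (xbn + p.gabab_k ** p.gabab_hill) - gb)
        if spike_st.any():
            sa_st = np.where(spike_st, sa_st + p.alpha_ampa * (1 - sa_st), sa_st)
            sn_st = np.where(spike_st, sn_st + p.alpha_nmda * (1 - sn_st), sn_st)

        # ---- record spikes
        if spike_e.any():
            m_idx, c_idx = np.nonzero(spike_e)
            spk_t.append(np.full(m_idx.size, (k + 1) * dt))
            spk_m.append(m_idx)
            spk_c.append(c_idx)
            spk_e.append(np.ones(m_idx.size, dtype=bool))
        if spike_i.any():
            m_idx, c_idx = np.nonzero(spike_i)
            spk_t.append(np.full(m_idx.size, (k + 1) * dt))
            spk_m.append(m_idx)
            spk_c.append(c_idx)
            spk_e.append(np.zeros(m_idx.size, dtype=bool))

        if k % 400 == 0:
            vmax = max(np.abs(vd).max(), np.abs(vs).max(), np.abs(vi).max())
            if not np.isfinite(vmax) or vmax > p.v_abort:
                raise NumericalDivergence(
                    f"voltage magnitude {vmax:.1f} mV at t={k * dt:.2f} ms"
                )

    raster = SpikeRaster(
        times=np.concatenate(spk_t) if spk_t else np.empty(0),
        module=np.concatenate(spk_m) if spk_m else np.empty(0, dtype=np.int64),
        cell=np.concatenate(spk_c) if spk_c else np.empty(0, dtype=np.int64),
        is_exc=np.concatenate(spk_e) if spk_e else np.empty(0, dtype=bool),
    )
    return SpikingResult(
        raster=raster, params=p, pools=pools, pool_times=pool_times,
        voltage_times=pool_times if record_cells else None,
        v_dend=v_dend, v_soma=v_soma,
        recorded_cells=list(record_cells) if record_cells else None,
    )


# ---------------------------------------------------------------------------
# single-cell reduction and energy landscape

@dataclass(frozen=True)
class DendriticDrive:
    """Frozen synaptic pool sums seen by one excitatory dendrite.

    ``*_sum`` fields are summed activation variables over the presynaptic
    pool (so the pool conductance is the per-synapse maximal conductance
    times the sum); ``ts_s_input`` is the activation of the cell's own TS
    channel (0.00175 times its rate in Hz).
    """

    ampa_sum: float = 0.0
    nmda_sum: float = 0.0
    ts_s_input: float = 0.0
    gabaa_sum: float = 0.0
    gabab_sum: float = 0.0


def dendritic_current(params: SpikingParams, drive: DendriticDrive, v,
                      vs_fixed: float | None = None):
    """Net outward steady-state dendritic current at voltage ``v`` with all
    synaptic activations frozen at ``drive``.

    Includes the coupling current to a soma held at ``vs_fixed`` (the
    somatic leak reversal when None).
    """
    p = params
    v = np.asarray(v, dtype=np.float64)
    vs0 = p.e_leak_s if vs_fixed is None else vs_fixed
    i = p.g_leak_d * (v - p.e_leak_d)
    i = i + p.g_ampa_ee * drive.ampa_sum * (v - p.e_exc)
    i = i + p.g_nmda_ee * drive.nmda_sum * mg_block(v, p.mg_mm) * (v - p.e_exc)
    i = i + ts_input_current(drive.ts_s_input, p.g_ts_e, v, p.e_exc)
    i = i + p.g_gabaa_e * drive.gabaa_sum * (v - p.e_gabaa)
    kir_cond = p.g_gabab * (p.kir_basal_frac * p.kir_basal_synapses
                            + (1 - p.kir_basal_frac) * drive.gabab_sum)
    i = i + kir_cond * (v - p.e_gabab_kir) / (
        1.0 + np.exp(0.1 * (v - p.e_gabab_kir + 10.0)))
    i = i + p.g_c / (1.0 - p.p_soma) * (v - vs0)
    return i


@dataclass
class EnergyLandscape:
    """Quasi-potential of the dendritic voltage under frozen activations.

    ``i_ss`` is the net outward steady-state current, so the voltage flows
    downhill on ``energy(V) = integral of i_ss dV`` and the stable voltages
    (wells) are the zero crossings of ``i_ss`` with positive slope.
    """

    v_grid: np.ndarray
    energy: np.ndarray
    i_ss: np.ndarray
    minima: np.ndarray

    @property
    def n_wells(self) -> int:
        return int(self.minima.size)


def energy_landscape(params: SpikingParams, drive: DendriticDrive,
                     v_grid: np.ndarray | None = None,
                     vs_fixed: float | None = None) -> EnergyLandscape:
    """Energy landscape of one dendrite with frozen synaptic activations.

    The energy is the integral of the net outward current over voltage
    (trapezoidal quadrature on ``v_grid``); its local minima -- the stable
    dendritic voltages -- are located where the current crosses zero with
    positive slope, refined by linear interpolation between grid points.
    """
    from scipy.integrate import cumulative_trapezoid

    if v_grid is None:
        v_grid = np.arange(-100.0, 0.0 + 1e-9, 0.05)
    i_ss = dendritic_current(params, drive, v_grid, vs_fixed=vs_fixed)
    energy = np.concatenate(([0.0], cumulative_trapezoid(i_ss, v_grid)))
    crossings = []
    for k in range(len(v_grid) - 1):
        if i_ss[k] < 0.0 <= i_ss[k + 1]:
            # linear interpolation of the zero crossing
            f = i_ss[k] / (i_ss[k] - i_ss[k + 1])
            crossings.append(v_grid[k] + f * (v_grid[k + 1] - v_grid[k]))
    return EnergyLandscape(v_grid=v_grid, energy=energy, i_ss=i_ss,
                           minima=np.array(crossings))


def simulate_single_cell(
    params: SpikingParams,
    schedule: Sequence[tuple[float, DendriticDrive]],
    duration: float,
    couple_soma: bool = True,
) -> dict[str, np.ndarray]:
    """Integrate one excitatory cell under a piecewise-constant drive.

    ``schedule`` is a list of ``(t_start_ms, drive)`` pairs in increasing
    time order; each drive holds until the next entry.  Returns a dict with
    keys ``t``, ``v_dend``, ``v_soma`` and ``spikes`` (somatic threshold
    crossings).  With ``couple_soma=False`` the dendrite is integrated in
    isolation against a fixed resting soma (useful for checking that the
    landscape's wells are where the dynamics settle).
    """
    p = params
    dt = p.dt
    n_steps = int(round(duration / dt))
    starts = [t for t, _ in schedule]
    drives = [d for _, d in schedule]
    vd = p.e_leak_d
    vs = p.e_leak_s
    h = float(_gate_inf(_alpha_h, _beta_h, np.array(vs)))
    n = float(_gate_inf(_alpha_n, _beta_n, np.array(vs)))
    gc_s = p.g_c / p.p_soma
    gc_d = p.g_c / (1.0 - p.p_soma)
    t_arr = np.arange(n_steps + 1) * dt
    vd_arr = np.empty(n_steps + 1)
    vs_arr = np.empty(n_steps + 1)
    vd_arr[0], vs_arr[0] = vd, vs
    spikes = []
    refr_until = -np.inf
    idx = 0
    for k in range(n_steps):
        t = k * dt
        while idx + 1 < len(starts) and t >= starts[idx + 1]:
            idx += 1
        drive = drives[idx]
        i_d = dendritic_current(p, drive, vd, vs_fixed=vs if couple_soma else None)
        if not couple_soma:
            vd = vd - dt / p.c_m * i_d
            vd_arr[k + 1] = vd
            vs_arr[k + 1] = vs
            continue
        m = float(_m_inf(np.array(vs)))
        i_s = (p.g_leak_s * (vs - p.e_leak_s)
               + p.g_na_e * m ** 3 * h * (vs - p.e_na)
               + p.g_kdr_e * n ** 4 * (vs - p.e_k)
               + gc_s * (vs - vd))
        # dendritic_current already contains the coupling to vs
        vs_new = vs - dt / p.c_m * i_s
        vd_new = vd - dt / p.c_m * i_d
        h += dt * p.phi_e * (_alpha_h(vs) * (1 - h) - _beta_h(vs) * h)
        n += dt * p.phi_e * (_alpha_n(vs) * (1 - n) - _beta_n(vs) * n)
        if vs < p.spike_threshold <= vs_new and t >= refr_until:
            spikes.append((k + 1) * dt)
            refr_until = t + p.refractory
        vd, vs = vd_new, vs_new
        vd_arr[k + 1], vs_arr[k + 1] = vd, vs
    return {"t": t_arr, "v_dend": vd_arr, "v_soma": vs_arr,
            "spikes": np.array(spikes)}
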