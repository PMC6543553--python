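"""Fully interconnected integrate-and-fire cortical network.

Each tonotopic channel of the periphery drives exactly one cortical neuron;
all cortical neurons are mutually connected.  Synaptic strengths are integer
codes in [-5, 5]: positive codes make excitatory conductance synapses
(reversal -30 mV), negative codes inhibitory ones (reversal -90 mV), zero
means no synapse.  The membrane follows a conductance-based leaky
integrate-and-fire equation,

    tau_m dv/dt = (v_rest - v) + R_m * sum_s g_s(t) * (v_rev,s - v) + tonic,

integrated by exponential Euler at a 0.25 ms step.  Synaptic conductances
have an alpha time course ``A * (t/tau_s) * exp(-t/tau_s)`` (peak ``A/e`` at
``t = tau_s``), advanced by the exact two-state recursion.  On threshold
crossing the membrane is reset to the after-hyperpolarization potential v_K
and clamped for an absolute refractory period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .periphery import ChannelBank, DischargeTrain

__all__ = [
    "NeuronParams",
    "Genome",
    "NetworkConfig",
    "SpikeRecord",
    "decode_genome",
    "alpha_current",
    "simulate_network",
    "tonic_offset_mv",
]

GENE_LOW = -5
GENE_HIGH = 5
#: decoded peripheral delay = DELAY_BASE_MS + DELAY_STEP_MS * code, spanning 0-50 ms
DELAY_BASE_MS = 25.0
DELAY_STEP_MS = 5.0


@dataclass(frozen=True)
class NeuronParams:
    """Integrate-and-fire membrane and synapse constants.

    Membrane/synapse values follow the published cortical-neuron parameter
    set (tau_m 10 ms, v_rest -70 mV, R_m 4 MOhm, reversals -30/-90 mV,
    g_m 2 uS, tau_s 2 ms, step 0.25 ms).  Threshold, reset and refractory
    period are declared defaults of this package: v_thresh -50 mV, reset to
    v_k -90 mV (doubling as the after-hyperpolarization potential),
    refractory 1 ms.  ``tonic_rate_hz`` > 0 enables a constant depolarizing
    drive sized analytically to produce that firing rate in silence.
    """

    tau_m_ms: float = 10.0
    v_rest_mv: float = -70.0
    r_m_mohm: float = 4.0
    v_e_mv: float = -30.0
    v_i_mv: float = -90.0
    v_k_mv: float = -90.0
    g_m_us: float = 2.0
    tau_s_ms: float = 2.0
    dt_ms: float = 0.25
    v_thresh_mv: float = -50.0
    refractory_ms: float = 1.0
    tonic_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        if not (self.v_k_mv <= self.v_rest_mv < self.v_thresh_mv < self.v_e_mv):
            raise ValueError("require v_k <= v_rest < v_thresh < v_e")
        if self.dt_ms <= 0 or self.tau_m_ms <= 0 or self.tau_s_ms <= 0:
            raise ValueError("time constants and step must be positive")


def tonic_offset_mv(params: NeuronParams) -> float:
    """Constant depolarization (mV) yielding ``tonic_rate_hz`` in silence.

    From the closed-form period of leaky integration from reset v_k to
    threshold toward a steady state v_ss: T = tau_m * ln((v_ss - v_k) /
    (v_ss - v_thresh)) + refractory; solved for v_ss.
    """
    if params.tonic_rate_hz <= 0:
        return 0.0
    period_ms = 1000.0 / params.tonic_rate_hz - params.refractory_ms
    if period_ms <= 0:
        raise ValueError("tonic rate too high for the refractory period")
    r = math.exp(period_ms / params.tau_m_ms)
    v_ss = params.v_thresh_mv + (params.v_thresh_mv - params.v_k_mv) / (r - 1.0)
    return v_ss - params.v_rest_mv


@dataclass(frozen=True)
class Genome:
    """Integer-coded network parameters: the search object of the fit.

    w[i, j]  cortico-cortical synapse code from presynaptic neuron i to
             postsynaptic neuron j (0 = none)
    istr[c]  peripheral input strength code into cortical neuron c
    idel[c]  peripheral input delay code (decoded to 0-50 ms)

    All entries are integers in [-5, 5]; a 15-neuron network has
    225 + 15 + 15 = 255 genes.
    """

    w: np.ndarray
    istr: np.ndarray
    idel: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=int)
        istr = np.asarray(self.istr, dtype=int)
        idel = np.asarray(self.idel, dtype=int)
        n = w.shape[0]
        if w.shape != (n, n) or istr.shape != (n,) or idel.shape != (n,):
            raise ValueError("genome shape mismatch")
        for name, arr in (("w", w), ("istr", istr), ("idel", idel)):
            if arr.min(initial=0) < GENE_LOW or arr.max(initial=0) > GENE_HIGH:
                raise ValueError(f"genome {name} entries must lie in [{GENE_LOW}, {GENE_HIGH}]")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "istr", istr)
        object.__setattr__(self, "idel", idel)

    @property
    def n_neurons(self) -> int:
        return self.w.shape[0]

    @property
    def n_genes(self) -> int:
        n = self.n_neurons
        return n * n + 2 * n

    def flat(self) -> np.ndarray:
        """Row-major w, then istr, then idel."""
        return np.concatenate([self.w.ravel(), self.istr, self.idel])

    @classmethod
    def from_flat(cls, values: np.ndarray, n_neurons: int) -> "Genome":
        values = np.asarray(values, dtype=int)
        n = n_neurons
        if values.shape != (n * n + 2 * n,):
            raise ValueError("flat genome length mismatch")
        return cls(values[: n * n].reshape(n, n), values[n * n : n * n + n], values[n * n + n :])

    @classmethod
    def zeros(cls, n_neurons: int) -> "Genome":
        n = n_neurons
        return cls(np.zeros((n, n), int), np.zeros(n, int), np.zeros(n, int))


@dataclass(frozen=True)
class NetworkConfig:
    """Decoded, physical form of a genome for a given bank and neuron params."""

    params: NeuronParams
    bank: ChannelBank
    w_amp_us: np.ndarray        # signed synaptic amplitude, uS; sign selects reversal
    cc_delay_ms: np.ndarray     # cortico-cortical transmission delays
    input_amp_us: np.ndarray    # signed peripheral input amplitude per neuron
    input_delay_ms: np.ndarray  # peripheral transmission delay per neuron

    @property
    def n_neurons(self) -> int:
        return len(self.input_amp_us)


def decode_genome(
    genome: Genome,
    params: NeuronParams,
    bank: ChannelBank,
    *,
    cc_base_ms: float = 2.0,
    cc_slope_ms_per_oct: float = 3.0,
) -> NetworkConfig:
    """Map integer codes to synaptic amplitudes and delays.

    Amplitude = (|code| / 5) * g_m, reaching the maximum conductance g_m at
    code +/-5, so the integer codes grade the synapse rather than saturate
    it; the code's sign selects the excitatory or inhibitory reversal
    potential.  Peripheral delay = 25 + 5 * code ms so
    codes -5..+5 span 0-50 ms.  Cortico-cortical delays grow with tonotopic
    separation: base + slope * |octave distance|, reflecting the
    distance-proportional latencies of the tonotopic map.
    """
    if bank.n_channels != genome.n_neurons:
        raise ValueError("bank channel count must equal genome neuron count")
    oct_pos = bank.octaves
    dist = np.abs(oct_pos[:, None] - oct_pos[None, :])
    cc_delay = cc_base_ms + cc_slope_ms_per_oct * dist
    input_delay = DELAY_BASE_MS + DELAY_STEP_MS * genome.idel.astype(float)
    if np.any(input_delay < 0) or np.any(input_delay > 50.0 + 1e-9):
        raise ValueError("decoded peripheral delays outside [0, 50] ms")
    return NetworkConfig(
        params=params,
        bank=bank,
        w_amp_us=genome.w.astype(float) / GENE_HIGH * params.g_m_us,
        cc_delay_ms=cc_delay,
        input_amp_us=genome.istr.astype(float) / GENE_HIGH * params.g_m_us,
        input_delay_ms=input_delay,
    )


def alpha_current(t_since_event_ms, amplitude_us: float, tau_s_ms: float):
    """Alpha-function conductance ``A * (t/tau_s) * exp(-t/tau_s)``, 0 for t <= 0."""
    t = np.asarray(t_since_event_ms, dtype=float)
    out = np.where(
        t > 0, amplitude_us * (t / tau_s_ms) * np.exp(-np.clip(t, 0, None) / tau_s_ms), 0.0
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SpikeRecord:
    """Per-neuron sorted spike times (ms), with optional membrane traces."""

    spike_times_ms: tuple[np.ndarray, ...]
    duration_ms: float
    v_mv: np.ndarray | None = None  # (n_steps, n_neurons) if recorded
    dt_ms: float = 0.25

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times_ms)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.spike_times_ms])


@njit(cache=True)
def _integrate(
    n_steps,
    n,
    dt,
    tau_m,
    v_rest,
    r_m,
    v_e,
    v_i,
    v_k,
    v_th,
    tau_s,
    refr_steps,
    tonic_mv,
    ev_step,
    ev_nrn,
    ev_amp,
    w_amp,
    cc_delay_steps,
    record_v,
    v_out,
    v_init,
):  # pragma: no cover - exercised through simulate_network
    decay = math.exp(-dt / tau_s)
    pe = np.zeros(n)
    ge = np.zeros(n)
    pi_ = np.zeros(n)
    gi = np.zeros(n)
    v = np.full(n, v_init)
    refr = np.zeros(n, dtype=np.int64)
    buf_len = 1
    for i in range(n):
        for j in range(n):
            if w_amp[i, j] != 0.0 and cc_delay_steps[i, j] + 1 > buf_len:
                buf_len = cc_delay_steps[i, j] + 1
    buf_e = np.zeros((buf_len, n))
    buf_i = np.zeros((buf_len, n))
    cap = n_steps * n // (refr_steps + 1) + n + 16
    sp_step = np.empty(cap, dtype=np.int64)
    sp_nrn = np.empty(cap, dtype=np.int64)
    m = 0
    ptr = 0
    n_ev = len(ev_step)
    for s in range(n_steps):
        while ptr < n_ev and ev_step[ptr] == s:
            a = ev_amp[ptr]
            k = ev_nrn[ptr]
            if a > 0.0:
                pe[k] += a
            elif a < 0.0:
                pi_[k] += -a
            ptr += 1
        slot = s % buf_len
        for k in range(n):
            pe[k] += buf_e[slot, k]
            pi_[k] += buf_i[slot, k]
            buf_e[slot, k] = 0.0
            buf_i[slot, k] = 0.0
        scale = decay * dt / tau_s
        for k in range(n):
            ge[k] = decay * ge[k] + scale * pe[k]
            pe[k] = decay * pe[k]
            gi[k] = decay * gi[k] + scale * pi_[k]
            pi_[k] = decay * pi_[k]
        for k in range(n):
            if refr[k] > 0:
                refr[k] -= 1
                v[k] = v_k
                continue
            g_tot = ge[k] + gi[k]
            b = (1.0 + r_m * g_tot) / tau_m
            a_drive = (v_rest + tonic_mv + r_m * (ge[k] * v_e + gi[k] * v_i)) / tau_m
            v_inf = a_drive / b
            v[k] = v_inf + (v[k] - v_inf) * math.exp(-b * dt)
            if v[k] >= v_th:
                sp_step[m] = s + 1
                sp_nrn[m] = k
                m += 1
                v[k] = v_k
                refr[k] = refr_steps
                for j in range(n):
                    a = w_amp[k, j]
                    if a != 0.0:
                        d = cc_delay_steps[k, j]
                        if d < 1:
                            d = 1
                        tgt = (s + d) % buf_len
                        if a > 0.0:
                            buf_e[tgt, j] += a
                        else:
                            buf_i[tgt, j] += -a
        if record_v:
            for k in range(n):
                v_out[s, k] = v[k]
    return sp_step[:m], sp_nrn[:m]


def simulate_network(
    config: NetworkConfig,
    inputs: DischargeTrain,
    duration_ms: float | None = None,
    seed: int | None = None,
    *,
    record_v: bool = False,
    v_init_mv: float | None = None,
) -> SpikeRecord:
    """Run the network on peripheral discharge trains.

    Peripheral channel c drives cortical neuron c only; every peripheral and
    recurrent synaptic event is honored after its transmission delay.  The
    simulation itself is deterministic (all stochasticity lives in the
    periphery); ``seed`` is accepted for interface symmetry and ignored.
    """
    params = config.params
    n = config.n_neurons
    if inputs.n_channels != n:
        raise ValueError(
            f"input train has {inputs.n_channels} channels, network has {n} neurons"
        )
    dt = params.dt_ms
    if duration_ms is None:
        duration_ms = inputs.duration_s * 1000.0
    n_steps = int(round(duration_ms / dt))
    active = config.input_amp_us != 0
    max_delay = float(config.input_delay_ms[active].max(initial=0.0)) if active.any() else 0.0
    if duration_ms < max_delay:
        warnings.warn(
            f"duration {duration_ms} ms shorter than max input delay {max_delay} ms",
            stacklevel=2,
        )

    steps_list = []
    nrn_list = []
    amp_list = []
    for c in range(n):
        amp = config.input_amp_us[c]
        t = inputs.times_s[c]
        if amp == 0.0 or t.size == 0:
            continue
        steps = np.round((t * 1000.0 + config.input_delay_ms[c]) / dt).astype(np.int64)
        keep = steps < n_steps
        steps = steps[keep]
        steps_list.append(steps)
        nrn_list.append(np.full(len(steps), c, dtype=np.int64))
        amp_list.append(np.full(len(steps), amp))
    if steps_list:
        ev_step = np.concatenate(steps_list)
        ev_nrn = np.concatenate(nrn_list)
        ev_amp = np.concatenate(amp_list)
        order = np.argsort(ev_step, kind="stable")
        ev_step, ev_nrn, ev_amp = ev_step[order], ev_nrn[order], ev_amp[order]
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_nrn = np.empty(0, dtype=np.int64)
        ev_amp = np.empty(0)

    cc_delay_steps = np.round(config.cc_delay_ms / dt).astype(np.int64)
    refr_steps = int(round(params.refractory_ms / dt))
    tonic = tonic_offset_mv(params)
    v_out = np.empty((n_steps if record_v else 1, n if record_v else 1))
    sp_step, sp_nrn = _integrate(
        n_steps,
        n,
        dt,
        params.tau_m_ms,
        params.v_rest_mv,
        params.r_m_mohm,
        params.v_e_mv,
        params.v_i_mv,
        params.v_k_mv,
        params.v_thresh_mv,
        params.tau_s_ms,
        refr_steps,
        tonic,
        ev_step,
        ev_nrn,
        ev_amp,
        config.w_amp_us,
        cc_delay_steps,
        record_v,
        v_out,
        params.v_rest_mv if v_init_mv is None else v_init_mv,
    )
    times = sp_step.astype(float) * dt
    per_neuron = tuple(times[sp_nrn == k] for k in range(n))
    return SpikeRecord(
        per_neuron, duration_ms, v_mv=v_out if record_v else None, dt_ms=dt
    )
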