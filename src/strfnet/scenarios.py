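"""Synthetic ground-truth scenarios and fitting targets.

Canonical single- and two-neuron network configurations whose STRFs have
known qualitative features (peak channel, sign, latency ordering): a simple
excitatory cochlear input produces a positive region at its CF, an
inhibitory input a negative one, a longer transmission delay shifts the
region along the lag axis, and a lateral connection from a second tuned
neuron adds a secondary region at that neuron's CF with a later latency.
These stand in for recorded cortical STRFs as fitting targets and as the
package's end-to-end self-test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .network import Genome, NeuronParams, decode_genome, simulate_network
from .optimize import EvalContext, evaluate_strf
from .periphery import DischargeTrain, RateParams, cf_grid, drive_rate, generate_discharges
from .strf import STRF, best_channel, significance_mask
from .torc import ChannelAxis

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "make_scenario",
    "make_target",
    "chirp_signal",
    "latency_shift_ms",
]

SCENARIO_NAMES = (
    "excit_5k",
    "excit_2k5",
    "inhib_5k",
    "excit_5k_delay55",
    "lateral_inhib",
    "lateral_excit",
    "tonic_demo",
    "chirp_demo",
)

#: delay code -4 decodes to 5 ms, the short cochlea-to-cortex transmission delay
SHORT_DELAY_CODE = -4
#: delay code +5 decodes to 50 ms, the top of the decodable delay range
LONG_DELAY_CODE = 5
#: lateral cortico-cortical synapse code: moderate, so the secondary STRF
#: region stays subordinate to the direct-input region
LATERAL_CODE = 3


@dataclass(frozen=True)
class Scenario:
    """Named ground-truth genome with checkable STRF predicates."""

    name: str
    genome: Genome
    recorded_neuron: int
    description: str
    check: Callable[[STRF], bool] | None
    tonic_rate_hz: float = 10.0


def _peak_lag_ms(strf: STRF, channel: int, sign: int = +1) -> float:
    trace = sign * strf.values[:, channel]
    return float(strf.lags_ms[int(np.argmax(trace))])


def latency_shift_ms(delayed: STRF, baseline: STRF) -> float:
    """Peak-lag difference of the two STRFs' positive peaks (same channel)."""
    ch = best_channel(baseline)
    return _peak_lag_ms(delayed, ch) - _peak_lag_ms(baseline, ch)


def _secondary_region_check(strf: STRF, primary_ch: int, secondary_ch: int, sign: int) -> bool:
    """Secondary region at the lateral neuron's CF, later than the primary peak."""
    v = strf.values
    sd = float(np.std(v))
    trace = sign * v[:, secondary_ch]
    if trace.max() < 2.0 * sd:
        return False
    return _peak_lag_ms(strf, secondary_ch, sign) > _peak_lag_ms(strf, primary_ch, +1)


def make_scenario(name: str, n_neurons: int = 15) -> Scenario:
    """Build a named ground-truth scenario on the default tonotopic bank."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")
    bank = cf_grid(n_neurons)
    g = Genome.zeros(n_neurons)
    ch5k = bank.channel_of(5000.0)
    ch2k5 = bank.channel_of(2500.0)
    ch8k = bank.channel_of(8000.0)
    ch3k = bank.channel_of(3000.0)
    ch1k5 = bank.channel_of(1500.0)

    def single_input(ch: int, strength: int, delay_code: int) -> Genome:
        istr = g.istr.copy()
        idel = g.idel.copy()
        istr[ch] = strength
        idel[ch] = delay_code
        return Genome(g.w.copy(), istr, idel)

    if name == "excit_5k":
        genome = single_input(ch5k, 5, SHORT_DELAY_CODE)
        return Scenario(
            name,
            genome,
            ch5k,
            "excitatory cochlear input at 5 kHz -> positive STRF peak at 5 kHz",
            lambda s: best_channel(s) == ch5k,
        )
    if name == "excit_2k5":
        genome = single_input(ch2k5, 5, SHORT_DELAY_CODE)
        return Scenario(
            name,
            genome,
            ch2k5,
            "excitatory cochlear input at 2.5 kHz -> positive STRF peak at 2.5 kHz",
            lambda s: best_channel(s) == ch2k5,
        )
    if name == "inhib_5k":
        genome = single_input(ch5k, -5, SHORT_DELAY_CODE)
        return Scenario(
            name,
            genome,
            ch5k,
            "inhibitory cochlear input at 5 kHz -> negative STRF region at 5 kHz",
            lambda s: (
                s.values.min() < 0
                and int(np.argmin(s.values.min(axis=0))) == ch5k
            ),
        )
    if name == "excit_5k_delay55":
        genome = single_input(ch5k, 5, LONG_DELAY_CODE)
        return Scenario(
            name,
            genome,
            ch5k,
            "excitatory input at 5 kHz with 50 ms (vs 5 ms) transmission delay "
            "-> peak shifted along the lag axis",
            lambda s: best_channel(s) == ch5k,
        )
    if name == "lateral_inhib":
        istr = g.istr.copy()
        idel = g.idel.copy()
        istr[ch8k] = 5
        idel[ch8k] = SHORT_DELAY_CODE
        istr[ch3k] = 5
        idel[ch3k] = SHORT_DELAY_CODE
        w = g.w.copy()
        w[ch3k, ch8k] = -LATERAL_CODE
        genome = Genome(w, istr, idel)
        return Scenario(
            name,
            genome,
            ch8k,
            "8 kHz neuron with inhibitory lateral input from a 3 kHz neuron "
            "-> later negative secondary region at 3 kHz",
            lambda s: best_channel(s) == ch8k
            and _secondary_region_check(s, ch8k, ch3k, sign=-1),
        )
    if name == "lateral_excit":
        istr = g.istr.copy()
        idel = g.idel.copy()
        istr[ch8k] = 5
        idel[ch8k] = SHORT_DELAY_CODE
        istr[ch1k5] = 5
        idel[ch1k5] = SHORT_DELAY_CODE
        w = g.w.copy()
        w[ch1k5, ch8k] = LATERAL_CODE
        genome = Genome(w, istr, idel)
        return Scenario(
            name,
            genome,
            ch8k,
            "8 kHz neuron with excitatory lateral input from a 1.5 kHz neuron "
            "-> later positive secondary region at 1.5 kHz",
            # the relayed excitatory region may rival the direct one in size,
            # so only its presence, sign and later latency are required
            lambda s: _secondary_region_check(s, ch8k, ch1k5, sign=+1),
        )
    if name == "tonic_demo":
        return Scenario(
            name,
            Genome.zeros(n_neurons),
            0,
            "no synaptic input; constant drive produces tonic firing in silence",
            None,
        )
    # chirp_demo
    return Scenario(
        name,
        single_input(ch5k, 5, SHORT_DELAY_CODE),
        ch5k,
        "log-frequency chirp activates peripheral channels in CF order",
        None,
        tonic_rate_hz=0.0,
    )


def make_target(
    scenario: Scenario,
    seed: int = 0,
    *,
    n_torcs: int = 30,
    reps: int = 4,
    duration_s: float | None = None,
    n_neurons: int | None = None,
) -> tuple[STRF, EvalContext]:
    """Run the forward pipeline on a ground-truth genome.

    Returns the estimated STRF (a fitting target standing in for a recorded
    receptive field) together with the evaluation context that generated it,
    so recovery experiments can reuse or vary the generating seeds.
    """
    n = n_neurons or scenario.genome.n_neurons
    ctx = EvalContext.build(
        n_neurons=n,
        n_torcs=n_torcs,
        reps=reps,
        seed=seed,
        duration_s=duration_s,
        recorded_neuron=scenario.recorded_neuron,
        tonic_rate_hz=scenario.tonic_rate_hz,
    )
    target = evaluate_strf(scenario.genome, ctx, scenario.recorded_neuron)
    return target, ctx


def chirp_signal(
    f0_hz: float,
    f1_hz: float,
    duration_s: float,
    sample_rate_hz: float = 48_000.0,
) -> tuple[np.ndarray, float]:
    """Constant-amplitude sweep, linear in log frequency, from f0 to f1."""
    if f0_hz <= 0 or f1_hz <= 0:
        raise ValueError("chirp endpoints must be positive frequencies")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    k = np.log(f1_hz / f0_hz) / duration_s
    if abs(k) < 1e-12:
        phase = 2.0 * np.pi * f0_hz * t
    else:
        phase = 2.0 * np.pi * f0_hz * (np.exp(k * t) - 1.0) / k
    return np.sin(phase), sample_rate_hz
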