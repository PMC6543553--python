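"""Moving-ripple (TORC) stimulus synthesis.

A ripple is a sinusoidal spectral envelope of density ``epsilon`` (cycles per
octave) drifting along the logarithmic frequency axis at velocity ``omega``
(Hz).  A TORC (temporally orthogonal ripple combination) superposes several
ripples with pairwise-distinct temporal velocities; the ensemble
autocorrelation of such a stimulus set approximates a delta function, which is
what makes unbiased reverse-correlation STRF estimation possible.

The dynamic spectrum of a TORC is

    S(t, x) = sum_i a_i * cos(2*pi*(omega_i * t + eps_i * x) + phi_i)

with ``x`` the octave coordinate above the lowest channel frequency.  The
overall amplitude scale is arbitrary: reverse correlation downstream is
normalized by stimulus power, so components default to unit amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RippleComponent",
    "ChannelAxis",
    "TORCSpec",
    "DynamicSpectrum",
    "PhiKernel",
    "make_torc_set",
    "dynamic_spectrum",
    "render_waveform",
    "phi",
]

#: density range (cycles/octave) used for stimulus sets
DENSITY_MAX = 1.4
#: per-TORC base ripple rates (Hz); harmonics k*base, k=1..6 give sets
#: spanning 4-24 Hz and 8-48 Hz
DEFAULT_BASE_RATES = (4.0, 8.0)
DEFAULT_N_RIPPLES = 6
DEFAULT_DURATIONS = (1.0, 1.5, 2.0)
#: envelope sampling step (s); 500 Hz > 2 * 48 Hz ripple Nyquist
DEFAULT_TIME_STEP = 2e-3


@dataclass(frozen=True)
class RippleComponent:
    """One moving spectral ripple.

    amplitude   dimensionless, >= 0 (scale is arbitrary, see module docs)
    velocity_hz signed drift velocity; negative = downward drift
    density_cpo spectral density in cycles/octave, >= 0
    phase_rad   phase offset in radians
    """

    amplitude: float
    velocity_hz: float
    density_cpo: float
    phase_rad: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"ripple amplitude must be >= 0, got {self.amplitude}")
        if self.density_cpo < 0:
            raise ValueError(f"ripple density must be >= 0, got {self.density_cpo}")


@dataclass(frozen=True)
class ChannelAxis:
    """Log-spaced frequency channel axis shared by stimuli and the periphery."""

    f_min_hz: float = 500.0
    octave_span: float = 5.0
    n_channels: int = 15

    def __post_init__(self) -> None:
        if self.f_min_hz <= 0 or self.octave_span <= 0 or self.n_channels < 2:
            raise ValueError("invalid channel axis definition")

    @property
    def octaves(self) -> np.ndarray:
        """Octave coordinate x of each channel above f_min (uniformly spaced)."""
        return np.linspace(0.0, self.octave_span, self.n_channels)

    @property
    def freqs_hz(self) -> np.ndarray:
        return self.f_min_hz * 2.0 ** self.octaves

    def channel_of(self, freq_hz: float) -> int:
        """Index of the channel nearest ``freq_hz`` on the log axis."""
        if freq_hz <= 0:
            raise ValueError("frequency must be positive")
        return int(np.argmin(np.abs(np.log2(self.freqs_hz / freq_hz))))


@dataclass(frozen=True)
class TORCSpec:
    """Parametric description of one TORC stimulus."""

    components: tuple[RippleComponent, ...]
    duration_s: float
    axis: ChannelAxis
    ident: str = "torc"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a TORC needs at least one ripple component")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        speeds = [abs(c.velocity_hz) for c in self.components]
        if len(set(speeds)) != len(speeds):
            raise ValueError(
                "ripple velocities within one TORC must be pairwise distinct "
                "(temporal orthogonality)"
            )

    @property
    def max_velocity_hz(self) -> float:
        return max(abs(c.velocity_hz) for c in self.components)


@dataclass(frozen=True)
class DynamicSpectrum:
    """Time x channel envelope matrix S(t, x) on a uniform grid."""

    values: np.ndarray  # (n_times, n_channels)
    time_step_s: float
    freqs_hz: np.ndarray
    octaves: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("dynamic spectrum values must be 2-D (time x channel)")
        if not np.all(np.isfinite(v)):
            raise ValueError("dynamic spectrum contains non-finite values")
        if v.shape[1] != len(self.freqs_hz) or v.shape[1] != len(self.octaves):
            raise ValueError("channel axis length mismatch")
        dx = np.diff(self.octaves)
        if len(dx) and not np.allclose(dx, dx[0], rtol=1e-9, atol=1e-12):
            raise ValueError("channel octave coordinates must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times * self.time_step_s

    def same_axes(self, other: "DynamicSpectrum") -> bool:
        return (
            math.isclose(self.time_step_s, other.time_step_s)
            and self.n_channels == other.n_channels
            and np.allclose(self.freqs_hz, other.freqs_hz)
        )


@dataclass(frozen=True)
class PhiKernel:
    """Stimulus-ensemble spectrotemporal autocorrelation.

    ``values[k, i, j]`` is the time-averaged lagged product between channels
    ``i`` (at lag 0) and ``j`` (lagged by ``lags_s[k]``), averaged over the
    stimulus ensemble.  Satisfies Phi(tau, x, x') = Phi(-tau, x', x).
    """

    values: np.ndarray  # (n_lags, n_channels, n_channels)
    lags_s: np.ndarray
    freqs_hz: np.ndarray

    def collapsed(self) -> tuple[np.ndarray, np.ndarray]:
        """Channel-difference form: mean over pairs with equal index offset.

        Returns (matrix of shape (n_lags, 2*C-1), channel differences).
        """
        n_lags, c, _ = self.values.shape
        diffs = np.arange(-(c - 1), c)
        out = np.zeros((n_lags, len(diffs)))
        for k, d in enumerate(diffs):
            out[:, k] = np.mean(np.diagonal(self.values, offset=d, axis1=1, axis2=2), axis=-1)
        return out, diffs


def make_torc_set(
    n_torcs: int,
    axis: ChannelAxis | None = None,
    seed: int | None = 0,
    *,
    base_rates_hz: tuple[float, ...] = DEFAULT_BASE_RATES,
    n_ripples: int = DEFAULT_N_RIPPLES,
    density_max_cpo: float = DENSITY_MAX,
    durations_s: tuple[float, ...] = DEFAULT_DURATIONS,
) -> list[TORCSpec]:
    """Generate a reproducible set of TORC specifications.

    Each TORC superposes ``n_ripples`` ripples whose velocities are the
    harmonics k*base of a per-TORC base rate cycled through
    ``base_rates_hz``; drift direction alternates between components.
    Densities are drawn uniformly from [0, density_max_cpo], phases uniformly
    from [0, 2*pi).  Deterministic for a fixed seed.
    """
    if n_torcs < 1:
        raise ValueError(f"n_torcs must be >= 1, got {n_torcs}")
    axis = axis or ChannelAxis()
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_torcs):
        base = base_rates_hz[i % len(base_rates_hz)]
        duration = durations_s[i % len(durations_s)]
        densities = rng.uniform(0.0, density_max_cpo, size=n_ripples)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ripples)
        comps = tuple(
            RippleComponent(
                amplitude=1.0,
                velocity_hz=(k + 1) * base * (1 if (i + k) % 2 == 0 else -1),
                density_cpo=float(densities[k]),
                phase_rad=float(phases[k]),
            )
            for k in range(n_ripples)
        )
        specs.append(TORCSpec(comps, duration, axis, ident=f"torc{i:03d}"))
    return specs


def dynamic_spectrum(spec: TORCSpec, time_step_s: float = DEFAULT_TIME_STEP) -> DynamicSpectrum:
    """Evaluate the TORC envelope S(t, x) on the spec's channel axis.

    Times are bin centers.  The step must resolve the fastest ripple
    (envelope Nyquist): time_step <= 1 / (2 * max |velocity|).
    """
    vmax = spec.max_velocity_hz
    if vmax > 0 and time_step_s > 1.0 / (2.0 * vmax):
        raise ValueError(
            f"time step {time_step_s} s too coarse for ripple velocity "
            f"{vmax} Hz (need <= {1.0 / (2.0 * vmax):.6g} s)"
        )
    n_t = int(math.ceil(spec.duration_s / time_step_s))
    t = (np.arange(n_t) + 0.5) * time_step_s
    x = spec.axis.octaves
    s = np.zeros((n_t, len(x)))
    for c in spec.components:
        s += c.amplitude * np.cos(
            2.0 * np.pi * (c.velocity_hz * t[:, None] + c.density_cpo * x[None, :])
            + c.phase_rad
        )
    return DynamicSpectrum(s, time_step_s, spec.axis.freqs_hz, x)


def render_waveform(
    spec: TORCSpec,
    carriers_per_octave: int = 20,
    audio_sample_rate_hz: float = 48_000.0,
    seed: int | None = 0,
    *,
    modulation_depth: float = 0.9,
    time_step_s: float = DEFAULT_TIME_STEP,
) -> tuple[np.ndarray, float]:
    """Render a TORC as audio: log-spaced tone carriers, each amplitude-
    modulated by the envelope at its octave coordinate.

    Carrier amplitude is (1 + m*S_n)/2 floored at 0, where S_n is the
    envelope normalized to unit peak magnitude, so modulation is nonnegative.
    Carrier phases are random but fixed by ``seed``.  The summed signal is
    peak-normalized to [-1, 1].  Returns ``(signal, sample_rate)``.
    """
    axis = spec.axis
    n_carriers = int(round(carriers_per_octave * axis.octave_span)) + 1
    x_carriers = np.linspace(0.0, axis.octave_span, n_carriers)
    f_carriers = axis.f_min_hz * 2.0 ** x_carriers
    if audio_sample_rate_hz < 2.0 * f_carriers[-1]:
        raise ValueError(
            f"sample rate {audio_sample_rate_hz} Hz below Nyquist of top carrier "
            f"{f_carriers[-1]} Hz"
        )
    rng = np.random.default_rng(seed)
    carrier_phases = rng.uniform(0.0, 2.0 * np.pi, size=n_carriers)

    n_samples = int(round(spec.duration_s * audio_sample_rate_hz))
    t_audio = np.arange(n_samples) / audio_sample_rate_hz

    # envelope on a coarse grid at every carrier coordinate, then interpolated
    n_env = int(math.ceil(spec.duration_s / time_step_s))
    t_env = (np.arange(n_env) + 0.5) * time_step_s
    env = np.zeros((n_env, n_carriers))
    for c in spec.components:
        env += c.amplitude * np.cos(
            2.0 * np.pi * (c.velocity_hz * t_env[:, None] + c.density_cpo * x_carriers[None, :])
            + c.phase_rad
        )
    peak = np.max(np.abs(env))
    if peak > 0:
        env = env / peak

    signal = np.zeros(n_samples)
    for j in range(n_carriers):
        amp = np.interp(t_audio, t_env, env[:, j])
        amp = np.clip((1.0 + modulation_depth * amp) / 2.0, 0.0, None)
        signal += amp * np.sin(2.0 * np.pi * f_carriers[j] * t_audio + carrier_phases[j])
    peak = np.max(np.abs(signal))
    if peak > 0:
        signal = signal / peak
    return signal, audio_sample_rate_hz


def phi(dspecs: list[DynamicSpectrum], max_lag_s: float = 0.25) -> PhiKernel:
    """Ensemble spectrotemporal autocorrelation Phi of a stimulus set.

    Phi(lag, x', x) = <(1/T) * sum_t S(t, x') * S(t - lag, x)> averaged over
    the ensemble; for a TORC set this concentrates at zero lag and zero
    channel difference, which is the delta-like property reverse correlation
    relies on.
    """
    if not dspecs:
        raise ValueError("need at least one dynamic spectrum")
    first = dspecs[0]
    for d in dspecs[1:]:
        if not first.same_axes(d):
            raise ValueError("dynamic spectra do not share channel axis / time step")
    dt = first.time_step_s
    n_lag = int(round(max_lag_s / dt))
    c = first.n_channels
    acc = np.zeros((2 * n_lag + 1, c, c))
    for d in dspecs:
        s = d.values
        n_t = s.shape[0]
        for k in range(n_lag + 1):
            if k >= n_t:
                continue
            # m[i, j] = sum_t S[t, i] * S[t - k, j]
            m = s[k:].T @ s[: n_t - k] / n_t
            acc[n_lag + k] += m
            acc[n_lag - k] += m.T
    # zero lag was accumulated twice into the same slot by the loop above
    acc[n_lag] /= 2.0
    acc /= len(dspecs)
    lags = np.arange(-n_lag, n_lag + 1) * dt
    return PhiKernel(acc, lags, first.freqs_hz)
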