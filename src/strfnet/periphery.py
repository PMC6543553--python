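"""Stochastic auditory-periphery front end.

Converts a stimulus — either a precomputed dynamic spectrum or raw audio —
into discharge trains on log-spaced frequency channels.  The essential
operation is band-pass filtering into tonotopic channels followed by a
stochastic discharge generator; this front end therefore uses a gammatone
filter bank (audio path) or the stimulus envelope directly (dynamic-spectrum
path), mapped affinely to an instantaneous event rate and sampled as an
inhomogeneous Poisson process with an absolute dead time.

Any substitute periphery that produces a :class:`DischargeTrain` on the same
:class:`ChannelBank` is accepted unchanged by the network simulator (adapter
contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .torc import ChannelAxis, DynamicSpectrum

__all__ = [
    "ChannelBank",
    "RateParams",
    "RateFunction",
    "DischargeTrain",
    "cf_grid",
    "drive_rate",
    "generate_discharges",
]


@dataclass(frozen=True)
class ChannelBank:
    """Tonotopic bank of channels with geometrically spaced center frequencies."""

    cf_hz: np.ndarray

    def __post_init__(self) -> None:
        cf = np.asarray(self.cf_hz, dtype=float)
        if cf.ndim != 1 or len(cf) < 2:
            raise ValueError("channel bank needs at least 2 center frequencies")
        if np.any(np.diff(cf) <= 0):
            raise ValueError("center frequencies must be strictly increasing")
        ratios = cf[1:] / cf[:-1]
        if not np.allclose(ratios, ratios[0], rtol=1e-9):
            raise ValueError("center frequencies must be log-spaced")
        object.__setattr__(self, "cf_hz", cf)

    @property
    def n_channels(self) -> int:
        return len(self.cf_hz)

    @property
    def octaves(self) -> np.ndarray:
        """Octave coordinate of each channel above the lowest CF."""
        return np.log2(self.cf_hz / self.cf_hz[0])

    def axis(self) -> ChannelAxis:
        return ChannelAxis(
            f_min_hz=float(self.cf_hz[0]),
            octave_span=float(np.log2(self.cf_hz[-1] / self.cf_hz[0])),
            n_channels=self.n_channels,
        )

    def channel_of(self, freq_hz: float) -> int:
        if freq_hz <= 0:
            raise ValueError("frequency must be positive")
        return int(np.argmin(np.abs(np.log2(self.cf_hz / freq_hz))))


def cf_grid(n: int = 15, fmin_hz: float = 500.0, fmax_hz: float = 16_000.0) -> ChannelBank:
    """Geometric progression of ``n`` center frequencies from fmin to fmax."""
    if n < 2:
        raise ValueError(f"need at least 2 channels, got {n}")
    if not (0 < fmin_hz < fmax_hz):
        raise ValueError(f"invalid frequency bounds ({fmin_hz}, {fmax_hz})")
    return ChannelBank(np.geomspace(fmin_hz, fmax_hz, n))


@dataclass(frozen=True)
class RateParams:
    """Affine envelope-to-rate map and audio-path filter settings.

    r_spont   spontaneous rate (events/s) at zero envelope
    r_gain    events/s per unit half-rectified envelope
    r_max     hard ceiling on the instantaneous rate
    """

    r_spont: float = 20.0
    r_gain: float = 150.0
    r_max: float = 400.0
    lowpass_hz: float = 250.0
    compression_exponent: float = 0.5


@dataclass(frozen=True)
class RateFunction:
    """Per-channel nonnegative instantaneous event rate on a uniform grid."""

    rates: np.ndarray  # (n_times, n_channels), events/s
    time_step_s: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 2:
            raise ValueError("rates must be 2-D (time x channel)")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite and nonnegative")
        object.__setattr__(self, "rates", r)

    @property
    def duration_s(self) -> float:
        return self.rates.shape[0] * self.time_step_s

    @property
    def n_channels(self) -> int:
        return self.rates.shape[1]


@dataclass(frozen=True)
class DischargeTrain:
    """Per-channel sorted event times in seconds."""

    times_s: tuple[np.ndarray, ...]
    duration_s: float

    def __post_init__(self) -> None:
        clean = []
        for ch, t in enumerate(self.times_s):
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(f"channel {ch}: event times must be strictly increasing")
            if t.size and (t[0] < 0 or t[-1] > self.duration_s):
                raise ValueError(f"channel {ch}: event times outside [0, duration]")
            clean.append(t)
        object.__setattr__(self, "times_s", tuple(clean))

    @property
    def n_channels(self) -> int:
        return len(self.times_s)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.times_s])


def drive_rate(
    stimulus: DynamicSpectrum | tuple[np.ndarray, float],
    bank: ChannelBank,
    params: RateParams | None = None,
    time_step_s: float | None = None,
) -> RateFunction:
    """Instantaneous event rate per channel for a stimulus.

    Dynamic-spectrum input: the envelope at the channel's octave coordinate is
    half-wave rectified and mapped affinely,
    ``rate = clip(r_spont + r_gain * max(0, S), 0, r_max)``.

    Audio input ``(samples, sample_rate)``: each channel is gammatone-filtered
    at its CF, half-wave rectified, low-pass filtered, power-compressed and
    peak-normalized across the bank, then mapped through the same affine rule.
    """
    params = params or RateParams()
    if isinstance(stimulus, DynamicSpectrum):
        dt = stimulus.time_step_s if time_step_s is None else time_step_s
        if time_step_s is not None and not np.isclose(time_step_s, stimulus.time_step_s):
            raise ValueError("time_step_s must match the dynamic spectrum grid")
        span = (stimulus.freqs_hz[0], stimulus.freqs_hz[-1])
        tol = 1e-6
        if bank.cf_hz[0] < span[0] * (1 - tol) or bank.cf_hz[-1] > span[1] * (1 + tol):
            raise ValueError(
                f"channel bank {bank.cf_hz[0]}-{bank.cf_hz[-1]} Hz outside "
                f"stimulus span {span[0]}-{span[1]} Hz"
            )
        stim_oct = np.log2(stimulus.freqs_hz / stimulus.freqs_hz[0])
        env = np.empty((stimulus.n_times, bank.n_channels))
        for c, f in enumerate(bank.cf_hz):
            idx = int(np.argmin(np.abs(stim_oct - np.log2(f / stimulus.freqs_hz[0]))))
            env[:, c] = stimulus.values[:, idx]
        rates = params.r_spont + params.r_gain * np.clip(env, 0.0, None)
        return RateFunction(np.clip(rates, 0.0, params.r_max), dt)

    samples, sr = stimulus
    samples = np.asarray(samples, dtype=float)
    dt = time_step_s or 2e-3
    block = max(1, int(round(dt * sr)))
    n_blocks = len(samples) // block
    if n_blocks == 0:
        raise ValueError("audio shorter than one envelope bin")
    if bank.cf_hz[-1] >= sr / 2:
        raise ValueError("highest CF at or above audio Nyquist frequency")
    b_lp, a_lp = sps.butter(2, params.lowpass_hz / (sr / 2))
    env = np.empty((n_blocks, bank.n_channels))
    for c, f in enumerate(bank.cf_hz):
        b, a = sps.gammatone(f, "iir", fs=sr)
        y = sps.lfilter(b, a, samples)
        y = np.clip(y, 0.0, None)                       # half-wave rectify
        y = sps.lfilter(b_lp, a_lp, y)
        y = np.clip(y, 0.0, None) ** params.compression_exponent
        env[:, c] = y[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    peak = env.max()
    if peak > 0:
        env = env / peak
    rates = params.r_spont + params.r_gain * env
    return RateFunction(np.clip(rates, 0.0, params.r_max), dt)


def generate_discharges(
    rate: RateFunction,
    seed: int | None,
    dead_time_s: float = 0.75e-3,
) -> DischargeTrain:
    """Sample per-channel inhomogeneous Poisson events by thinning.

    Candidate events are drawn at the channel's peak rate and accepted with
    probability ``rate(t) / rate_max`` (rate piecewise constant per envelope
    bin).  Accepted events closer than ``dead_time_s`` to the previous kept
    event are discarded (absolute refractoriness); set the dead time to 0 for
    an exact Poisson process.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    dt = rate.time_step_s
    duration = rate.duration_s
    n_bins = rate.rates.shape[0]
    trains = []
    for c in range(rate.n_channels):
        lam = rate.rates[:, c]
        lam_max = float(lam.max())
        if lam_max <= 0:
            trains.append(np.empty(0))
            continue
        # draw homogeneous candidates at lam_max out past the duration
        n_guess = int(lam_max * duration + 10.0 * np.sqrt(lam_max * duration) + 10)
        gaps = rng.exponential(1.0 / lam_max, size=n_guess)
        t = np.cumsum(gaps)
        while t.size and t[-1] < duration:
            extra = rng.exponential(1.0 / lam_max, size=n_guess)
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
        t = t[t < duration]
        u = rng.random(len(t))
        bins = np.minimum((t / dt).astype(int), n_bins - 1)
        accepted = t[u * lam_max < lam[bins]]
        if dead_time_s > 0 and accepted.size:
            kept = [accepted[0]]
            for ev in accepted[1:]:
                if ev - kept[-1] >= dead_time_s:
                    kept.append(ev)
            accepted = np.array(kept)
        trains.append(accepted)
    return DischargeTrain(tuple(trains), duration)
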