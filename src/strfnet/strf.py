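"""Reverse-correlation STRF estimation, significance masking, and the
significance-weighted cost.

The spectrotemporal receptive field (STRF) is estimated by cross-correlating
the stimulus dynamic spectrum with the spike response,

    C(tau, x) = (1/T) * sum_spikes S(t_spike - tau, x),

averaged over the stimulus ensemble and repetitions.  Because a TORC set's
autocorrelation is delta-like, dividing each channel by the ensemble envelope
power ("power" normalization) recovers the linear kernel without a full 2-D
deconvolution; a raw (1/T) mode is also available.

Model/target STRFs are compared by a cost that sums absolute differences
weighted by the target's significance mask: points further than 3 standard
deviations from the STRF's overall mean weigh 1, all others 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .torc import DynamicSpectrum

__all__ = [
    "STRF",
    "SignificanceMask",
    "EstimationConfig",
    "reverse_correlate",
    "significance_mask",
    "cost",
    "best_frequency",
    "best_channel",
]

NONSIGNIFICANT_WEIGHT = 0.1
SIGNIFICANCE_SD = 3.0


@dataclass(frozen=True)
class STRF:
    """Lag x channel kernel matrix; the lag axis starts at 0."""

    values: np.ndarray  # (n_lags, n_channels)
    lag_step_ms: float
    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("STRF values must be a finite 2-D matrix")
        if v.shape[1] != len(self.freqs_hz):
            raise ValueError("channel axis length mismatch")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, dtype=float))

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(self.n_lags) * self.lag_step_ms

    def congruent(self, other: "STRF") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.lag_step_ms, other.lag_step_ms)
            and np.allclose(self.freqs_hz, other.freqs_hz)
        )


@dataclass(frozen=True)
class SignificanceMask:
    """Boolean mask plus the 1 / 0.1 weights used in the cost."""

    mask: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.shape != self.weights.shape:
            raise ValueError("mask/weight shape mismatch")


@dataclass(frozen=True)
class EstimationConfig:
    """Reverse-correlation settings.

    The lag window is 0-250 ms at the 2 ms envelope step by default.
    ``normalization``: "power" divides each channel by the ensemble envelope
    power; "raw" divides by total stimulus time only.
    """

    lag_span_ms: float = 250.0
    lag_step_ms: float = 2.0
    normalization: str = "power"

    def __post_init__(self) -> None:
        if not (self.lag_span_ms >= self.lag_step_ms > 0):
            raise ValueError("require lag span >= lag step > 0")
        if self.normalization not in ("power", "raw"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_lags(self) -> int:
        return int(round(self.lag_span_ms / self.lag_step_ms)) + 1


def _bin_spikes(resp, n_bins: int, dt_s: float) -> np.ndarray:
    """Spike times (s) or list of repetition spike arrays -> counts per bin."""
    r = np.zeros(n_bins)
    if isinstance(resp, np.ndarray) and resp.ndim == 1 and resp.size == n_bins and (
        resp.dtype.kind == "f"
    ):
        # already a rate/count signal on the envelope grid
        return resp.astype(float)
    reps = resp if isinstance(resp, (list, tuple)) else [resp]
    for rep in reps:
        t = np.asarray(rep, dtype=float)
        idx = (t / dt_s).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(r, idx, 1.0)
    return r


def reverse_correlate(
    dspecs: list[DynamicSpectrum],
    responses: list,
    cfg: EstimationConfig | None = None,
) -> STRF:
    """Estimate an STRF from per-stimulus responses.

    ``responses[i]`` is, for stimulus ``dspecs[i]``, either a spike-time
    array (s), a list of such arrays (repetitions, summed), or a float array
    of length ``n_times`` taken as a rate signal on the envelope grid.
    """
    cfg = cfg or EstimationConfig()
    if len(dspecs) != len(responses):
        raise ValueError("need one response entry per stimulus")
    if not dspecs:
        raise ValueError("need at least one stimulus")
    first = dspecs[0]
    dt = first.time_step_s
    if not math.isclose(cfg.lag_step_ms, dt * 1000.0):
        raise ValueError(
            f"lag step {cfg.lag_step_ms} ms must equal the envelope step {dt * 1e3} ms"
        )
    n_lags = cfg.n_lags
    num = np.zeros((n_lags, first.n_channels))
    power = np.zeros(first.n_channels)
    total_t = 0.0
    for d, resp in zip(dspecs, responses):
        if not first.same_axes(d):
            raise ValueError("dynamic spectra do not share axes")
        n_t = d.n_times
        if n_lags > n_t:
            raise ValueError(
                f"lag span {cfg.lag_span_ms} ms exceeds stimulus duration "
                f"{d.duration_s * 1e3:.0f} ms"
            )
        r = _bin_spikes(resp, n_t, dt)
        n_reps = len(resp) if isinstance(resp, (list, tuple)) else 1
        s = d.values
        for k in range(n_lags):
            num[k] += s[: n_t - k].T @ r[k:]
        power += n_reps * np.sum(s * s, axis=0)
        total_t += n_reps * d.duration_s
    if cfg.normalization == "power":
        den = np.where(power > 0, power, 1.0)
        values = num / den[None, :]
    else:
        values = num / total_t
    return STRF(values, cfg.lag_step_ms, first.freqs_hz)


def significance_mask(strf: STRF) -> SignificanceMask:
    """Two-sided 3-standard-deviation mask over the whole STRF.

    A point is significant iff |value - mean| >= 3 * s.d. of all points
    (two-sided, so inhibitory regions can be significant).  A constant STRF
    (s.d. = 0) has an empty mask.  Weights are 1 on significant points and
    0.1 elsewhere.
    """
    v = strf.values
    sd = float(np.std(v))
    if sd == 0.0:
        mask = np.zeros_like(v, dtype=bool)
    else:
        mask = np.abs(v - np.mean(v)) >= SIGNIFICANCE_SD * sd
    weights = np.where(mask, 1.0, NONSIGNIFICANT_WEIGHT)
    return SignificanceMask(mask, weights)


def cost(model: STRF, target: STRF, *, normalize: bool = True) -> float:
    """Significance-weighted absolute difference between model and target.

    c = sum |M - E| * sig(E) with sig = 1 on the target's significant points
    and 0.1 elsewhere.  With ``normalize`` (default) both STRFs are first
    scaled to unit maximum absolute value so the comparison is of shape, not
    firing-rate scale; the mask is scale-invariant either way.
    """
    if not model.congruent(target):
        raise ValueError("model and target STRFs are not congruent")
    m = model.values
    e = target.values
    if normalize:
        if np.max(np.abs(m)) > 0:
            m = m / np.max(np.abs(m))
        if np.max(np.abs(e)) > 0:
            e = e / np.max(np.abs(e))
    w = significance_mask(target).weights
    return float(np.sum(np.abs(m - e) * w))


def best_channel(strf: STRF) -> int:
    """Channel index of the maximum positive STRF value (ties -> lower index)."""
    v = strf.values
    peak = v.max()
    if peak <= 0:
        raise ValueError("best frequency undefined: STRF has no positive values")
    per_channel_max = v.max(axis=0)
    return int(np.flatnonzero(per_channel_max >= peak)[0])


def best_frequency(strf: STRF) -> float:
    """Center frequency (Hz) of the channel holding the STRF's positive peak."""
    return float(strf.freqs_hz[best_channel(strf)])
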