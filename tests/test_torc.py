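"""TORC synthesis, dynamic spectra, waveform rendering and the Phi kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strfnet.torc import (
    ChannelAxis,
    DynamicSpectrum,
    RippleComponent,
    TORCSpec,
    dynamic_spectrum,
    make_torc_set,
    phi,
    render_waveform,
)

AXIS = ChannelAxis()


class TestMakeTorcSet:
    def test_set_composition(self):
        specs = make_torc_set(30, AXIS, seed=0)
        assert len(specs) == 30
        assert all(len(s.components) == 6 for s in specs)
        assert all(1.0 <= s.duration_s <= 2.0 for s in specs)

    def test_seed_determinism(self):
        a = make_torc_set(5, AXIS, seed=3)
        b = make_torc_set(5, AXIS, seed=3)
        for sa, sb in zip(a, b):
            assert sa == sb

    def test_density_bounds(self):
        specs = make_torc_set(30, AXIS, seed=1)
        densities = [c.density_cpo for s in specs for c in s.components]
        assert 0.0 <= min(densities) and max(densities) <= 1.4

    def test_velocities_are_harmonics(self):
        for s in make_torc_set(4, AXIS, seed=0):
            speeds = sorted(abs(c.velocity_hz) for c in s.components)
            base = speeds[0]
            assert speeds == pytest.approx([k * base for k in range(1, 7)])
            assert base in (4.0, 8.0)

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            make_torc_set(0, AXIS, seed=0)

    def test_distinct_velocities_enforced(self):
        comp = RippleComponent(1.0, 4.0, 0.5, 0.0)
        with pytest.raises(ValueError, match="distinct"):
            TORCSpec((comp, comp), 1.0, AXIS)


class TestDynamicSpectrum:
    def test_flat_density_makes_identical_channels(self):
        spec = TORCSpec((RippleComponent(1.0, 4.0, 0.0, 0.0),), 1.0, AXIS)
        d = dynamic_spectrum(spec, 0.002)
        t = (np.arange(d.n_times) + 0.5) * 0.002
        expected = np.cos(2 * np.pi * 4.0 * t)
        for c in range(d.n_channels):
            np.testing.assert_allclose(d.values[:, c], expected, atol=1e-12)

    def test_zero_amplitude_gives_zero_matrix(self):
        spec = TORCSpec((RippleComponent(0.0, 4.0, 0.5, 1.0),), 1.0, AXIS)
        assert np.all(dynamic_spectrum(spec).values == 0)

    def test_hand_evaluated_point(self):
        # a=1, w=4 Hz, eps=1 cyc/oct, phi=0 at t=0.25 s, x=0.5 oct:
        # cos(2*pi*(1.0 + 0.5)) = -1
        axis = ChannelAxis(f_min_hz=500.0, octave_span=5.0, n_channels=11)
        spec = TORCSpec((RippleComponent(1.0, 4.0, 1.0, 0.0),), 1.0, axis)
        d = dynamic_spectrum(spec, 0.1)  # bin centers 0.05, 0.15, 0.25, ...
        assert d.values[2, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_too_coarse_step_names_velocity(self):
        spec = TORCSpec((RippleComponent(1.0, 48.0, 0.5, 0.0),), 1.0, AXIS)
        with pytest.raises(ValueError, match="48"):
            dynamic_spectrum(spec, 0.02)

    @settings(max_examples=20, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 2.0),
                st.sampled_from([2.0, 4.0, 6.0, 8.0, 12.0]),
                st.floats(0.0, 1.4),
                st.floats(0.0, 6.28),
            ),
            min_size=1,
            max_size=4,
            unique_by=lambda t: t[1],
        )
    )
    def test_linearity_in_components(self, params):
        comps = [RippleComponent(*p) for p in params]
        combined = dynamic_spectrum(TORCSpec(tuple(comps), 0.5, AXIS))
        parts = sum(
            dynamic_spectrum(TORCSpec((c,), 0.5, AXIS)).values for c in comps
        )
        np.testing.assert_allclose(combined.values, parts, atol=1e-9)

    def test_zero_mean_over_whole_periods(self):
        # 1 s duration is an integer number of periods for 4 Hz harmonics
        spec = make_torc_set(1, AXIS, seed=0, durations_s=(1.0,))[0]
        d = dynamic_spectrum(spec)
        assert np.abs(d.values.mean(axis=0)).max() < 1e-10


class TestRenderWaveform:
    def test_duration_and_normalization(self):
        spec = make_torc_set(1, AXIS, seed=0, durations_s=(1.0,))[0]
        signal, sr = render_waveform(spec, seed=0)
        assert abs(len(signal) - spec.duration_s * sr) <= 1
        assert np.max(np.abs(signal)) <= 1.0 + 1e-12

    def test_zero_spectrum_renders_unmodulated_carriers(self):
        spec = TORCSpec((RippleComponent(0.0, 4.0, 0.5, 0.0),), 0.5, AXIS)
        signal, _ = render_waveform(spec, seed=1)
        assert np.max(np.abs(signal)) <= 1.0 + 1e-12
        assert np.std(signal) > 0  # carriers present

    def test_sample_rate_below_nyquist_rejected(self):
        spec = make_torc_set(1, AXIS, seed=0)[0]
        with pytest.raises(ValueError, match="Nyquist"):
            render_waveform(spec, audio_sample_rate_hz=16_000.0, seed=0)

    def test_ripple_velocity_visible_in_band_envelope(self):
        # a single 6 Hz ripple modulates each carrier's energy at 6 Hz
        spec = TORCSpec((RippleComponent(1.0, 6.0, 0.5, 0.0),), 2.0, AXIS)
        signal, sr = render_waveform(spec, seed=0)
        from scipy import signal as sps

        f0 = 2000.0
        sos = sps.butter(4, [f0 * 0.95, f0 * 1.05], btype="band", fs=sr, output="sos")
        band = sps.sosfiltfilt(sos, signal)
        env = np.abs(sps.hilbert(band))
        env = env - env.mean()
        spec_f = np.abs(np.fft.rfft(env * np.hanning(len(env))))
        freqs = np.fft.rfftfreq(len(env), 1 / sr)
        peak = freqs[(freqs > 1)][np.argmax(spec_f[freqs > 1])]
        assert peak == pytest.approx(6.0, abs=1.0)


def _phi_brute_force(dspecs, n_lag):
    """Independent triple-loop evaluation of the lagged channel products."""
    c = dspecs[0].n_channels
    out = np.zeros((2 * n_lag + 1, c, c))
    for d in dspecs:
        s = d.values
        n_t = s.shape[0]
        for k_i, lag in enumerate(range(-n_lag, n_lag + 1)):
            for i in range(c):
                for j in range(c):
                    acc = 0.0
                    for t in range(n_t):
                        if 0 <= t - lag < n_t:
                            acc += s[t, i] * s[t - lag, j]
                    out[k_i, i, j] += acc / n_t
    return out / len(dspecs)


class TestPhi:
    def test_zero_ensemble(self):
        d = DynamicSpectrum(
            np.zeros((100, 4)), 0.002, np.array([500.0, 1000, 2000, 4000]),
            np.array([0.0, 1, 2, 3]),
        )
        assert np.all(phi([d], max_lag_s=0.05).values == 0)

    def test_symmetry(self, torc30_dspecs):
        k = phi(torc30_dspecs[:4], max_lag_s=0.05)
        n_lag = (len(k.lags_s) - 1) // 2
        for off in range(-n_lag, n_lag + 1):
            np.testing.assert_allclose(
                k.values[n_lag + off], k.values[n_lag - off].T, atol=1e-12
            )

    def test_matches_brute_force_oracle(self):
        specs = make_torc_set(2, ChannelAxis(n_channels=3), seed=5, durations_s=(1.0,))
        dspecs = [dynamic_spectrum(s, 0.01) for s in specs]
        k = phi(dspecs, max_lag_s=0.05)
        expected = _phi_brute_force(dspecs, 5)
        np.testing.assert_allclose(k.values, expected, rtol=1e-8, atol=1e-12)

    def test_mismatched_axes_rejected(self, torc30_dspecs):
        other = DynamicSpectrum(
            np.zeros((10, 3)), 0.002, np.array([500.0, 1000, 2000]),
            np.array([0.0, 1, 2]),
        )
        with pytest.raises(ValueError):
            phi([torc30_dspecs[0], other])

    def test_energy_concentrates_at_zero_lag_and_difference(self, torc30_dspecs):
        k = phi(torc30_dspecs, max_lag_s=0.1)
        collapsed, diffs = k.collapsed()
        n_lag = (len(k.lags_s) - 1) // 2
        center = np.abs(collapsed[n_lag, diffs.tolist().index(0)])
        off_diag = np.abs(collapsed[:, diffs != 0]).max()
        assert center > off_diag
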