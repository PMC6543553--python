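"""Genome decoding, alpha synapses, and the integrate-and-fire network."""

import math

import numpy as np
import pytest

from strfnet.network import (
    Genome,
    NeuronParams,
    alpha_current,
    decode_genome,
    simulate_network,
    tonic_offset_mv,
)
from strfnet.periphery import DischargeTrain, cf_grid


def _single_input_genome(n, ch, strength, delay_code):
    g = Genome.zeros(n)
    istr = g.istr.copy()
    idel = g.idel.copy()
    istr[ch] = strength
    idel[ch] = delay_code
    return Genome(g.w.copy(), istr, idel)


def _train(n_channels, channel, times, duration):
    seqs = [np.array([]) for _ in range(n_channels)]
    seqs[channel] = np.asarray(times, dtype=float)
    return DischargeTrain(tuple(seqs), duration)


class TestGenome:
    def test_gene_count_is_255_for_15_neurons(self):
        g = Genome.zeros(15)
        assert g.n_genes == 255
        assert len(g.flat()) == 255

    def test_flat_roundtrip(self):
        rng = np.random.default_rng(0)
        flat = rng.integers(-5, 6, size=5 * 5 + 10)
        g = Genome.from_flat(flat, 5)
        np.testing.assert_array_equal(g.flat(), flat)

    def test_out_of_range_rejected(self):
        w = np.zeros((5, 5), int)
        w[1, 2] = 6
        with pytest.raises(ValueError, match=r"\[-5, 5\]"):
            Genome(w, np.zeros(5, int), np.zeros(5, int))


class TestDecodeGenome:
    def test_delay_code_endpoints_span_0_to_50_ms(self):
        bank = cf_grid(15)
        g = Genome.zeros(15)
        idel = g.idel.copy()
        idel[0] = -5
        idel[1] = 5
        idel[2] = 0
        cfg = decode_genome(Genome(g.w, g.istr, idel), NeuronParams(), bank)
        assert cfg.input_delay_ms[0] == pytest.approx(0.0)
        assert cfg.input_delay_ms[1] == pytest.approx(50.0)
        assert cfg.input_delay_ms[2] == pytest.approx(25.0)

    def test_zero_code_means_no_synapse(self):
        bank = cf_grid(15)
        cfg = decode_genome(Genome.zeros(15), NeuronParams(), bank)
        assert np.all(cfg.w_amp_us == 0)
        assert np.all(cfg.input_amp_us == 0)

    def test_sign_selects_polarity_and_magnitude_grades(self):
        bank = cf_grid(5)
        g = Genome.zeros(5)
        w = g.w.copy()
        w[0, 1] = 5
        w[1, 0] = -3
        cfg = decode_genome(Genome(w, g.istr, g.idel), NeuronParams(), bank)
        assert cfg.w_amp_us[0, 1] == pytest.approx(NeuronParams().g_m_us)
        assert cfg.w_amp_us[1, 0] == pytest.approx(-0.6 * NeuronParams().g_m_us)

    def test_cc_delay_grows_with_octave_distance(self):
        bank = cf_grid(15)
        cfg = decode_genome(Genome.zeros(15), NeuronParams(), bank)
        assert cfg.cc_delay_ms[0, 0] == pytest.approx(2.0)
        row = cfg.cc_delay_ms[0]
        assert np.all(np.diff(row) > 0)
        adjacent = np.diag(cfg.cc_delay_ms, k=1)
        np.testing.assert_allclose(adjacent, adjacent[0])
        assert cfg.cc_delay_ms[0, 14] == pytest.approx(2.0 + 3.0 * 5.0)

    def test_bank_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_genome(Genome.zeros(5), NeuronParams(), cf_grid(15))


class TestAlphaCurrent:
    def test_gated_to_zero_at_and_before_onset(self):
        assert alpha_current(0.0, 3.0, 2.0) == 0.0
        assert alpha_current(-1.0, 3.0, 2.0) == 0.0

    def test_peak_at_tau_s_with_value_amplitude_over_e(self):
        t = np.linspace(0, 20, 20001)
        vals = alpha_current(t, 3.0, 2.0)
        assert t[np.argmax(vals)] == pytest.approx(2.0, abs=1e-3)
        assert vals.max() == pytest.approx(3.0 * math.exp(-1), rel=1e-6)


class TestMembraneDynamics:
    def test_rest_is_a_fixed_point(self):
        bank = cf_grid(3)
        cfg = decode_genome(Genome.zeros(3), NeuronParams(), bank)
        rec = simulate_network(cfg, _train(3, 0, [], 0.1), 100.0, record_v=True)
        np.testing.assert_allclose(rec.v_mv, -70.0, atol=1e-12)

    def test_passive_relaxation_matches_closed_form(self):
        # v(t) = v_rest + (v0 - v_rest) * exp(-t / tau_m), checked at t=tau_m
        params = NeuronParams()
        bank = cf_grid(3)
        cfg = decode_genome(Genome.zeros(3), params, bank)
        rec = simulate_network(
            cfg, _train(3, 0, [], 0.1), 20.0, record_v=True, v_init_mv=-60.0
        )
        step = int(round(params.tau_m_ms / params.dt_ms)) - 1
        expected = -70.0 + 10.0 * math.exp(-1)
        assert rec.v_mv[step, 0] == pytest.approx(expected, rel=1e-3)

    def test_excitatory_event_depolarizes(self):
        params = NeuronParams()
        bank = cf_grid(3)
        genome = _single_input_genome(3, 1, 2, -5)  # weak input, 0 ms delay
        cfg = decode_genome(genome, params, bank)
        rec = simulate_network(cfg, _train(3, 1, [0.005], 0.1), 50.0, record_v=True)
        window = rec.v_mv[int(7 / 0.25) : int(15 / 0.25), 1]
        assert window.max() > -70.0

    def test_zero_genome_without_tonic_is_silent(self):
        bank = cf_grid(5)
        cfg = decode_genome(Genome.zeros(5), NeuronParams(), bank)
        train = _train(5, 2, np.linspace(0.01, 0.9, 50), 1.0)
        rec = simulate_network(cfg, train, 1000.0)
        assert rec.counts().sum() == 0


class TestSimulateNetwork:
    def test_spikes_follow_input_events_after_delay(self):
        # strong input chain: cortical spikes only after event + transmission
        bank = cf_grid(3)
        genome = _single_input_genome(3, 1, 5, -4)  # 5 ms delay
        cfg = decode_genome(genome, NeuronParams(), bank)
        events = [0.050, 0.051, 0.052, 0.300, 0.301, 0.302]
        rec = simulate_network(cfg, _train(3, 1, events, 0.5), 500.0)
        spikes = rec.spike_times_ms[1]
        assert len(spikes) > 0
        for s in spikes:
            assert any(ev * 1000 + 5.0 <= s <= ev * 1000 + 25.0 for ev in events)

    def test_tonic_drive_fires_in_silence_and_modulates_with_input(self):
        params = NeuronParams(tonic_rate_hz=10.0)
        bank = cf_grid(3)
        cfg = decode_genome(Genome.zeros(3), params, bank)
        silent = simulate_network(cfg, _train(3, 0, [], 2.0), 2000.0)
        rate = silent.counts()[0] / 2.0
        assert rate == pytest.approx(10.0, abs=2.0)
        driven_genome = _single_input_genome(3, 0, 5, -4)
        driven_cfg = decode_genome(driven_genome, params, bank)
        driven = simulate_network(
            driven_cfg, _train(3, 0, np.linspace(0.01, 1.99, 150), 2.0), 2000.0
        )
        assert driven.counts()[0] > silent.counts()[0]

    def test_determinism(self, small_ctx, small_gt):
        from strfnet.optimize import evaluate_strf

        gt, _ = small_gt
        a = evaluate_strf(gt, small_ctx, 2)
        b = evaluate_strf(gt, small_ctx, 2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_refractory_period_respected(self):
        params = NeuronParams(tonic_rate_hz=0.0)
        bank = cf_grid(3)
        genome = _single_input_genome(3, 0, 5, -5)
        cfg = decode_genome(genome, params, bank)
        dense = np.arange(0.001, 0.999, 0.002)
        rec = simulate_network(cfg, _train(3, 0, dense, 1.0), 1000.0)
        isi = np.diff(rec.spike_times_ms[0])
        assert len(isi) > 10
        assert isi.min() >= params.refractory_ms

    def test_sign_flip_cannot_increase_spike_count(self):
        bank = cf_grid(3)
        events = np.sort(np.random.default_rng(5).uniform(0, 1, 120))
        params = NeuronParams(tonic_rate_hz=10.0)
        counts = {}
        for code in (4, -4):
            genome = _single_input_genome(3, 1, code, -4)
            cfg = decode_genome(genome, params, bank)
            rec = simulate_network(cfg, _train(3, 1, events, 1.0), 1000.0)
            counts[code] = rec.counts()[1]
        assert counts[-4] <= counts[4]

    def test_short_duration_warns(self):
        bank = cf_grid(3)
        genome = _single_input_genome(3, 0, 5, 5)  # 50 ms delay
        cfg = decode_genome(genome, NeuronParams(), bank)
        with pytest.warns(UserWarning, match="delay"):
            simulate_network(cfg, _train(3, 0, [0.001], 0.04), 40.0)

    def test_dt_convergence(self):
        # halving the step changes spike counts of a reference run by < 5%
        bank = cf_grid(5)
        rng = np.random.default_rng(17)
        seqs = tuple(np.sort(rng.uniform(0, 2, 150)) for _ in range(5))
        train = DischargeTrain(seqs, 2.0)
        g = Genome.zeros(5)
        istr = g.istr.copy()
        idel = g.idel.copy()
        w = g.w.copy()
        istr[:] = [3, 4, 5, -3, 2]
        idel[:] = -4
        w[1, 2] = 2
        w[3, 2] = -2
        genome = Genome(w, istr, idel)
        counts = {}
        for dt in (0.25, 0.125):
            params = NeuronParams(dt_ms=dt, tonic_rate_hz=10.0)
            cfg = decode_genome(genome, params, bank)
            counts[dt] = simulate_network(cfg, train, 2000.0).counts().sum()
        assert abs(counts[0.25] - counts[0.125]) / counts[0.125] < 0.05


def test_tonic_offset_closed_form_matches_target_rate():
    params = NeuronParams(tonic_rate_hz=20.0)
    off = tonic_offset_mv(params)
    # steady state sits above threshold by construction
    v_ss = params.v_rest_mv + off
    period = params.tau_m_ms * math.log(
        (v_ss - params.v_k_mv) / (v_ss - params.v_thresh_mv)
    ) + params.refractory_ms
    assert 1000.0 / period == pytest.approx(20.0, rel=1e-9)
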