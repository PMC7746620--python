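from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_rms, butterworth1_bandpass_gain

from duetgamma.datamodel_io import CallEvent, LFPTrace, ValidationError
from duetgamma.lfp_ars import (
    ARSRecord,
    FragmentError,
    ars_to_frame,
    bandpass,
    compute_ars,
    design_filter_bank,
    extract_fragments,
    log_squared,
    normalize_within_bird,
    rms,
    select_band_of_interest,
)
from duetgamma.synthetic_data import LFPSimParams, simulate_lfp


def _trace(samples, fs=1000.0, bird="b1"):
    return LFPTrace(bird, np.asarray(samples, dtype=float), fs)


def _call(onset, duration, call_type="tet", emitter="m"):
    return CallEvent(emitter, call_type, onset, duration, 0, "NB")


class TestDesignFilterBank:
    def test_default_bank(self):
        bank = design_filter_bank(1000.0)
        assert len(bank.bands) == 19
        assert (bank.bands[0].low_hz, bank.bands[0].high_hz) == (10.0, 20.0)
        assert (bank.bands[-1].low_hz, bank.bands[-1].high_hz) == (190.0, 200.0)
        assert bank.labels() == list(range(10, 200, 10))

    def test_nyquist_violation(self):
        with pytest.raises(ValidationError, match="[Nn]yquist"):
            design_filter_bank(300.0)

    def test_all_filters_stable(self):
        # impulse response energy over 10 s stays finite and decays
        bank = design_filter_bank(1000.0)
        impulse = np.zeros(10000)
        impulse[0] = 1.0
        trace = _trace(impulse)
        for band in bank.bands:
            out = bandpass(trace, band, bank, zero_phase=False)
            energy = np.sum(out**2)
            assert np.isfinite(energy)
            assert np.abs(out[-100:]).max() < 1e-6  # decayed by 10 s


class TestBandpass:
    def test_dc_killed(self):
        bank = design_filter_bank(1000.0)
        trace = _trace(np.ones(2000))
        out = bandpass(trace, bank.bands[0], bank)
        assert np.abs(out[500:1500]).max() < 1e-3

    def test_output_length(self):
        bank = design_filter_bank(1000.0)
        trace = _trace(np.random.default_rng(0).normal(size=777))
        assert len(bandpass(trace, bank.bands[3], bank)) == 777

    def test_40hz_band_energy_ordering(self):
        # matches the analytic order-1 Butterworth magnitude ordering
        bank = design_filter_bank(1000.0)
        t = np.arange(4000) / 1000.0
        trace = _trace(np.sin(2 * np.pi * 40 * t))
        by_label = {b.label_hz: b for b in bank.bands}
        measured = {
            label: np.sqrt(np.mean(bandpass(trace, by_label[label], bank)[1000:3000] ** 2))
            for label in (30, 40, 120)
        }
        predicted = {
            label: butterworth1_bandpass_gain(40.0, by_label[label].low_hz,
                                              by_label[label].high_hz)
            for label in (30, 40, 120)
        }
        assert measured[30] > measured[120]
        assert measured[40] > measured[120]
        # zero-phase doubles the attenuation: compare |H|^2 ratios
        assert measured[30] / measured[120] == pytest.approx(
            (predicted[30] / predicted[120]) ** 2, rel=0.15
        )

    def test_linearity(self):
        bank = design_filter_bank(1000.0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=3000)
        out1 = bandpass(_trace(x), bank.bands[2], bank)
        out3 = bandpass(_trace(3.0 * x), bank.bands[2], bank)
        np.testing.assert_allclose(out3, 3.0 * out1, rtol=1e-9, atol=1e-12)

    def test_fs_mismatch_rejected(self):
        bank = design_filter_bank(2000.0)
        with pytest.raises(ValidationError):
            bandpass(_trace(np.zeros(100), fs=1000.0), bank.bands[0], bank)


class TestExtractFragments:
    def test_index_arithmetic(self):
        trace = _trace(np.arange(20000, dtype=float))
        base, stim = extract_fragments(trace, _call(10.0, 0.2))
        np.testing.assert_array_equal(stim, np.arange(10000, 10200))
        np.testing.assert_array_equal(base, np.arange(9800, 10000))

    def test_insufficient_baseline_raises(self):
        trace = _trace(np.zeros(1000))
        with pytest.raises(FragmentError):
            extract_fragments(trace, _call(0.05, 0.2))

    def test_stimulus_past_end_raises(self):
        trace = _trace(np.zeros(1000))
        with pytest.raises(FragmentError):
            extract_fragments(trace, _call(0.95, 0.2))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_equal_lengths(self, seed):
        rng = np.random.default_rng(seed)
        trace = _trace(np.zeros(30000))
        call = _call(float(rng.uniform(1.0, 25.0)), float(rng.uniform(0.01, 1.0)))
        base, stim = extract_fragments(trace, call)
        assert len(base) == len(stim) >= 1


class TestRMS:
    def test_zeros(self):
        assert rms(np.zeros(100)) == 0.0

    def test_unit_sine_closed_form(self):
        t = np.arange(1000) / 1000.0  # exactly 40 periods of 40 Hz
        assert rms(np.sin(2 * np.pi * 40 * t)) == pytest.approx(1 / np.sqrt(2), abs=1e-6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rms(np.array([]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(1, 300)))
        assert rms(x) == pytest.approx(brute_rms(x), rel=1e-12)


class TestComputeARS:
    def test_noise_free_burst_band_specific(self):
        calls = [_call(t, 0.4) for t in (5.0, 15.0, 25.0)]
        params = LFPSimParams(noise_sigma=0.0, burst_fc_hz=40.0, burst_amplitude=1.0, seed=0)
        trace = simulate_lfp(calls, 30.0, params)
        bank = design_filter_bank(1000.0)
        frame = ars_to_frame(compute_ars(trace, calls, bank))
        mean_ars = frame.groupby("band_hz")["ars"].mean()
        assert mean_ars[30] > 0.1 and mean_ars[40] > 0.1
        assert abs(mean_ars[120]) < 0.01

    def test_periodic_trace_zero_ars(self):
        # identical stimulus and baseline segments -> ars ~ 0
        t = np.arange(30000) / 1000.0
        trace = _trace(np.sin(2 * np.pi * 40 * t))
        call = _call(10.0, 0.5)  # 0.5 s = 20 whole periods
        bank = design_filter_bank(1000.0)
        frame = ars_to_frame(compute_ars(trace, [call], bank))
        assert frame["ars"].abs().max() < 1e-6

    def test_monotone_in_gain(self):
        call = _call(5.0, 0.4)
        bank = design_filter_bank(1000.0)
        values = []
        for g in (0.5, 1.0, 2.0, 4.0):
            params = LFPSimParams(noise_sigma=0.3, burst_fc_hz=45.0, burst_amplitude=g, seed=7)
            trace = simulate_lfp([call], 10.0, params)
            frame = ars_to_frame(compute_ars(trace, [call], bank))
            values.append(frame.set_index("band_hz")["ars"][40])
        assert values == sorted(values)

    def test_edge_calls_skipped(self):
        trace = _trace(np.zeros(10000))
        calls = [_call(0.05, 0.2), _call(5.0, 0.2)]
        bank = design_filter_bank(1000.0)
        records = compute_ars(trace, calls, bank)
        assert len(records) == 19  # only the interior call, all bands

    def test_pipeline_linearity(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(size=20000)
        calls = [_call(5.0, 0.3), _call(12.0, 0.25)]
        bank = design_filter_bank(1000.0)
        f1 = ars_to_frame(compute_ars(_trace(samples), calls, bank))
        f2 = ars_to_frame(compute_ars(_trace(2.5 * samples), calls, bank))
        np.testing.assert_allclose(f2["ars"], 2.5 * f1["ars"], rtol=1e-9)

    def test_strict_baseline_excludes_contaminated(self):
        trace = _trace(np.zeros(20000))
        calls = [_call(5.0, 0.3), _call(5.15, 0.3)]  # second baseline overlaps first call
        bank = design_filter_bank(1000.0)
        lax = compute_ars(trace, calls, bank)
        strict = compute_ars(trace, calls, bank, strict_baseline=True)
        assert len(lax) == 2 * 19
        assert len(strict) < len(lax)


class TestNormalizeWithinBird:
    def test_scaling_rule(self):
        records = [
            ARSRecord("b", "m", "tet", 1.0, 0.1, 0, "NB", "other", 40, 0.0, a)
            for a in (-2.0, 1.0, 4.0)
        ]
        normalize_within_bird(records)
        assert [r.ars_normalized for r in records] == pytest.approx([-0.5, 0.25, 1.0])

    def test_all_zero_passes_through(self):
        records = [
            ARSRecord("b", "m", "tet", 1.0, 0.1, 0, "NB", "other", 40, 0.5, 0.5)
            for _ in range(3)
        ]
        normalize_within_bird(records)
        assert all(r.ars_normalized == 0.0 for r in records)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_max_abs_is_one(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            ARSRecord("b", "m", "tet", 1.0, 0.1, 0, "NB", "other", 40, 0.0,
                      float(rng.normal()))
            for _ in range(int(rng.integers(1, 20)))
        ]
        if all(r.ars == 0 for r in records):
            return
        normalize_within_bird(records)
        assert max(abs(r.ars_normalized) for r in records) == pytest.approx(1.0)
        assert all(-1 <= r.ars_normalized <= 1 for r in records)

    def test_per_bird_independence(self):
        records = [
            ARSRecord("b1", "m", "tet", 1.0, 0.1, 0, "NB", "other", 40, 0.0, 2.0),
            ARSRecord("b2", "m", "tet", 1.0, 0.1, 0, "NB", "other", 40, 0.0, 8.0),
        ]
        normalize_within_bird(records)
        assert records[0].ars_normalized == 1.0
        assert records[1].ars_normalized == 1.0


class TestLogSquared:
    def test_monotone_above_floor(self):
        x = np.array([0.001, 0.01, 0.1, 1.0])
        values, n_excluded = log_squared(x)
        assert n_excluded == 0
        assert np.all(np.diff(values) > 0)

    def test_epsilon_floor_excludes(self):
        values, n_excluded = log_squared(np.array([0.0, 1e-15, 0.5]))
        assert n_excluded == 2
        assert len(values) == 1
        assert np.isfinite(values).all()


def _burst_records(seed, fc=45.0, bw=30.0, sigma=0.3, n_calls=20, amplitude=None):
    rng = np.random.default_rng(seed)
    calls = [_call(2.0 + 2.0 * i, 0.4) for i in range(n_calls)]
    if amplitude is None:
        # per-band burst power = 2x the white-noise band power; the burst
        # spans 3 bands, so total burst RMS = sqrt(3 * 2) * band noise RMS
        band_noise_rms = sigma * np.sqrt(10.0 / 500.0)
        amplitude = np.sqrt(2.0) * np.sqrt(6.0) * band_noise_rms
    params = LFPSimParams(noise_sigma=sigma, burst_fc_hz=fc, burst_bw_hz=bw,
                          burst_amplitude=amplitude, seed=seed)
    trace = simulate_lfp(calls, 2.0 * n_calls + 4.0, params, rng=rng)
    bank = design_filter_bank(1000.0)
    return compute_ars(trace, calls, bank)


class TestSelectBandOfInterest:
    def test_recovers_low_gamma(self):
        records = _burst_records(seed=0)
        selection = select_band_of_interest(records)
        assert set(selection.selected) <= {30, 40, 50}

    def test_k1_single_band_burst(self):
        records = _burst_records(seed=1, fc=45.0, bw=8.0, sigma=0.05)
        selection = select_band_of_interest(records, k=1)
        assert selection.selected == (40,)

    def test_white_noise_flagged_not_dominant(self):
        rng = np.random.default_rng(2)
        calls = [_call(2.0 + 2.0 * i, 0.4) for i in range(20)]
        params = LFPSimParams(noise_sigma=0.5, burst_amplitude=0.0, seed=2)
        trace = simulate_lfp(calls, 44.0, params, rng=rng)
        bank = design_filter_bank(1000.0)
        selection = select_band_of_interest(compute_ars(trace, calls, bank))
        assert not selection.dominant

    def test_too_few_bands_rejected(self):
        records = _burst_records(seed=3)
        only_two_bands = [r for r in records if r.band_hz in (30, 40)]
        with pytest.raises(ValidationError):
            select_band_of_interest(only_two_bands, k=3)
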