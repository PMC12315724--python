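"""PPG processing: resampling, beat detection, IBI filtering, HR, HF-HRV."""

import numpy as np
import pytest

import stressglm as sg
import stressglm.physio as ph
from stressglm.physio import (IBI_BOUNDS_MS, BeatSeries, IBISeries,
                              PhysioRecording, block_average_windows,
                              detect_beats, filter_ibis, hf_hrv,
                              hr_block_means, hr_hf_correlation,
                              hr_volume_means, read_physio, resample,
                              write_physio)


def _ibis_from_intervals(intervals_ms, use_filter=True):
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    t = np.concatenate([[0.0], np.cumsum(intervals_ms / 1000.0)])
    if use_filter:
        return filter_ibis(BeatSeries(t))
    lo, hi = IBI_BOUNDS_MS
    accepted = (intervals_ms >= lo) & (intervals_ms <= hi)
    return IBISeries(t, intervals_ms, accepted)


class TestResample:
    def test_downsample_length(self):
        rec = PhysioRecording(np.random.default_rng(0).normal(size=50_000),
                              fs=5000.0)
        out = resample(rec, 100.0)
        assert out.fs == 100.0
        assert abs(out.samples.size - 1000) <= 1

    def test_identity(self):
        rec = PhysioRecording(np.arange(100.0), fs=100.0)
        assert resample(rec, 100.0) is rec

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(0, 10, 1 / 5000)
        rec = PhysioRecording(np.sin(2 * np.pi * 1.0 * t), fs=5000.0)
        out = resample(rec, 100.0)
        mid = out.samples[100:-100]   # away from filter edges
        assert abs(mid.max() - 1.0) < 0.01
        t2 = np.arange(mid.size) / 100.0 + 1.0
        np.testing.assert_allclose(mid, np.sin(2 * np.pi * t2), atol=0.02)


class TestDetectBeats:
    def test_clean_pulse_train_recovered(self):
        true_beats = np.arange(1.0, 59.0, 1.0)   # 60 bpm
        rec = sg.render_ppg(true_beats, snr_db=20, seed_or_rng=0, duration=60.0)
        beats, quality = detect_beats(rec)
        assert quality.rating == 1
        assert len(beats) == len(true_beats)
        # each detected peak within one sample of a true beat
        err = np.abs(beats.beat_times[:, None] - true_beats[None, :]).min(axis=1)
        assert np.all(err <= 1.5 / rec.fs + 1e-9)

    def test_flat_signal_rated_unusable(self):
        rec = PhysioRecording(np.zeros(6000), fs=100.0)
        beats, quality = detect_beats(rec)
        assert len(beats) == 0 and quality.rating == 3

    def test_dropout_lowers_rating(self):
        true_beats = np.arange(1.0, 119.0, 1.0)
        rec = sg.render_ppg(true_beats, snr_db=40, seed_or_rng=1,
                            duration=120.0, dropout=(50.0, 10.0))
        _, quality = detect_beats(rec)
        assert quality.longest_gap_s > 8.0
        assert quality.rating >= 2


class TestFilterIBIs:
    def test_constant_intervals_all_accepted(self):
        ibis = _ibis_from_intervals([1000.0] * 50)
        assert ibis.accepted.all()

    def test_short_ectopic_interval_rejected(self):
        ibis = _ibis_from_intervals([1000.0] * 10 + [500.0] + [1000.0] * 10)
        assert not ibis.accepted[10]
        assert ibis.accepted.sum() == 20

    def test_slow_drift_fully_accepted(self):
        intervals = np.linspace(1000.0, 1100.0, 50)
        ibis = _ibis_from_intervals(intervals)
        assert ibis.accepted.all()

    def test_never_accepts_outside_physiological_bounds(self, rng):
        intervals = rng.uniform(100.0, 3000.0, size=200)
        ibis = _ibis_from_intervals(intervals)
        lo, hi = IBI_BOUNDS_MS
        bad = (ibis.interval_ms < lo) | (ibis.interval_ms > hi)
        assert not np.any(ibis.accepted & bad)

    def test_rejected_flagged_not_deleted(self):
        ibis = _ibis_from_intervals([1000.0] * 5 + [500.0] + [1000.0] * 5)
        assert ibis.interval_ms.size == 11

    def test_too_few_beats(self):
        out = filter_ibis(BeatSeries(np.array([1.0])))
        assert out.interval_ms.size == 0


class TestHRTraces:
    def test_constant_intervals_give_sixty_bpm(self, short_design):
        n = int(short_design.duration) + 2
        ibis = _ibis_from_intervals([1000.0] * n)
        bt = hr_block_means(ibis, short_design)
        np.testing.assert_allclose(bt.values, 60.0)
        vt = hr_volume_means(ibis, short_design)
        np.testing.assert_allclose(vt.values, 60.0)

    def test_alternating_regimes(self):
        d = sg.default_design(phases=1, blocks_per_phase=2, active_s=60.0,
                              rest_s=40.0, n_dummy=0)
        intervals = []
        t = 0.0
        while t < d.duration + 2:
            block = int(t // 100.0)
            ms = 1000.0 if block % 2 == 0 else 750.0
            intervals.append(ms)
            t += ms / 1000.0
        ibis = _ibis_from_intervals(intervals, use_filter=False)
        bt = hr_block_means(ibis, d)
        assert abs(bt.values[0] - 60.0) < 1.0
        assert abs(bt.values[1] - 80.0) < 1.0

    def test_block_means_ignore_rejected_intervals(self, short_design):
        n = int(short_design.duration) + 2
        clean = _ibis_from_intervals([1000.0] * n)
        # inject rejected junk: same beats, but flip some accepts manually
        noisy = IBISeries(clean.beat_times, clean.interval_ms,
                          clean.accepted.copy())
        noisy.interval_ms = noisy.interval_ms.copy()
        noisy.interval_ms[10:15] = 400.0
        noisy.accepted[10:15] = False
        bt_clean = hr_block_means(clean, short_design)
        bt_noisy = hr_block_means(noisy, short_design)
        np.testing.assert_allclose(bt_noisy.values, bt_clean.values)

    def test_step_change_interpolates_linearly(self):
        d = sg.default_design(phases=1, blocks_per_phase=1, active_s=60.0,
                              rest_s=40.0, n_dummy=0)
        intervals = [1000.0] * 50 + [600.0] * 80
        ibis = _ibis_from_intervals(intervals, use_filter=False)
        vt = hr_volume_means(ibis, d)
        assert abs(vt.values[5] - 60.0) < 1.0
        assert abs(vt.values[-5] - 100.0) < 1.0
        # the interpolated ramp crosses exactly between the scan midtimes
        # bracketing the step at t = 50 s (midpoints 49.5 s and 50.3 s)
        assert vt.values[24] == pytest.approx(60.0, abs=1.0)
        assert vt.values[25] == pytest.approx(100.0, abs=1.0)
        ramp = np.interp(49.9, ibis.midpoints, ibis.instantaneous_hr)
        assert 60.0 < ramp < 100.0

    def test_volume_means_consistent_with_block_means(self, design, truth):
        import dataclasses
        smooth_truth = dataclasses.replace(truth, rsa_amp0=0.0)
        proc = sg.simulate_hr_process(design, smooth_truth, 77)
        ibis = filter_ibis(BeatSeries(proc.beat_times))
        bt = hr_block_means(ibis, design)
        vt = hr_volume_means(ibis, design)
        t = design.scan_midtimes()
        for j, b in enumerate(design.active_blocks):
            sel = (t >= b.onset) & (t < b.offset)
            assert abs(vt.values[sel].mean() - bt.values[j]) < 1.0


class TestHFHRV:
    def _sine_ibis(self, f_mod, duration=900.0, hr0=70.0, amp=5.0):
        dt = 0.1
        t = np.arange(0, duration, dt)
        hr = hr0 + amp * np.sin(2 * np.pi * f_mod * t)
        cum = np.concatenate([[0.0], np.cumsum((hr[:-1] + hr[1:]) / 2) * dt / 60])
        beats = np.interp(np.arange(1, int(cum[-1])), cum, t)
        return filter_ibis(BeatSeries(beats))

    def test_hf_modulation_concentrates_in_band(self):
        ibis = self._sine_ibis(0.30)
        hf = hf_hrv(ibis, band=(0.15, 0.40))
        total = hf_hrv(ibis, band=(0.04, 0.40))
        assert np.all(hf.values >= 0.95 * total.values)

    def test_constant_hr_has_negligible_power(self):
        ibis_const = _ibis_from_intervals([60000.0 / 70] * 1100)
        ibis_sine = self._sine_ibis(0.30)
        p_const = hf_hrv(ibis_const).values.mean()
        p_sine = hf_hrv(ibis_sine).values.mean()
        assert p_const < 1e-6 * p_sine

    def test_low_frequency_modulation_outside_band(self):
        ibis = self._sine_ibis(0.10)
        hf = hf_hrv(ibis, band=(0.15, 0.40))
        total = hf_hrv(ibis, band=(0.04, 0.40))
        assert np.all(hf.values < 0.05 * total.values)

    def test_band_powers_sum_to_total(self):
        """Parseval: disjoint band powers add to the full-band power."""
        ibis = self._sine_ibis(0.22, duration=600.0)
        bands = [(0.0, 0.15), (0.15, 0.40), (0.40, 2.0)]
        parts = [hf_hrv(ibis, band=b).values for b in bands]
        # recompute total over the full periodogram range
        full = hf_hrv(ibis, band=(0.0, 2.0)).values
        np.testing.assert_allclose(sum(parts), full, rtol=1e-6)

    def test_short_recording_names_minimum(self):
        ibis = _ibis_from_intervals([1000.0] * 100)
        with pytest.raises(ValueError, match="300"):
            hf_hrv(ibis)

    def test_block_averaging_covers_every_block(self, simulated_subject, design):
        hf = hf_hrv(simulated_subject["ibis"])
        bt = block_average_windows(hf, design)
        assert np.all(np.isfinite(bt.values))
        assert bt.values.size == 15


class TestHRHFCorrelation:
    def test_perfect_anticorrelation(self):
        hr = ph.BlockTrace(np.array([60.0, 70, 80, 90]))
        hf = ph.BlockTrace(-hr.values)
        assert hr_hf_correlation([hr], [hf]) == pytest.approx(-1.0)

    def test_independent_traces_near_zero(self, rng):
        hrs = [ph.BlockTrace(rng.normal(70, 5, 15)) for _ in range(500)]
        hfs = [ph.BlockTrace(rng.normal(3, 1, 15)) for _ in range(500)]
        assert abs(hr_hf_correlation(hrs, hfs)) < 0.05

    def test_zero_variance_returns_nan(self):
        hr = ph.BlockTrace(np.full(5, 70.0))
        hf = ph.BlockTrace(np.arange(5.0))
        with pytest.warns(UserWarning):
            assert np.isnan(hr_hf_correlation([hr], [hf]))


def test_physio_io_round_trip(tmp_path):
    rec = PhysioRecording(np.random.default_rng(3).normal(size=500), fs=100.0,
                          start_offset=0.0)
    write_physio(rec, tmp_path / "sub-01_physio")
    back = read_physio(tmp_path / "sub-01_physio")
    assert back.fs == 100.0
    np.testing.assert_allclose(back.samples, np.round(rec.samples, 6))


def test_physio_write_deterministic(tmp_path):
    rec = PhysioRecording(np.arange(100.0), fs=100.0)
    write_physio(rec, tmp_path / "a")
    write_physio(rec, tmp_path / "b")
    assert (tmp_path / "a.tsv.gz").read_bytes() == (tmp_path / "b.tsv.gz").read_bytes()
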