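"""Beat detection, outlier rejection, SNR screening and averaging."""

import numpy as np
import pytest

from wovecg.errors import EmptyResultError
from wovecg.waveform_processing import (ECGRecord, compute_snr, detect_r_peaks,
                                        drop_contaminated_followers,
                                        mean_waveform, read_ecg_csv,
                                        reject_outlier_beats, screen_dataset,
                                        write_ecg_csv)

FS = 500.0


def gaussian_beat(t, amp=1e-3, width=0.012):
    return amp * np.exp(-0.5 * (t / width) ** 2)


def beat_train(n_beats=100, rr=1.0, fs=FS, amp=1e-3, noise=0.0, seed=0,
               amp_per_beat=None):
    """Identical Gaussian 'R waves' at fixed RR; ground-truth peaks known."""
    n = round((n_beats + 1) * rr * fs)
    x = np.zeros(n)
    peaks = []
    for k in range(n_beats):
        tc = (k + 0.5) * rr
        lo = int((tc - 0.1) * fs)
        hi = int((tc + 0.1) * fs)
        tt = np.arange(lo, hi) - round(tc * fs)
        a = amp if amp_per_beat is None else amp_per_beat[k]
        x[lo:hi] = gaussian_beat(tt / fs, amp=a)  # windows bitwise identical
        peaks.append(round(tc * fs))
    if noise > 0:
        x = x + noise * np.random.default_rng(seed).standard_normal(n)
    return ECGRecord(samples=x, fs=fs), np.asarray(peaks)


class TestDetection:
    def test_known_train_detected_exactly(self):
        rec, truth = beat_train(100)
        got = detect_r_peaks(rec)
        assert got.size == truth.size
        assert np.all(np.abs(got - truth) <= 1)

    def test_flat_record_gives_no_peaks(self):
        rec = ECGRecord(samples=np.zeros(5000), fs=FS)
        assert detect_r_peaks(rec).size == 0

    def test_refractory_keeps_larger_of_close_pair(self):
        fs = FS
        x = np.zeros(round(2.0 * fs))
        for tc, amp in ((0.9, 0.5e-3), (1.0, 1e-3)):  # 0.1 s apart
            tt = np.arange(x.size) / fs - tc
            x += gaussian_beat(tt, amp=amp)
        rec = ECGRecord(samples=x, fs=fs)
        peaks = detect_r_peaks(rec, min_prominence=1e-4, refractory=0.25)
        assert peaks.size == 1
        assert abs(peaks[0] - round(1.0 * fs)) <= 1


class TestOutlierRejection:
    def test_identical_beats_all_retained(self):
        rec, peaks = beat_train(50)
        assert np.array_equal(reject_outlier_beats(peaks, rec), peaks)

    def test_amplitude_outlier_removed(self):
        amps = [1e-3] * 50
        amps[25] = 10e-3
        rec, peaks = beat_train(50, amp_per_beat=amps)
        kept = reject_outlier_beats(peaks, rec)
        assert kept.size == 49
        assert peaks[25] not in kept

    def test_rr_outlier_removed(self):
        # one beat arrives 2 s late: its preceding RR deviates by > 3 MAD
        rec, peaks = beat_train(50)
        shifted = peaks.copy()
        rec2 = ECGRecord(samples=np.zeros(rec.samples.size + round(2 * FS)),
                         fs=FS)
        x = rec2.samples
        for i, p in enumerate(peaks):
            q = p + (round(2.0 * FS) if i >= 25 else 0)
            tt = np.arange(max(0, q - 50), min(x.size, q + 50)) / FS - q / FS
            x[max(0, q - 50):min(x.size, q + 50)] += gaussian_beat(tt)
            shifted[i] = q
        kept = reject_outlier_beats(shifted, rec2)
        assert shifted[25] not in kept          # the late beat
        assert kept.size >= 48

    def test_few_peaks_pass_through_with_warning(self):
        rec, peaks = beat_train(2)
        with pytest.warns(UserWarning):
            kept = reject_outlier_beats(peaks[:2], rec)
        assert np.array_equal(kept, peaks[:2])

    def test_followers_of_rejected_beats_dropped(self):
        detected = np.array([100, 200, 300, 400, 500])
        retained = np.array([100, 200, 400, 500])  # beat at 300 rejected
        clean = drop_contaminated_followers(retained, detected)
        assert 400 not in clean
        assert set(clean) == {100, 200, 500}


class TestSNR:
    def test_noiseless_train_hits_cap(self):
        rec, peaks = beat_train(60)
        assert compute_snr(rec, peaks) == 300.0

    def test_equal_power_noise_reads_near_zero_db(self):
        rec, peaks = beat_train(120, noise=0.0)
        # noise power set to the clean signal power over the beat windows
        pre_n, post_n = round(0.25 * FS), round(0.45 * FS)
        covered = np.zeros(rec.samples.size, dtype=bool)
        for p in peaks:
            covered[p - pre_n:p + post_n + 1] = True
        sigma = np.sqrt(np.mean(rec.samples[covered] ** 2))
        noisy = ECGRecord(
            samples=rec.samples + sigma * np.random.default_rng(1)
            .standard_normal(rec.samples.size), fs=FS)
        snr = compute_snr(noisy, peaks)
        assert abs(snr) <= 0.5

    def test_pure_noise_is_negative(self):
        rng = np.random.default_rng(2)
        rec = ECGRecord(samples=1e-3 * rng.standard_normal(round(120 * FS)),
                        fs=FS)
        peaks = detect_r_peaks(rec)
        assert peaks.size >= 2
        assert compute_snr(rec, peaks) < 0.0


class TestScreening:
    def test_too_few_peaks_rejected(self):
        rec, _ = beat_train(29)
        report = screen_dataset(rec)
        assert not report.passed
        assert "min_peaks" in report.reasons
        assert report.n_peaks == 29

    def test_low_snr_rejected(self):
        rec, peaks = beat_train(120)
        sigma = 2.5 * np.sqrt(np.mean(rec.samples ** 2))
        noisy = ECGRecord(samples=rec.samples + sigma * np.random
                          .default_rng(3).standard_normal(rec.samples.size),
                          fs=FS)
        report = screen_dataset(noisy)
        assert not report.passed
        assert "snr" in report.reasons

    def test_clean_long_record_passes(self):
        rec, _ = beat_train(120)
        report = screen_dataset(rec)
        assert report.passed and not report.reasons
        assert report.snr_db >= 0.0 and report.n_peaks >= 30


class TestMeanWaveform:
    def test_identical_beats_reproduce_single_beat(self):
        rec, peaks = beat_train(40)
        beat = mean_waveform(rec, peaks)
        pre_n = beat.r_index
        single = rec.samples[peaks[5] - pre_n:
                             peaks[5] - pre_n + beat.waveform.size]
        assert np.allclose(beat.waveform, single, rtol=0, atol=1e-18)
        assert beat.n_beats_used == 40

    def test_averaging_suppresses_noise_by_sqrt_n(self):
        sigma = 1e-4
        rec, peaks = beat_train(100, noise=sigma, seed=4)
        clean, _ = beat_train(100)
        beat = mean_waveform(rec, peaks)
        ref = mean_waveform(clean, peaks)
        resid = np.std(beat.waveform - ref.waveform)
        # 1/sqrt(100) law within a 3 sigma allowance
        assert resid < 3 * sigma / np.sqrt(100)
        assert resid > sigma / (3 * np.sqrt(100))

    def test_boundary_beats_skipped(self):
        rec, peaks = beat_train(10)
        early = np.r_[round(0.05 * FS), peaks]  # window would start < 0
        beat = mean_waveform(rec, early, pre_r=0.2, post_r=0.4)
        assert beat.n_beats_used == 10

    def test_no_usable_beat_raises(self):
        rec = ECGRecord(samples=np.zeros(100), fs=FS)
        with pytest.raises(EmptyResultError):
            mean_waveform(rec, [5], pre_r=0.25, post_r=0.45)

    def test_rr_metadata_uses_full_detected_grid(self):
        rec, peaks = beat_train(10)
        kept = np.delete(peaks, 4)
        beat = mean_waveform(rec, kept, all_peaks=peaks)
        # every preceding interval comes from the detected grid: all 1 s
        assert np.allclose(beat.rr_s, 1.0, atol=2 / FS)


class TestCsvIO:
    def test_round_trip(self, tmp_path):
        rec, _ = beat_train(5)
        path = tmp_path / "subject03_electrode07.csv"
        write_ecg_csv(rec, path)
        back = read_ecg_csv(path)
        assert abs(back.fs - rec.fs) <= 1e-6 * rec.fs
        assert np.allclose(back.samples, rec.samples, atol=1e-12)
        assert back.subject_id == 3 and back.electrode_id == 7

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="time_s"):
            read_ecg_csv(path)

    def test_nonuniform_time_base_rejected(self, tmp_path):
        path = tmp_path / "warped.csv"
        path.write_text("time_s,voltage_V\n0.0,0\n0.002,0\n0.005,0\n0.006,0\n")
        with pytest.raises(ValueError, match="non-uniform"):
            read_ecg_csv(path)

    def test_unparseable_file_names_offender(self, tmp_path):
        path = tmp_path / "corrupt.csv"
        path.write_bytes(b"\x00\x01\x02 time_s,voltage_V \x00")
        with pytest.raises(ValueError, match="corrupt.csv"):
            read_ecg_csv(path)
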