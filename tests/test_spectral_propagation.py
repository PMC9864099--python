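"""Frequency-domain propagation and inversion of the acquisition chain."""

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq
from scipy.integrate import solve_ivp
from scipy.signal import residue

from wovecg.circuit_model import ElectrodeParams, RationalTF, system_tf
from wovecg.errors import SingularInversionError
from wovecg.spectral_propagation import (apply_tf, invert_tf, recover_in_body,
                                         spill_factor)
from wovecg.synthetic_data import GaussianComponent
from wovecg.waveform_processing import MeanBeat

from conftest import make_beat

FS = 2000.0
IDENTITY = RationalTF([1.0], [1.0])


def random_compact_beat(rng, fs=FS, pre_r=0.25, post_r=0.45) -> MeanBeat:
    """Random sum-of-Gaussians beat whose support lies well inside the
    window, so windowing is lossless and an analytic input is available."""
    comps = []
    for _ in range(rng.integers(3, 6)):
        # supports end > 6 sigma inside the window so the signal is at rest
        # at both edges (required for a from-rest time-domain oracle)
        comps.append(GaussianComponent(
            amplitude=float(rng.uniform(-1.0, 1.0)) * 1e-3,
            center=float(rng.uniform(-0.12, 0.30)),
            width=float(rng.uniform(0.008, 0.020))))
    n = round((pre_r + post_r) * fs) + 1
    t = np.arange(n) / fs - pre_r
    x = np.zeros(n)
    for c in comps:
        x += c.amplitude * np.exp(-0.5 * ((t - c.center) / c.width) ** 2)
    beat = MeanBeat(waveform=x, fs=fs, n_beats_used=1,
                    pre_r=pre_r, post_r=post_r)
    return beat, comps


def ode_oracle(tf: RationalTF, comps, t):
    """Independent time-domain simulation via pole-residue scalar ODEs.

    Partial fractions give H(s) = sum_i r_i / (s - p_i); each term is the
    scalar ODE z' = p z + u(t) with the analytic input u, integrated with a
    tight-tolerance Runge-Kutta solver from rest.
    """
    res, poles, direct = residue(tf.num, tf.den)
    assert direct.size == 0  # strictly proper chain

    def u(tt):
        out = 0.0
        for c in comps:
            out += c.amplitude * np.exp(-0.5 * ((tt - c.center) / c.width) ** 2)
        return out

    def rhs(tt, z):
        return poles * z + u(tt)

    sol = solve_ivp(rhs, (t[0], t[-1]), np.zeros(poles.size, dtype=complex),
                    t_eval=t, rtol=1e-10, atol=1e-16, max_step=1e-3)
    return np.real(res @ sol.y)


class TestApplyTF:
    def test_identity_returns_input(self, beat):
        out = apply_tf(beat, IDENTITY)
        assert np.allclose(out.waveform, beat.waveform, rtol=0,
                           atol=1e-12 * np.abs(beat.waveform).max())

    def test_single_bin_sinusoid_scaled_by_response(self, skin, front):
        """A sinusoid on an exact FFT bin (circular mode) comes out scaled
        by |H| and shifted by arg H at that frequency."""
        tf = system_tf(ElectrodeParams(100e-9, 500e3, 50e3), skin, front)
        n = round(0.7 * FS) + 1
        k = 18                                   # bin index
        f0 = k * FS / n
        t = np.arange(n) / FS
        wave = MeanBeat(waveform=1e-3 * np.cos(2 * np.pi * f0 * t), fs=FS,
                        n_beats_used=1)
        out = apply_tf(wave, tf, pad_factor=1)
        h = complex(tf.freq_response(f0))
        expected = 1e-3 * np.abs(h) * np.cos(2 * np.pi * f0 * t + np.angle(h))
        assert np.allclose(out.waveform, expected,
                           atol=1e-9 * np.abs(expected).max())

    def test_linearity(self, skin, front):
        rng = np.random.default_rng(0)
        tf = system_tf(ElectrodeParams(50e-9, 1e6, 2e5), skin, front)
        x, _ = random_compact_beat(rng)
        y, _ = random_compact_beat(rng)
        lhs = apply_tf(MeanBeat(waveform=2 * x.waveform - 3 * y.waveform,
                                fs=FS, n_beats_used=1), tf)
        rhs_ = 2 * apply_tf(x, tf).waveform - 3 * apply_tf(y, tf).waveform
        assert np.allclose(lhs.waveform, rhs_,
                           atol=1e-9 * np.abs(rhs_).max())

    def test_matches_time_domain_ode_oracle(self, skin, front):
        """FFT-domain application must agree with an independent pole-residue
        time-domain simulation on random beats and random electrodes."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            cd = 10 ** rng.uniform(-8, -5.7)
            corner = 10 ** rng.uniform(np.log10(2.0), np.log10(30.0))
            params = ElectrodeParams(Cd=cd,
                                     Rd=1 / (2 * np.pi * corner * cd),
                                     Rs=10 ** rng.uniform(4, 6))
            tf = system_tf(params, skin, front)
            beat, comps = random_compact_beat(rng)
            got = apply_tf(beat, tf, pad_factor=8).waveform
            t = np.arange(beat.waveform.size) / FS - beat.pre_r
            ref = ode_oracle(tf, comps, t)
            peak = np.abs(ref).max()
            assert np.abs(got - ref).max() <= 1e-6 * peak

    def test_notch_removes_mains_bin(self, skin, front):
        """After forward application essentially no energy remains at the
        notch frequency."""
        n = 2000                                  # 1 s window: 1 Hz bins
        rng = np.random.default_rng(5)
        x = rng.standard_normal(n) * 1e-3
        wave = MeanBeat(waveform=x, fs=FS, n_beats_used=1,
                        pre_r=0.5, post_r=(n - 1) / FS - 0.5)
        tf = system_tf(ElectrodeParams(100e-9, 500e3, 50e3), skin, front)
        out = apply_tf(wave, tf, pad_factor=1)
        spec_in = rfft(x)
        spec_out = rfft(out.waveform)
        k60 = 60  # exact bin
        assert (np.abs(spec_out[k60]) ** 2
                <= 1e-6 * np.abs(spec_in[k60]) ** 2 + 1e-300)


class TestInvertTF:
    def test_round_trip_exact_in_circular_mode(self, skin, front):
        beat = make_beat(zero_mean=True)
        tf = system_tf(ElectrodeParams(100e-9, 500e3, 50e3), skin, front)
        fwd = apply_tf(beat, tf, pad_factor=1)
        back = invert_tf(fwd, tf, reg_eps=0.0, pad_factor=1)
        err = np.linalg.norm(back.waveform - beat.waveform)
        assert err <= 1e-6 * np.linalg.norm(beat.waveform)

    def test_identity_inversion(self, beat):
        out = invert_tf(beat, IDENTITY, reg_eps=0.0)
        assert np.allclose(out.waveform, beat.waveform, rtol=0,
                           atol=1e-12 * np.abs(beat.waveform).max())

    def test_regularization_bounds_notch_amplification(self, skin, front):
        """With Tikhonov regularization the notch bin is suppressed rather
        than amplified: |out| <= |in| / (2 eps |H|_max) at every bin."""
        reg = 1e-3
        tf = system_tf(ElectrodeParams(100e-9, 500e3, 50e3), skin, front)
        n = 2000
        rng = np.random.default_rng(9)
        wave = MeanBeat(waveform=1e-3 * rng.standard_normal(n), fs=FS,
                        n_beats_used=1, pre_r=0.5, post_r=(n - 1) / FS - 0.5)
        out = invert_tf(wave, tf, reg_eps=reg, pad_factor=1)
        spec_in = np.abs(rfft(wave.waveform))
        spec_out = np.abs(rfft(out.waveform))
        h_max = np.abs(tf.freq_response(rfftfreq(n, 1 / FS))).max()
        bound = spec_in / (2 * reg * h_max)
        assert np.all(spec_out <= bound * (1 + 1e-9) + 1e-300)

    def test_zero_response_rejected(self, beat):
        dead = RationalTF([0.0], [1.0])
        with pytest.raises(SingularInversionError):
            invert_tf(beat, dead, reg_eps=0.0)


class TestRecoverInBody:
    def test_identity_chain_returns_measurement(self, beat):
        out = recover_in_body(beat, IDENTITY)
        assert np.allclose(out.waveform, beat.waveform,
                           atol=1e-5 * np.abs(beat.waveform).max())

    def test_flat_gain_chain_halves(self, beat):
        out = recover_in_body(beat, RationalTF([2.0], [1.0]))
        assert np.allclose(out.waveform, beat.waveform / 2,
                           atol=1e-5 * np.abs(beat.waveform).max())

    def test_recovers_known_in_body_beat(self, skin, front, adhesive_params):
        beat = make_beat()
        tf = system_tf(adhesive_params, skin, front)
        measured = apply_tf(beat, tf)
        rec = recover_in_body(measured, tf)
        assert np.corrcoef(rec.waveform, beat.waveform)[0, 1] > 0.999


class TestSpillFactor:
    def test_none_is_identity(self):
        assert spill_factor(np.arange(5.0), None) == 1.0

    def test_zero_frequency_counts_all_beats(self):
        # at DC every phasor is 1: factor = 2 (or 3 with the two-back term)
        f = np.array([0.0])
        rr = np.full(10, 0.9)
        assert np.allclose(spill_factor(f, rr), 2.0)
        assert np.allclose(spill_factor(f, rr, 2 * rr), 3.0)

    def test_models_preceding_beat_ringing(self, skin, front):
        """A beat average cut from a filtered train equals the isolated-beat
        response times the spill factor (first-order check on a clean,
        exactly periodic train)."""
        rr = 1.0
        n_beats = 30
        beat = make_beat()
        tf = system_tf(ElectrodeParams(100e-9, 500e3, 50e3), skin, front)
        n = beat.waveform.size
        series = np.zeros(round((n_beats + 2) * rr * FS))
        for k in range(n_beats):
            start = round((k + 1) * rr * FS) - beat.r_index
            series[start:start + n] += beat.waveform
        from wovecg.synthetic_data import _propagate_series
        y = _propagate_series(series, FS, tf)
        peaks = [round((k + 1) * rr * FS) for k in range(2, n_beats)]
        windows = np.array([y[p - beat.r_index:p - beat.r_index + n]
                            for p in peaks])
        measured = windows.mean(axis=0)
        rr_arr = np.full(len(peaks), rr)
        model = apply_tf(beat, tf, spill_rr=rr_arr).waveform
        plain = apply_tf(beat, tf).waveform
        peak = np.abs(measured).max()
        assert (np.abs(model - measured).max()
                < 0.2 * np.abs(plain - measured).max())
        assert np.abs(model - measured).max() < 1e-3 * peak
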