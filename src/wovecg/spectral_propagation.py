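"""Frequency-domain application and inversion of the acquisition chain.

A mean beat is a short finite waveform; passing it through (or undoing) the
measurement chain is done bin-wise on its FFT, evaluating the rational
transfer function at the continuous bin frequencies H(j 2 pi f_k). Beats are
zero-padded before the FFT so that the filter's impulse-response tail decays
inside the padded block, making the circular product an accurate linear
convolution; the result is cropped back to the original length.

Inversion uses Tikhonov-regularized spectral division,

    Vin = Vout * conj(H) / (|H|^2 + (eps * max|H|)^2),

because the band-pass and notch have true zeros (DC, 60 Hz) where literal
division is undefined. With eps = 0 the division is exact wherever |H| is
nonzero; bins where both |H| and the signal vanish are zeroed, and a bin
where the signal carries energy but |H| ~ 0 raises SingularInversionError.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft, rfftfreq

from .circuit_model import RationalTF
from .errors import SingularInversionError
from .waveform_processing import MeanBeat

__all__ = ["apply_tf", "invert_tf", "recover_in_body", "DEFAULT_PAD_FACTOR",
           "DEFAULT_REG_EPS"]

DEFAULT_PAD_FACTOR = 4
DEFAULT_REG_EPS = 1e-4


def spill_factor(freqs, rr_s, rr2_s=None):
    """Spectral factor 1 + mean_k exp(+j 2 pi f RR_k) [+ two-back term].

    A beat average taken from a filtered beat train is the single-beat
    response plus the RR-averaged response of the preceding beat evaluated
    one RR interval later (its ringing outlasts the RR gap; the following
    beat cannot contribute, by causality). The advance v(tau + RR) is the
    positive-exponent phase factor. Multiplying H by this factor models the
    averaged window exactly for identical beats at the recorded RR
    intervals. ``rr_s`` is the list of preceding RR intervals in seconds;
    ``None`` or empty falls back to the isolated-beat model (factor 1).
    """
    if rr_s is None:
        return 1.0
    rr = np.atleast_1d(np.asarray(rr_s, dtype=float))
    if rr.size == 0:
        return 1.0
    f = np.asarray(freqs, dtype=float)
    out = 1.0 + np.mean(np.exp(2j * np.pi * f[:, None] * rr[None, :]), axis=1)
    if rr2_s is not None:
        rr2 = np.atleast_1d(np.asarray(rr2_s, dtype=float))
        if rr2.size:
            # the beat two RR intervals back still rings faintly at the
            # window; its decayed tail matters at the 1e-4 level
            out = out + np.mean(np.exp(2j * np.pi * f[:, None] * rr2[None, :]),
                                axis=1)
    return out


def _padded_grid(n: int, fs: float, pad_factor: int):
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    # pad_factor == 1 is pure circular semantics at the beat length (exactly
    # invertible); padded modes round up to a fast FFT size
    n_fft = n if pad_factor == 1 else next_fast_len(pad_factor * n)
    return n_fft, rfftfreq(n_fft, 1.0 / fs)


def apply_tf(wave: MeanBeat, tf: RationalTF,
             pad_factor: int = DEFAULT_PAD_FACTOR,
             spill_rr=None) -> MeanBeat:
    """Propagate a beat through H(s): bin-wise spectral multiplication.

    Output has the same length, sampling rate and window as the input and is
    real by construction (real-input FFT). ``spill_rr`` optionally models
    preceding-beat ringing for window averages (see :func:`spill_factor`).
    """
    x = wave.waveform
    if x.size == 0:
        raise ValueError("empty waveform")
    n_fft, freqs = _padded_grid(x.size, wave.fs, pad_factor)
    h = tf.freq_response(freqs)  # raises DegenerateModelError on a pole
    h = h * spill_factor(freqs, spill_rr)
    y = irfft(rfft(x, n_fft) * h, n_fft)[: x.size]
    return replace(wave, waveform=y)


def invert_tf(wave: MeanBeat, tf: RationalTF,
              reg_eps: float = DEFAULT_REG_EPS,
              pad_factor: int = DEFAULT_PAD_FACTOR,
              spill_rr=None) -> MeanBeat:
    """Undo H(s) by (regularized) spectral division; see module docstring."""
    if reg_eps < 0:
        raise ValueError("reg_eps must be non-negative")
    x = wave.waveform
    if x.size == 0:
        raise ValueError("empty waveform")
    n_fft, freqs = _padded_grid(x.size, wave.fs, pad_factor)
    spec = rfft(x, n_fft)
    h = tf.freq_response(freqs) * spill_factor(freqs, spill_rr)
    h_max = float(np.max(np.abs(h)))
    if h_max == 0.0:
        raise SingularInversionError("transfer function is identically zero")
    if reg_eps > 0.0:
        out = spec * np.conj(h) / (np.abs(h) ** 2 + (reg_eps * h_max) ** 2)
    else:
        small = np.abs(h) < 1e-12 * h_max
        # bins where H truly vanishes are unrecoverable; drop them, but a
        # substantial energy fraction there means the inversion is singular
        dropped = np.linalg.norm(spec[small])
        if dropped > 1e-2 * np.linalg.norm(spec):
            raise SingularInversionError(
                "substantial signal energy at frequencies where |H| "
                "vanishes; use reg_eps > 0"
            )
        out = np.zeros_like(spec)
        out[~small] = spec[~small] / h[~small]
    y = irfft(out, n_fft)[: x.size]
    return replace(wave, waveform=y)


def recover_in_body(adhesive_beat: MeanBeat, adhesive_tf: RationalTF,
                    pad_factor: int = DEFAULT_PAD_FACTOR,
                    damp: float = 1e-3,
                    maxiter: int = 600) -> MeanBeat:
    """Recover the in-body beat from an adhesive-electrode mean beat.

    The adhesive chain parameters are known, so undoing its transfer
    function on the gold-standard recording yields the subject's "true"
    cardiac waveform. The beat's recorded RR intervals, when present,
    correct for preceding-beat ringing in the average.

    The forward map from a windowed in-body beat to a windowed measurement
    is convolution followed by cropping, so its inverse is not bin-wise
    spectral division (cropping couples the bins). The recovery instead
    solves the windowed-deconvolution least-squares problem

        min_r || Crop(h_eff * Embed(r)) - m ||^2 + (damp * |H|_max)^2 ||r||^2

    matrix-free with LSMR (FFT-based operator and adjoint). The Tikhonov
    damping suppresses the unobservable directions - DC of the AC-coupled
    chain and the notch band - instead of amplifying them.

    When the beat average carries a known noise level
    (``adhesive_beat.noise_std``), a curvature (second-difference) penalty
    lambda^2 ||D2 r||^2 is added and lambda is chosen by the discrepancy
    principle: the largest value whose reconstruction residual still sits
    at the noise level. The cardiac beat is smooth, so the penalty leaves
    its (low-frequency) content essentially unbiased while suppressing the
    jagged measurement noise that would otherwise propagate into the
    recovered waveform and bias the downstream fit (an errors-in-variables
    effect). Noiseless averages keep only the floor damping and are
    reproduced essentially exactly. Deterministic in its inputs; callers
    cache the result per subject.
    """
    from scipy.sparse.linalg import LinearOperator, lsmr

    x = adhesive_beat.waveform
    if x.size == 0:
        raise ValueError("empty waveform")
    n = x.size
    n_fft, freqs = _padded_grid(n, adhesive_beat.fs, max(pad_factor, 2))
    heff = (adhesive_tf.freq_response(freqs)
            * spill_factor(freqs, adhesive_beat.rr_s, adhesive_beat.rr2_s))
    h_max = float(np.max(np.abs(heff)))
    if h_max == 0.0:
        raise SingularInversionError("transfer function is identically zero")

    def forward(r):
        return irfft(rfft(r, n_fft) * heff, n_fft)[:n]

    def solve(lam):
        def matvec(r):
            d2 = lam * (r[:-2] - 2.0 * r[1:-1] + r[2:])
            return np.concatenate([forward(r), d2])

        def rmatvec(v):
            v1, v2 = v[:n], v[n:]
            out = irfft(rfft(v1, n_fft) * np.conj(heff), n_fft)[:n]
            out[:-2] += lam * v2
            out[1:-1] -= 2.0 * lam * v2
            out[2:] += lam * v2
            return out

        op = LinearOperator((2 * n - 2, n), matvec=matvec, rmatvec=rmatvec,
                            dtype=float)
        b = np.concatenate([x, np.zeros(n - 2)])
        r = lsmr(op, b, damp=damp * h_max, maxiter=maxiter,
                 atol=1e-10, btol=1e-10)[0]
        resid = float(np.sqrt(np.mean((forward(r) - x) ** 2)))
        return r, resid

    r, resid_floor = solve(0.0)
    noise = adhesive_beat.noise_std
    if noise is not None and noise > 0:
        # largest lambda on a log grid whose residual stays at the noise
        # level; the residual is monotone in lambda, so bisect the grid
        target = math.hypot(resid_floor, noise)
        grid = np.geomspace(0.01 * h_max, 1e5 * h_max, 12)
        lo_i, hi_i, best = -1, len(grid), None
        while hi_i - lo_i > 1:
            mid = (lo_i + hi_i) // 2
            r_cand, resid = solve(float(grid[mid]))
            if resid <= target:
                lo_i, best = mid, r_cand
            else:
                hi_i = mid
        if best is not None:
            r = best
    return replace(adhesive_beat, waveform=r)
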