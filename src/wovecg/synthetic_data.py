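"""Synthetic ECG studies with known ground truth.

The generator emulates the study design the rest of the package analyses:
6 seated subjects, ~2 minutes of single-lead ECG per (subject, electrode)
pair, one adhesive reference electrode plus 16 woven types. Each subject has
a fixed "in-body" PQRST waveform (a sum of five Gaussian deflections with
subject-specific amplitudes, timings and widths) tiled at jittered RR
intervals; every recording is that series propagated through the full
acquisition chain for the electrode's true circuit parameters, then
corrupted with additive white Gaussian measurement noise and occasional
outlier beats (amplitude-scaled segments emulating motion artifacts).

Every stage keeps its ground truth (templates, R-peak times, electrode
parameters) so parameter-recovery and cross-validation claims can be checked
exactly; the whole study is bitwise-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .catalog import ADHESIVE_ID, default_catalog
from .circuit_model import (ElectrodeParams, FrontEndParams, SkinParams,
                            system_tf)
from .waveform_processing import ECGRecord, write_ecg_csv

__all__ = [
    "GaussianComponent",
    "BeatTemplate",
    "StudySpec",
    "Study",
    "default_adhesive_params",
    "woven_truth_table",
    "area_sweep_truths",
    "make_beat_template",
    "render_in_body_series",
    "simulate_measurement",
    "simulate_study",
    "make_study",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One PQRST deflection: amplitude (V), center (s, R peak at 0), width
    (Gaussian sigma, s)."""

    amplitude: float
    center: float
    width: float


#: nominal deflections of a resting adult beat, volts / seconds; supports
#: lie well inside the default averaging window (-0.25 s, +0.45 s) so the
#: windowed beat carries the whole PQRST complex
_BASE_COMPONENTS = (
    GaussianComponent(0.12e-3, -0.160, 0.018),   # P
    GaussianComponent(-0.15e-3, -0.035, 0.010),  # Q
    GaussianComponent(1.00e-3, 0.000, 0.012),    # R
    GaussianComponent(-0.25e-3, 0.040, 0.012),   # S
    GaussianComponent(0.35e-3, 0.250, 0.038),    # T
)


@dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians PQRST waveform (the subject's in-body beat)."""

    components: tuple
    beat_len: float = 0.7

    def __post_init__(self):
        amps = [abs(c.amplitude) for c in self.components]
        if amps and max(amps) > 0:
            r = max(range(len(amps)), key=amps.__getitem__)
            centers = [c.center for c in self.components]
            if centers != sorted(centers):
                raise ValueError("component centers must be ordered in time")
            # R dominance is a property of the construction; tolerate ties
            if amps[r] < max(a for i, a in enumerate(amps) if i != r):
                raise ValueError("R deflection must dominate")

    def render(self, t) -> np.ndarray:
        """Evaluate the template at times t (seconds, R peak at 0)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.components:
            out += c.amplitude * np.exp(-0.5 * ((t - c.center) / c.width) ** 2)
        return out

    @property
    def peak_amplitude(self) -> float:
        return max(abs(c.amplitude) for c in self.components)


def default_adhesive_params() -> ElectrodeParams:
    """Known interface triple of the clinical wet Ag/AgCl reference."""
    return ElectrodeParams(Cd=4.7e-6, Rd=12e3, Rs=150.0)


def area_sweep_truths(scale_cd: float = 10e-9, scale_rd: float = 6e6,
                      scale_rs: float = 3e6) -> dict:
    """True parameters for the 8 area-sweep electrodes (ids 1-8).

    Capacitance grows and both resistances shrink proportionally with patch
    area (parallel-plate / volume-conduction scaling), keeping the Rd*Cd
    corner near 2.7 Hz for every size. Scales put |Z_E| in the
    hundreds-of-kOhm dry-electrode regime.
    """
    cat = default_catalog()
    out = {}
    for _, row in cat[cat["id"] <= 8].iterrows():
        a = row["area_cm2"]
        out[int(row["id"])] = ElectrodeParams(Cd=scale_cd * a,
                                              Rd=scale_rd / a,
                                              Rs=scale_rs / a)
    return out


def woven_truth_table() -> dict:
    """Default ground truth for all 16 woven electrode types.

    Ids 1-8 follow the area sweep; ids 9-16 span Cd over more than two
    decades with Rd chosen so the Rd*Cd corner frequency stays inside the
    1-35 Hz pass-band (larger capacitances paired with lower corners, so
    every Rd stays in the tens-of-kOhm-and-up dry-electrode regime) and Rs
    within a factor of ~3 of Rd so that both resistors leave a visible
    signature in the divider response.
    """
    out = area_sweep_truths()
    cds = np.logspace(math.log10(1e-8), math.log10(2e-6), 8)
    corners = np.logspace(math.log10(15.0), math.log10(3.0), 8)
    ratios = [0.3, 1.0, 3.0, 0.5, 2.0, 0.4, 1.5, 0.7]
    for k in range(8):
        rd = 1.0 / (2.0 * math.pi * corners[k] * cds[k])
        out[9 + k] = ElectrodeParams(Cd=float(cds[k]), Rd=float(rd),
                                     Rs=float(ratios[k] * rd))
    return out


@dataclass
class StudySpec:
    """Design of one synthetic study (defaults mirror the emulated study:
    6 seated subjects, ~2 min per recording, 17 electrode types)."""

    n_subjects: int = 6
    duration: float = 120.0
    fs: float = 2000.0
    heart_rate_bpm: float = 65.0
    rr_jitter: float = 0.03
    snr_db: float | None = 20.0       # None -> noiseless
    outlier_rate: float = 0.02
    electrode_truths: dict = field(default_factory=woven_truth_table)
    adhesive: ElectrodeParams = field(default_factory=default_adhesive_params)
    adhesive_id: int = ADHESIVE_ID
    skin: SkinParams = field(default_factory=SkinParams)
    front: FrontEndParams = field(default_factory=FrontEndParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.duration <= 0 or self.fs <= 0:
            raise ValueError("study dimensions must be positive")
        if self.adhesive_id in self.electrode_truths:
            raise ValueError("adhesive id collides with a woven electrode id")

    @property
    def electrode_ids(self) -> list:
        return sorted(self.electrode_truths) + [self.adhesive_id]

    def params_for(self, electrode_id: int) -> ElectrodeParams:
        if electrode_id == self.adhesive_id:
            return self.adhesive
        return self.electrode_truths[electrode_id]


def _rng_for(spec_seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(spec_seed)] + [int(s) for s in stream])


def make_beat_template(seed: int, subject_id: int,
                       amplitude_scale: float = 1.0) -> BeatTemplate:
    """Randomized but physiologic per-subject PQRST template.

    Deterministic per (seed, subject): amplitudes jittered +-20%, centers by
    a few ms and widths +-10% around the nominal beat; the jitter bounds
    keep the P<Q<R<S<T ordering and R dominance by construction.
    ``amplitude_scale`` = 0 yields a flat template.
    """
    rng = _rng_for(seed, 1, subject_id)
    comps = []
    for c in _BASE_COMPONENTS:
        amp = c.amplitude * (1.0 + 0.2 * rng.uniform(-1, 1)) * amplitude_scale
        center = c.center + (0.0 if c.center == 0.0
                             else 0.004 * rng.uniform(-1, 1))
        width = c.width * (1.0 + 0.1 * rng.uniform(-1, 1))
        comps.append(GaussianComponent(amp, center, width))
    return BeatTemplate(components=tuple(comps))


def render_in_body_series(template: BeatTemplate, spec: StudySpec,
                          subject_id: int):
    """Tile the template at jittered RR intervals over the study duration.

    Returns (record, true R-peak sample indices). With zero jitter at
    60 bpm and 120 s this yields exactly 120 beats 1 s apart.
    """
    rng = _rng_for(spec.seed, 2, subject_id)
    rr0 = 60.0 / spec.heart_rate_bpm
    margin = 0.5
    t_beats = []
    t = margin
    while t <= spec.duration - margin + 1e-9:
        t_beats.append(t)
        rr = rr0 * (1.0 + spec.rr_jitter * rng.standard_normal())
        t += float(np.clip(rr, 0.5 * rr0, 1.5 * rr0))
    n = round(spec.duration * spec.fs)
    x = np.zeros(n)
    half = template.beat_len / 2.0 + 0.2
    for tb in t_beats:
        lo = max(0, int((tb - half) * spec.fs))
        hi = min(n, int((tb + half) * spec.fs) + 1)
        tt = np.arange(lo, hi) / spec.fs - tb
        x[lo:hi] += template.render(tt)
    peaks = np.array([round(tb * spec.fs) for tb in t_beats], dtype=int)
    rec = ECGRecord(samples=x, fs=spec.fs, subject_id=subject_id,
                    electrode_id=None)
    return rec, peaks


def _propagate_series(x: np.ndarray, fs: float, tf) -> np.ndarray:
    """Linear-convolution propagation of a long series through H(s): single
    zero-padded FFT block with continuous-frequency evaluation of the chain
    (the pad leaves room for the slowest pole's tail to decay)."""
    n = x.size
    n_fft = next_fast_len(n + int(4.0 * fs))
    h = tf.freq_response(rfftfreq(n_fft, 1.0 / fs))
    return irfft(rfft(x, n_fft) * h, n_fft)[:n]


def simulate_measurement(in_body: ECGRecord, electrode: ElectrodeParams,
                         spec: StudySpec, electrode_id: int,
                         peak_indices=None) -> ECGRecord:
    """One (subject, electrode) recording: chain propagation, then outlier
    beats (single beats scaled x3-10, emulating artifacts the screening
    stage should remove), then additive white noise at the spec SNR."""
    tf = system_tf(electrode, spec.skin, spec.front)
    y = _propagate_series(in_body.samples, in_body.fs, tf)
    rng = _rng_for(spec.seed, 3, in_body.subject_id, electrode_id)
    if peak_indices is not None and spec.outlier_rate > 0:
        fs = in_body.fs
        for p in np.asarray(peak_indices, dtype=int):
            if rng.random() < spec.outlier_rate:
                lo = max(0, p - round(0.25 * fs))
                hi = min(y.size, p + round(0.45 * fs) + 1)
                y[lo:hi] *= rng.uniform(3.0, 10.0)
    if spec.snr_db is not None and np.isfinite(spec.snr_db):
        p_sig = float(np.mean(y ** 2))
        sigma = math.sqrt(p_sig / 10.0 ** (spec.snr_db / 10.0))
        y = y + sigma * rng.standard_normal(y.size)
    return ECGRecord(samples=y, fs=in_body.fs,
                     subject_id=in_body.subject_id, electrode_id=electrode_id)


@dataclass
class Study:
    """A fully materialized synthetic study with its ground truth."""

    spec: StudySpec
    templates: dict           # subject_id -> BeatTemplate
    in_body: dict             # subject_id -> ECGRecord
    true_peaks: dict          # subject_id -> R-peak sample indices
    records: dict             # (subject_id, electrode_id) -> ECGRecord

    @property
    def subject_ids(self) -> list:
        return sorted(self.templates)


def simulate_study(spec: StudySpec) -> Study:
    """Generate the complete study in memory (no file I/O)."""
    templates, in_body, true_peaks, records = {}, {}, {}, {}
    for subject in range(1, spec.n_subjects + 1):
        templates[subject] = make_beat_template(spec.seed, subject)
        rec, peaks = render_in_body_series(templates[subject], spec, subject)
        in_body[subject], true_peaks[subject] = rec, peaks
        for eid in spec.electrode_ids:
            records[(subject, eid)] = simulate_measurement(
                rec, spec.params_for(eid), spec, eid, peak_indices=peaks)
    return Study(spec=spec, templates=templates, in_body=in_body,
                 true_peaks=true_peaks, records=records)


def _manifest(study: Study) -> dict:
    spec = study.spec
    return {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "duration_s": spec.duration,
        "fs_hz": spec.fs,
        "heart_rate_bpm": spec.heart_rate_bpm,
        "rr_jitter": spec.rr_jitter,
        "snr_db": spec.snr_db,
        "outlier_rate": spec.outlier_rate,
        "adhesive_id": spec.adhesive_id,
        "adhesive_params": {"Cd": spec.adhesive.Cd, "Rd": spec.adhesive.Rd,
                            "Rs": spec.adhesive.Rs},
        "electrode_truths": {
            int(eid): {"Cd": p.Cd, "Rd": p.Rd, "Rs": p.Rs}
            for eid, p in sorted(spec.electrode_truths.items())
        },
        "templates": {
            int(s): [[c.amplitude, c.center, c.width]
                     for c in t.components]
            for s, t in sorted(study.templates.items())
        },
        "true_r_peaks": {int(s): [int(p) for p in peaks]
                         for s, peaks in sorted(study.true_peaks.items())},
    }


def make_study(spec: StudySpec, out_dir) -> Study:
    """Materialize a study as one CSV per (subject, electrode) plus a
    ground-truth manifest (YAML). Same seed -> byte-identical manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(spec)
    for (subject, eid), rec in sorted(study.records.items()):
        write_ecg_csv(rec, out_dir / f"subject{subject:02d}_electrode{eid:02d}.csv")
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_manifest(study), fh, sort_keys=True)
    from .catalog import write_catalog
    write_catalog(default_catalog(), out_dir / "catalog.csv")
    return study
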