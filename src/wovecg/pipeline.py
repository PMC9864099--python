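"""End-to-end orchestration: screen datasets, average beats, recover the
in-body waveform from the adhesive reference, fit every woven electrode and
cross-validate, and join the fits against the manufacturing catalogue.

Works either on a directory of CSV recordings (the CLI path) or directly on
an in-memory synthetic :class:`~wovecg.synthetic_data.Study`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import waveform_processing as wp
from .circuit_model import impedance_mag_phase, system_tf
from .config import Config, default_config
from .cross_validation import LoocvResult, loocv
from .errors import WovecgError
from .parameter_fitting import FitProblem, FitResult, SubjectPair, fit_electrode
from .spectral_propagation import recover_in_body

__all__ = ["PipelineResult", "screen_and_average", "recover_in_body_beats",
           "build_fit_problem", "fit_electrodes", "run_loocv", "run_pipeline",
           "load_records", "summarize_vs_manufacturing", "plot_summary",
           "fit_report_frame", "loocv_report_frame", "screening_frame"]

log = logging.getLogger("wovecg")


@dataclass
class PipelineResult:
    """Everything one analysis run produced."""

    screening: list                  # ScreeningReport per dataset
    mean_beats: dict                 # (subject, electrode) -> MeanBeat
    in_body: dict                    # subject -> MeanBeat
    fits: dict = field(default_factory=dict)    # electrode -> FitResult
    loocv: dict = field(default_factory=dict)   # electrode -> LoocvResult


def load_records(data_dir) -> dict:
    """Read every ``subjectNN_electrodeMM.csv`` under ``data_dir``."""
    data_dir = Path(data_dir)
    records = {}
    for path in sorted(data_dir.glob("subject*_electrode*.csv")):
        rec = wp.read_ecg_csv(path)
        records[(rec.subject_id, rec.electrode_id)] = rec
    if not records:
        raise WovecgError(f"no ECG records found under {data_dir}")
    return records


def screen_and_average(records: dict, config: Config):
    """Screen every dataset; average retained beats of the passing ones.

    Returns (mean_beats, screening_reports). Failing datasets are logged
    with their reasons and excluded from all later stages.
    """
    proc = config.processing
    beats, reports = {}, []
    for key, rec in sorted(records.items()):
        peaks = wp.detect_r_peaks(rec, refractory=proc.refractory)
        report = wp.screen_dataset(
            rec, min_peaks=proc.min_peaks, min_snr_db=proc.min_snr_db,
            refractory=proc.refractory, pre_r=proc.pre_r, post_r=proc.post_r,
            peaks=peaks)
        reports.append(report)
        if not report.passed:
            log.info("screened out subject=%s electrode=%s (%s; SNR=%.1f dB, "
                     "%d peaks)", rec.subject_id, rec.electrode_id,
                     ",".join(report.reasons), report.snr_db, report.n_peaks)
            continue
        retained = wp.reject_outlier_beats(peaks, rec)
        clean = wp.drop_contaminated_followers(retained, peaks)
        beats[key] = wp.mean_waveform(rec, clean, all_peaks=peaks,
                                      pre_r=proc.pre_r, post_r=proc.post_r)
    return beats, reports


def recover_in_body_beats(mean_beats: dict, config: Config,
                          adhesive_id: int) -> dict:
    """Invert the known adhesive chain on each subject's adhesive beat.

    Raises if no subject has a usable adhesive dataset (in-body recovery,
    and hence any fitting, is then impossible). Results are cached per
    subject by virtue of being computed once here.
    """
    adhesive_tf = system_tf(config.adhesive, config.skin, config.frontend)
    in_body = {}
    for (subject, eid), beat in mean_beats.items():
        if eid == adhesive_id:
            in_body[subject] = recover_in_body(
                beat, adhesive_tf, pad_factor=config.processing.pad_factor)
    if not in_body:
        raise WovecgError(
            "no subject has a usable adhesive dataset; cannot recover the "
            "in-body waveform")
    return in_body


def build_fit_problem(electrode_id, mean_beats: dict, in_body: dict,
                      config: Config) -> FitProblem | None:
    """Pair each subject's in-body beat with their measured beat for one
    electrode. ``None`` when no subject has both."""
    pairs = []
    for subject in sorted(in_body):
        beat = mean_beats.get((subject, electrode_id))
        if beat is not None:
            pairs.append(SubjectPair(subject_id=subject,
                                     in_body=in_body[subject],
                                     measured=beat))
    if not pairs:
        return None
    proc = config.processing
    return FitProblem(pairs=pairs, skin=config.skin, front=config.frontend,
                      bounds=dict(config.fit_bounds),
                      pad_factor=proc.pad_factor, align=proc.align)


def fit_electrodes(mean_beats: dict, in_body: dict, config: Config,
                   electrode_ids, seed: int = 0, **fit_kwargs) -> dict:
    fits = {}
    for eid in sorted(electrode_ids):
        problem = build_fit_problem(eid, mean_beats, in_body, config)
        if problem is None:
            log.warning("electrode %s: no usable subject pairs; skipped", eid)
            continue
        fits[eid] = fit_electrode(problem, seed=seed, **fit_kwargs)
        log.info("electrode %s: cost=%.3g over %d subjects", eid,
                 fits[eid].total_cost, len(problem.pairs))
    return fits


def run_loocv(mean_beats: dict, in_body: dict, config: Config,
              electrode_ids, seed: int = 0, **fit_kwargs) -> dict:
    results = {}
    for eid in sorted(electrode_ids):
        problem = build_fit_problem(eid, mean_beats, in_body, config)
        if problem is None or len(problem.pairs) < 2:
            log.warning("electrode %s: fewer than 2 subject pairs; "
                        "LOOCV skipped", eid)
            continue
        results[eid] = loocv(problem, seed=seed, electrode_id=eid,
                             **fit_kwargs)
    return results


def run_pipeline(records: dict, config: Config | None = None, seed: int = 0,
                 adhesive_id: int | None = None, with_loocv: bool = False,
                 **fit_kwargs) -> PipelineResult:
    """Full analysis on a set of loaded records (see module docstring)."""
    config = config or default_config()
    if adhesive_id is None:
        from .catalog import ADHESIVE_ID
        adhesive_id = ADHESIVE_ID
    beats, reports = screen_and_average(records, config)
    in_body = recover_in_body_beats(beats, config, adhesive_id)
    woven_ids = sorted({eid for (_, eid) in beats if eid != adhesive_id})
    fits = fit_electrodes(beats, in_body, config, woven_ids, seed=seed,
                          **fit_kwargs)
    result = PipelineResult(screening=reports, mean_beats=beats,
                            in_body=in_body, fits=fits)
    if with_loocv:
        result.loocv = run_loocv(beats, in_body, config, woven_ids,
                                 seed=seed, **fit_kwargs)
    return result


# ---------------------------------------------------------------------------
# report frames

def screening_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": r.subject_id, "electrode_id": r.electrode_id,
         "snr_db": r.snr_db, "n_peaks": r.n_peaks, "passed": r.passed,
         "reasons": ";".join(r.reasons)}
        for r in reports
    ])


def fit_report_frame(fits: dict, config: Config,
                     at_hz: float = 25.0) -> pd.DataFrame:
    """Fit report: parameters plus |Z_E| and phase at the display frequency."""
    rows = []
    for eid, fit in sorted(fits.items()):
        mag, phase = impedance_mag_phase(fit.params, config.skin, at_hz)
        rows.append({"electrode_id": eid, "Cd_F": fit.params.Cd,
                     "Rd_ohm": fit.params.Rd, "Rs_ohm": fit.params.Rs,
                     "zE_mag_ohm": float(mag), "zE_phase_deg": float(phase),
                     "total_cost": fit.total_cost,
                     "n_subjects": len(fit.per_subject_cost),
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def loocv_report_frame(results: dict) -> pd.DataFrame:
    rows = []
    for eid, res in sorted(results.items()):
        for fold in res.folds:
            rows.append({"electrode_id": eid,
                         "held_out_subject": fold.subject_id,
                         "fold_rmse_V": fold.rmse, "fold_ok": fold.ok,
                         "mean_rmse_V": res.mean_rmse})
    return pd.DataFrame(rows)


def summarize_vs_manufacturing(fit_report: pd.DataFrame,
                               catalog: pd.DataFrame) -> pd.DataFrame:
    """Join fitted circuit parameters against manufacturing parameters.

    Raises on electrode ids present in the fit report but absent from the
    catalogue (listing the offenders).
    """
    missing = sorted(set(fit_report["electrode_id"])
                     - set(catalog["id"]))
    if missing:
        raise WovecgError(f"fit report ids missing from catalog: {missing}")
    cat = catalog.rename(columns={"id": "electrode_id"})
    cols = ["electrode_id", "label", "area_cm2", "yarn", "pattern"]
    return cat[cols].merge(fit_report, on="electrode_id", how="inner")


def plot_summary(summary: pd.DataFrame, out_dir) -> list:
    """Scatter plots of fitted parameters and |Z_E| versus surface area."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    panels = [("Cd_F", "Cd (F)"), ("Rd_ohm", "Rd (Ohm)"),
              ("Rs_ohm", "Rs (Ohm)"), ("zE_mag_ohm", "|Z_E| at 25 Hz (Ohm)")]
    for col, label in panels:
        fig, ax = plt.subplots(figsize=(5, 4))
        for yarn, grp in summary.groupby("yarn"):
            ax.scatter(grp["area_cm2"], grp[col], label=yarn)
        ax.set_xlabel("surface area (cm$^2$)")
        ax.set_ylabel(label)
        ax.set_yscale("log")
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"summary_{col}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def write_reports(result: PipelineResult, config: Config, out_dir) -> dict:
    """Write screening / fit / LOOCV CSV reports; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["screening"] = out_dir / "screening_log.csv"
    screening_frame(result.screening).to_csv(paths["screening"], index=False)
    paths["fit"] = out_dir / "fit_report.csv"
    fit_report_frame(result.fits, config).to_csv(paths["fit"], index=False)
    if result.loocv:
        paths["loocv"] = out_dir / "loocv_report.csv"
        loocv_report_frame(result.loocv).to_csv(paths["loocv"], index=False)
    return paths
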