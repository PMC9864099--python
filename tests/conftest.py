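"""Shared fixtures.

Light fixtures build single beats and short records; the session-scoped
study fixtures materialize the full six-subject synthetic study once and
share its pipeline products (screened beats, recovered in-body waveforms,
per-electrode fits) across the end-to-end tests that need them.
"""

import numpy as np
import pytest

from wovecg.circuit_model import FrontEndParams, SkinParams
from wovecg.config import default_config
from wovecg.pipeline import (fit_electrodes, recover_in_body_beats,
                             screen_and_average)
from wovecg.synthetic_data import StudySpec, make_beat_template, simulate_study
from wovecg.waveform_processing import MeanBeat

FS = 2000.0


@pytest.fixture(scope="session")
def skin():
    return SkinParams()


@pytest.fixture(scope="session")
def front():
    return FrontEndParams()


def make_beat(template_seed=0, subject=1, fs=FS, pre_r=0.25, post_r=0.45,
              zero_mean=False) -> MeanBeat:
    """One synthetic PQRST beat in the standard averaging window."""
    tmpl = make_beat_template(template_seed, subject)
    n = round((pre_r + post_r) * fs) + 1
    t = np.arange(n) / fs - pre_r
    x = tmpl.render(t)
    if zero_mean:
        x = x - x.mean()
    return MeanBeat(waveform=x, fs=fs, n_beats_used=1, pre_r=pre_r,
                    post_r=post_r, subject_id=subject)


@pytest.fixture()
def beat():
    return make_beat()


@pytest.fixture(scope="session")
def adhesive_params():
    return default_config().adhesive


@pytest.fixture(scope="session")
def noiseless_pipeline(skin, front):
    """Full noiseless study run end to end: study, screened mean beats,
    recovered in-body beats and one fit per woven electrode."""
    spec = StudySpec(snr_db=None, seed=11)
    study = simulate_study(spec)
    config = default_config()
    beats, reports = screen_and_average(study.records, config)
    in_body = recover_in_body_beats(beats, config, spec.adhesive_id)
    fits = fit_electrodes(beats, in_body, config,
                          sorted(spec.electrode_truths), seed=3)
    return {"spec": spec, "study": study, "config": config, "beats": beats,
            "reports": reports, "in_body": in_body, "fits": fits}
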