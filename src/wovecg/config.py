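"""YAML configuration: skin and front-end constants, adhesive reference
parameters, fitting bounds and processing options.

Example file::

    skin:       {Ce: 0.9e-6, Re: 35.2e3, Ru: 2.6e3, RLead: 10.0}
    frontend:   {gain_db: 66.0, f_hp: 1.0, f_lp: 35.0,
                 f_notch: 60.0, notch_q: 30.0, Ramp: 2.0e6}
    adhesive:   {Cd: 4.7e-6, Rd: 12.0e3, Rs: 150.0}
    fit_bounds: {Cd: [1.0e-11, 1.0e-4], Rd: [1.0, 1.0e8], Rs: [1.0, 1.0e8]}
    processing: {pre_r: 0.25, post_r: 0.45, refractory: 0.25,
                 min_peaks: 30, min_snr_db: 0.0, reg_eps: 1.0e-4,
                 pad_factor: 4, align: shift}

All values are SI (farads, ohms, seconds, Hz, dB). Omitted keys fall back
to the defaults shown above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .circuit_model import ElectrodeParams, FrontEndParams, SkinParams
from .parameter_fitting import DEFAULT_BOUNDS

__all__ = ["ProcessingParams", "Config", "default_config", "load_config"]


@dataclass(frozen=True)
class ProcessingParams:
    """Beat extraction / screening / deconvolution knobs."""

    pre_r: float = 0.25
    post_r: float = 0.45
    refractory: float = 0.25
    min_peaks: int = 30
    min_snr_db: float = 0.0
    reg_eps: float = 1e-4
    pad_factor: int = 4
    align: str = "shift"


@dataclass(frozen=True)
class Config:
    skin: SkinParams = field(default_factory=SkinParams)
    frontend: FrontEndParams = field(default_factory=FrontEndParams)
    adhesive: ElectrodeParams = field(
        default_factory=lambda: ElectrodeParams(Cd=4.7e-6, Rd=12e3, Rs=150.0))
    fit_bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    processing: ProcessingParams = field(default_factory=ProcessingParams)


def default_config() -> Config:
    return Config()


def load_config(path=None) -> Config:
    """Load a YAML config, merging over the defaults. ``None`` -> defaults."""
    if path is None:
        return Config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    kwargs = {}
    if "skin" in raw:
        kwargs["skin"] = SkinParams(**{k: float(v) for k, v in raw["skin"].items()})
    if "frontend" in raw:
        kwargs["frontend"] = FrontEndParams(
            **{k: float(v) for k, v in raw["frontend"].items()})
    if "adhesive" in raw:
        kwargs["adhesive"] = ElectrodeParams(
            **{k: float(v) for k, v in raw["adhesive"].items()})
    if "fit_bounds" in raw:
        bounds = dict(DEFAULT_BOUNDS)
        for k, v in raw["fit_bounds"].items():
            lo, hi = (float(x) for x in v)
            bounds[k] = (lo, hi)
        kwargs["fit_bounds"] = bounds
    if "processing" in raw:
        kwargs["processing"] = ProcessingParams(**raw["processing"])
    return Config(**kwargs)
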