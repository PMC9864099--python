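"""Equivalent-circuit models of the skin-electrode interface and ECG front end.

The skin-electrode interface follows the classical double-time-constant
("double time") model: two parallel RC stages in series with ohmic terms,

    Z_E(s) = R_lead + Rd / (1 + s Rd Cd) + Rs + Re / (1 + s Re Ce) + Ru

where (Cd, Rd) describe the electrode-electrolyte interface, Rs the
electrolyte (for a dry textile electrode, the perspiration layer), (Ce, Re)
the epidermis/stratum corneum, Ru the deeper tissue and R_lead the lead wire.
Skin terms are treated as known constants shared by all subjects; the triple
(Cd, Rd, Rs) is specific to an electrode type and is the fitting target.

The acquisition chain is a voltage divider formed by Z_E against half the
amplifier's differential input impedance, cascaded with a flat voltage gain,
a second-order band-pass filter and a second-order notch:

    H(s) = (Ramp/2) / (Z_E(s) + Ramp/2) * G * H_bpf(s) * H_notch(s)

All stages are rational in the Laplace variable s, so the full chain is kept
as a single rational function (order 6 once the two RC poles of Z_E are
included) that can be evaluated at any complex frequency s = j 2 pi f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError

__all__ = [
    "ElectrodeParams",
    "SkinParams",
    "FrontEndParams",
    "RationalTF",
    "electrode_impedance",
    "electrode_impedance_tf",
    "impedance_mag_phase",
    "bandpass_tf",
    "notch_tf",
    "divider_tf",
    "system_tf",
]


def _check_positive_finite(obj, fields):
    for name in fields:
        value = getattr(obj, name)
        if not (np.isfinite(value) and value > 0.0):
            raise ValueError(
                f"{type(obj).__name__}.{name} must be strictly positive and "
                f"finite, got {value!r}"
            )


@dataclass(frozen=True)
class ElectrodeParams:
    """Unknown interface triple of one electrode type.

    Cd : farads, electrode-electrolyte interface capacitance
    Rd : ohms, charge-transfer resistance (parallel with Cd)
    Rs : ohms, electrolyte / perspiration-layer series resistance
    """

    Cd: float
    Rd: float
    Rs: float

    def __post_init__(self):
        _check_positive_finite(self, ("Cd", "Rd", "Rs"))

    def as_array(self) -> np.ndarray:
        return np.array([self.Cd, self.Rd, self.Rs], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ElectrodeParams":
        Cd, Rd, Rs = (float(v) for v in x)
        return cls(Cd=Cd, Rd=Rd, Rs=Rs)

    @property
    def corner_hz(self) -> float:
        """Corner frequency of the Rd||Cd stage, 1/(2 pi Rd Cd)."""
        return 1.0 / (2.0 * math.pi * self.Rd * self.Cd)


@dataclass(frozen=True)
class SkinParams:
    """Known skin/tissue terms, constant across subjects.

    Defaults: Ce = 0.9 uF, Ru = 2.6 kOhm, R_lead = 10 Ohm; Re defaults to
    35.2 kOhm (its printed unit is ambiguous in the source catalogue, so it
    is configuration-exposed rather than asserted).
    """

    Ce: float = 0.9e-6
    Re: float = 35.2e3
    Ru: float = 2.6e3
    RLead: float = 10.0

    def __post_init__(self):
        _check_positive_finite(self, ("Ce", "Re", "Ru", "RLead"))


@dataclass(frozen=True)
class FrontEndParams:
    """Idealized acquisition front end.

    gain_db   : flat amplifier gain in dB (66 dB default)
    f_hp/f_lp : band-pass -3 dB cutoffs in Hz (1 and 35 Hz defaults)
    f_notch   : mains notch center in Hz (60 Hz default)
    notch_q   : notch quality factor (narrow band; width not published,
                default Q = 30)
    Ramp      : differential input impedance in ohms (2 MOhm default); each
                input sees Ramp/2 against its electrode.
    """

    gain_db: float = 66.0
    f_hp: float = 1.0
    f_lp: float = 35.0
    f_notch: float = 60.0
    notch_q: float = 30.0
    Ramp: float = 2.0e6

    def __post_init__(self):
        _check_positive_finite(self, ("f_hp", "f_lp", "f_notch", "notch_q", "Ramp"))
        if not (self.f_hp < self.f_lp < self.f_notch):
            raise ValueError(
                "front-end cutoffs must satisfy f_hp < f_lp < f_notch, got "
                f"{self.f_hp}, {self.f_lp}, {self.f_notch}"
            )
        if not np.isfinite(self.gain_db):
            raise ValueError("gain_db must be finite")

    @property
    def gain_linear(self) -> float:
        return 10.0 ** (self.gain_db / 20.0)


class RationalTF:
    """Rational transfer function H(s) = num(s)/den(s).

    Coefficients are stored in descending powers of s (numpy polynomial
    convention). Cascading is polynomial multiplication; evaluation uses
    Horner's rule and guards against poles on the evaluated frequency.
    """

    __slots__ = ("num", "den")

    def __init__(self, num, den):
        num = np.atleast_1d(np.asarray(num, dtype=float))
        den = np.atleast_1d(np.asarray(den, dtype=float))
        den = np.trim_zeros(den, "f")
        if den.size == 0 or den[0] == 0.0:
            raise ValueError("leading denominator coefficient must be nonzero")
        if not (np.all(np.isfinite(num)) and np.all(np.isfinite(den))):
            raise ValueError("transfer function coefficients must be finite")
        self.num = num
        self.den = den

    @classmethod
    def identity(cls) -> "RationalTF":
        return cls([1.0], [1.0])

    def __call__(self, s, check: bool = True):
        """Evaluate H at complex frequency s (scalar or array)."""
        s = np.asarray(s, dtype=complex)
        num_v = np.polyval(self.num, s)
        den_v = np.polyval(self.den, s)
        if check:
            # pole guard: |den(s)| relative to the scale of its terms
            scale = np.polyval(np.abs(self.den), np.abs(s))
            bad = np.abs(den_v) <= 1e-12 * scale
            if np.any(bad):
                raise DegenerateModelError(
                    "transfer function has a pole at an evaluated frequency"
                )
        return num_v / den_v

    def freq_response(self, f, check: bool = True):
        """H(j 2 pi f) for real frequency f in Hz."""
        return self(2j * np.pi * np.asarray(f, dtype=float), check=check)

    def cascade(self, other: "RationalTF") -> "RationalTF":
        return RationalTF(np.polymul(self.num, other.num),
                          np.polymul(self.den, other.den))

    __mul__ = cascade

    def scale(self, k: float) -> "RationalTF":
        return RationalTF(self.num * float(k), self.den)

    def inf_limit(self) -> float:
        """Limit of H(s) as |s| -> infinity (0 if strictly proper)."""
        if self.num.size > self.den.size:
            raise ValueError("improper transfer function has no finite limit")
        if self.num.size < self.den.size:
            return 0.0
        return float(self.num[0] / self.den[0])

    def __repr__(self):
        return f"RationalTF(num={self.num!r}, den={self.den!r})"


def electrode_impedance(params: ElectrodeParams, skin: SkinParams, s):
    """Skin-electrode interface impedance Z_E at complex frequency s (ohms).

    Z_E(s) = RLead + Rd/(1 + s Rd Cd) + Rs + Re/(1 + s Re Ce) + Ru.
    Vectorized over s.
    """
    s = np.asarray(s, dtype=complex)
    if not np.all(np.isfinite(s)):
        raise ValueError("frequency s must be finite")
    z = (skin.RLead + params.Rs + skin.Ru
         + params.Rd / (1.0 + s * params.Rd * params.Cd)
         + skin.Re / (1.0 + s * skin.Re * skin.Ce))
    return z if z.ndim else complex(z)


def electrode_impedance_tf(params: ElectrodeParams, skin: SkinParams) -> RationalTF:
    """Z_E expressed as a rational function of s (two poles, two zeros)."""
    tau_d = np.array([params.Rd * params.Cd, 1.0])  # 1 + s Rd Cd
    tau_e = np.array([skin.Re * skin.Ce, 1.0])      # 1 + s Re Ce
    den = np.polymul(tau_d, tau_e)
    series = skin.RLead + params.Rs + skin.Ru
    num = np.polyadd(series * den,
                     np.polyadd(params.Rd * tau_e, skin.Re * tau_d))
    return RationalTF(num, den)


def impedance_mag_phase(params: ElectrodeParams, skin: SkinParams, f):
    """(|Z_E|, phase in degrees) at real frequency f >= 0 Hz.

    For this topology (series resistances plus two parallel RC branches) the
    phase lies in (-90, 0] degrees.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0):
        raise ValueError("frequency must be non-negative")
    z = electrode_impedance(params, skin, 2j * np.pi * f)
    return np.abs(z), np.degrees(np.angle(z))


def bandpass_tf(front: FrontEndParams) -> RationalTF:
    """Second-order band-pass with unity peak gain.

    H(s) = (w0/Q) s / (s^2 + (w0/Q) s + w0^2) with w0 = 2 pi sqrt(f_hp f_lp)
    and w0/Q = 2 pi (f_lp - f_hp); magnitude is exactly 1/sqrt(2) at both
    cutoff frequencies and 1 at the geometric-mean frequency.
    """
    if front.f_hp >= front.f_lp:
        raise ValueError("band-pass requires f_hp < f_lp")
    w0 = 2.0 * math.pi * math.sqrt(front.f_hp * front.f_lp)
    bw = 2.0 * math.pi * (front.f_lp - front.f_hp)
    return RationalTF([bw, 0.0], [1.0, bw, w0 * w0])


def notch_tf(front: FrontEndParams) -> RationalTF:
    """Second-order notch: zeros on the j-omega axis at the notch frequency.

    H(s) = (s^2 + wn^2) / (s^2 + (wn/Q) s + wn^2); unity at DC and far from
    the notch, exactly zero at f_notch.
    """
    wn = 2.0 * math.pi * front.f_notch
    return RationalTF([1.0, 0.0, wn * wn],
                      [1.0, wn / front.notch_q, wn * wn])


def divider_tf(params: ElectrodeParams, skin: SkinParams,
               front: FrontEndParams) -> RationalTF:
    """Input voltage divider (Ramp/2) / (Z_E(s) + Ramp/2) as a rational TF."""
    r = front.Ramp / 2.0
    ze = electrode_impedance_tf(params, skin)
    return RationalTF(r * ze.den, np.polyadd(ze.num, r * ze.den))


def system_tf(params: ElectrodeParams, skin: SkinParams,
              front: FrontEndParams) -> RationalTF:
    """Full acquisition-chain transfer function.

    H(s) = divider(s) * G * H_bpf(s) * H_notch(s), returned as one rational
    function (order 6: two divider poles, two band-pass poles, two notch
    poles). Evaluation agrees with the stage-by-stage product to rounding.
    """
    chain = divider_tf(params, skin, front) * bandpass_tf(front) * notch_tf(front)
    return chain.scale(front.gain_linear)
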