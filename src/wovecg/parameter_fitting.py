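"""Estimation of the electrode triple (Cd, Rd, Rs) from beat pairs.

For one electrode type the data are per-subject pairs (in-body beat,
measured beat). A candidate parameter set defines the chain H(s); the
in-body beat propagated through H is compared with the measured beat via a
max-normalized sum of squared residuals, accumulated over subjects:

    cost = sum_subjects sum_t ((V_meas(t) - V_sim(t)) / max|V_meas|)^2

Because every dataset's beat window is aligned on its own detected R peak,
the measured and simulated beats can differ by a pure nuisance time shift
(the divider stage delays the R peak by an electrode-dependent amount that
the adhesive reference chain does not share). The cost therefore removes a
single best cross-correlation shift (sub-sample, bounded) per subject before
computing the residual; this leaves |H| information untouched, so the
parameters remain identifiable. Set ``align="none"`` to compare on the raw
time base.

Optimization runs in log10 parameter space (positivity, decade-spanning
bounds) with a bounded quasi-Newton local minimizer from several log-uniform
multistart points; the best of all starts is returned and the whole
procedure is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft
from scipy.optimize import minimize

from .circuit_model import (ElectrodeParams, FrontEndParams, SkinParams,
                            system_tf)
from .errors import DegenerateModelError
from .spectral_propagation import DEFAULT_PAD_FACTOR, _padded_grid
from .waveform_processing import MeanBeat

__all__ = [
    "DEFAULT_BOUNDS",
    "SubjectPair",
    "FitProblem",
    "FitResult",
    "normalized_cost",
    "per_subject_costs",
    "fit_electrode",
    "predict_measured",
]

#: default fitting bounds (low, high) per parameter, SI units
DEFAULT_BOUNDS = {"Cd": (1e-11, 1e-4), "Rd": (1.0, 1e8), "Rs": (1.0, 1e8)}
#: cost returned when the model is degenerate at a bin frequency
PENALTY_COST = 1e12
#: largest nuisance shift removed by alignment, seconds
DEFAULT_MAX_SHIFT_S = 0.025


@dataclass(frozen=True)
class SubjectPair:
    """One subject's (in-body, measured) beat pair for a given electrode."""

    subject_id: object
    in_body: MeanBeat
    measured: MeanBeat

    def __post_init__(self):
        if self.in_body.fs != self.measured.fs:
            raise ValueError("in-body and measured beats must share fs")
        if self.in_body.waveform.size != self.measured.waveform.size:
            raise ValueError("in-body and measured beats must share length")


@dataclass
class FitProblem:
    """Inputs to one electrode fit."""

    pairs: list
    skin: SkinParams = field(default_factory=SkinParams)
    front: FrontEndParams = field(default_factory=FrontEndParams)
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    x0: ElectrodeParams | None = None
    pad_factor: int = DEFAULT_PAD_FACTOR
    align: str = "shift"
    max_shift_s: float = DEFAULT_MAX_SHIFT_S

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise ValueError("a fit needs at least one subject pair")
        fs0 = self.pairs[0].measured.fs
        n0 = self.pairs[0].measured.waveform.size
        for p in self.pairs:
            if p.measured.fs != fs0 or p.measured.waveform.size != n0:
                raise ValueError("all pairs must share fs and beat length")
        for name in ("Cd", "Rd", "Rs"):
            lo, hi = self.bounds[name]
            if not (0 < lo < hi and np.isfinite(hi)):
                raise ValueError(f"invalid bounds for {name}: {(lo, hi)}")
        if self.align not in ("shift", "none"):
            raise ValueError("align must be 'shift' or 'none'")
        self._engine = None

    def engine(self) -> "_CostEngine":
        if self._engine is None:
            self._engine = _CostEngine(self)
        return self._engine


@dataclass
class FitResult:
    """Fitted parameters with their cost and convergence metadata."""

    params: ElectrodeParams
    total_cost: float
    per_subject_cost: list
    n_evaluations: int
    converged: bool
    n_starts: int = 1


def _best_shift(corr: np.ndarray, max_shift_n: int) -> float:
    """Lag (samples, signed, sub-sample) maximizing a circular correlation
    array (lag l at index l mod len), searched globally within the allowed
    window with parabolic vertex refinement."""
    n_c = corr.size
    lags = np.arange(-max_shift_n, max_shift_n + 1)
    k = int(np.argmax(corr[lags % n_c]))
    lag0 = int(lags[k])
    c0 = corr[lag0 % n_c]
    cm = corr[(lag0 - 1) % n_c]
    cp = corr[(lag0 + 1) % n_c]
    denom = cm + cp - 2.0 * c0
    if denom < 0.0:  # proper maximum; refine the vertex
        return lag0 + float(np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0))
    return float(lag0)


class _CostEngine:
    """Precomputed spectra and frequency grid for fast repeated cost calls."""

    def __init__(self, problem: FitProblem):
        self.problem = problem
        beat0 = problem.pairs[0].measured
        self.n = beat0.waveform.size
        self.fs = beat0.fs
        self.n_fft, self.freqs = _padded_grid(self.n, self.fs,
                                              problem.pad_factor)
        self.s = 2j * np.pi * self.freqs
        self.max_shift_n = max(1, round(problem.max_shift_s * self.fs))
        self.x_in = [rfft(p.in_body.waveform, self.n_fft)
                     for p in problem.pairs]
        # preceding-beat ringing factor of each measured dataset's average
        from .spectral_propagation import spill_factor
        self.spill = [spill_factor(self.freqs, p.measured.rr_s,
                                   p.measured.rr2_s)
                      for p in problem.pairs]
        self.v_meas = [p.measured.waveform for p in problem.pairs]
        self.norm = [float(np.max(np.abs(v))) for v in self.v_meas]
        for nrm in self.norm:
            if nrm == 0.0:
                raise ValueError("a measured beat is identically zero")
        # small FFT grid for linear cross-correlation: exact for lags up to
        # (n_corr - n), comfortably covering the allowed shift window
        from scipy.fft import next_fast_len
        self.n_corr = next_fast_len(self.n + 4 * self.max_shift_n)
        self.m_corr = [rfft(v, self.n_corr) for v in self.v_meas]
        # phase-ramp cache (speed only; values depend just on the lag)
        self._ramp = [None] * len(self.v_meas)
        # stacked copies for the batched cost path (one 2-D FFT per stage
        # instead of one FFT per subject)
        self.x_in_mat = np.vstack(self.x_in)
        self.spill_mat = np.vstack([np.broadcast_to(sp, self.freqs.shape)
                                    for sp in self.spill])
        self.v_meas_mat = np.vstack(self.v_meas)
        self.m_corr_mat = np.vstack(self.m_corr)
        self.norm_arr = np.asarray(self.norm)
        # response fast path: the band-pass, notch and gain do not depend on
        # the fitted triple, so their response is a fixed array; only the
        # divider R/(Z_E + R) is recomputed per candidate (algebraically
        # identical to evaluating the full rational cascade)
        from .circuit_model import bandpass_tf, notch_tf
        front, skin = problem.front, problem.skin
        self._fixed_resp = (front.gain_linear
                            * bandpass_tf(front).freq_response(self.freqs)
                            * notch_tf(front).freq_response(self.freqs))
        self._skin_branch = (skin.RLead + skin.Ru
                             + skin.Re / (1.0 + self.s * skin.Re * skin.Ce))
        self._r_half = front.Ramp / 2.0

    def _shift_spec(self, spec, i, total):
        if total == 0.0:
            return spec
        cached = self._ramp[i]
        if cached is None or cached[0] != total:
            ramp = np.exp(-2j * np.pi * self.freqs * (total / self.fs))
            self._ramp[i] = (total, ramp)
        else:
            ramp = cached[1]
        return spec * ramp

    def _response(self, params: ElectrodeParams) -> np.ndarray:
        z_e = (self._skin_branch + params.Rs
               + params.Rd / (1.0 + self.s * params.Rd * params.Cd))
        return self._fixed_resp * self._r_half / (z_e + self._r_half)

    def simulate(self, params: ElectrodeParams, i: int,
                 h: np.ndarray | None = None,
                 lag: float | None = None):
        """Simulated measured beat for pair i, alignment included.

        Returns (waveform, lag). When ``lag`` is given the alignment search
        is skipped and that shift is applied directly.
        """
        if h is None:
            h = self._response(params)
        spec = self.x_in[i] * h * self.spill[i]
        if self.problem.align != "shift":
            return irfft(spec, self.n_fft)[: self.n], 0.0
        if lag is not None:
            return irfft(self._shift_spec(spec, i, lag),
                         self.n_fft)[: self.n], lag
        # Align the cropped simulation (what the residual sees, not the
        # padded block with its ringing tail) against the data, searching
        # all allowed lags every time (a local search can trap the
        # optimizer, and any carried-over state would make the cost
        # history-dependent). The crop itself slightly skews the
        # correlation vertex, so refine: after shifting, the re-cropped
        # simulation carries the right window content and the residual
        # lag -> 0.
        total = 0.0
        v_sim = None
        for _ in range(4):
            v_sim = irfft(self._shift_spec(spec, i, total),
                          self.n_fft)[: self.n]
            corr = irfft(self.m_corr[i] * np.conj(rfft(v_sim, self.n_corr)),
                         self.n_corr)
            step = _best_shift(corr, self.max_shift_n)
            if abs(step) < 1e-2:
                break
            total = float(np.clip(total + step, -self.max_shift_n,
                                  self.max_shift_n))
        return v_sim, total

    def subject_costs(self, params: ElectrodeParams,
                      lags=None) -> np.ndarray:
        costs, _ = self.subject_costs_lags(params, lags=lags)
        return costs

    def subject_costs_lags(self, params: ElectrodeParams, lags=None):
        """Batched per-subject costs; same alignment semantics as
        :meth:`simulate` but with one 2-D FFT per stage across subjects."""
        h = self._response(params)
        spec = self.x_in_mat * h[None, :] * self.spill_mat
        n_pairs = spec.shape[0]
        if self.problem.align != "shift":
            v = irfft(spec, self.n_fft, axis=1)[:, : self.n]
            totals = np.zeros(n_pairs)
        else:
            totals = (np.zeros(n_pairs) if lags is None
                      else np.asarray(lags, dtype=float))
            v = None
            for it in range(4):
                if np.all(totals == 0.0):
                    shifted = spec
                else:
                    ramp = np.exp(-2j * np.pi * self.freqs[None, :]
                                  * (totals[:, None] / self.fs))
                    shifted = spec * ramp
                v = irfft(shifted, self.n_fft, axis=1)[:, : self.n]
                if lags is not None:
                    break
                corr = irfft(self.m_corr_mat
                             * np.conj(rfft(v, self.n_corr, axis=1)),
                             self.n_corr, axis=1)
                steps = np.array([_best_shift(corr[i], self.max_shift_n)
                                  for i in range(n_pairs)])
                if np.max(np.abs(steps)) < 1e-2:
                    break
                totals = np.clip(totals + steps, -self.max_shift_n,
                                 self.max_shift_n)
        r = (self.v_meas_mat - v) / self.norm_arr[:, None]
        return np.einsum("ij,ij->i", r, r), list(totals)


def per_subject_costs(params: ElectrodeParams, problem: FitProblem) -> np.ndarray:
    """Normalized cost contribution of each subject (see module docstring)."""
    return problem.engine().subject_costs(params)


def normalized_cost(params: ElectrodeParams, problem: FitProblem) -> float:
    """Total cross-subject normalized cost; finite penalty on a degenerate
    model so an optimizer can step away from it."""
    try:
        return float(np.sum(per_subject_costs(params, problem)))
    except DegenerateModelError:
        return PENALTY_COST


def fit_electrode(problem: FitProblem, n_starts: int = 6, seed: int = 0,
                  max_evals: int = 2000, ftol: float = 1e-10) -> FitResult:
    """Best-of-``n_starts`` bounded local minimization in log10 space.

    Start points: the problem's initial guess (or the geometric midpoint of
    the bounds) plus log-uniform draws from a generator seeded with ``seed``.
    Deterministic given (problem, seed). ``converged`` is False only when no
    start improved on the best initial cost.
    """
    engine = problem.engine()
    lo = np.log10([problem.bounds[k][0] for k in ("Cd", "Rd", "Rs")])
    hi = np.log10([problem.bounds[k][1] for k in ("Cd", "Rd", "Rs")])

    n_calls = 0

    def objective(u):
        nonlocal n_calls
        n_calls += 1
        try:
            params = ElectrodeParams(*(10.0 ** u))
            cost = float(np.sum(engine.subject_costs(params)))
        except DegenerateModelError:
            return PENALTY_COST
        return cost if np.isfinite(cost) else PENALTY_COST


    # coarse log-grid prescan: the cost basin around the Rd*Cd corner is
    # narrow in decade-spanning bounds, so descending from the best few grid
    # nodes is far more reliable than random restarts alone
    grid_axes = [np.linspace(a, b, 8)[1:-1] for a, b in zip(lo, hi)]
    nodes = []
    for u_cd in grid_axes[0]:
        for u_rd in grid_axes[1]:
            for u_rs in grid_axes[2]:
                u = np.array([u_cd, u_rd, u_rs])
                nodes.append((objective(u), tuple(u)))
    nodes.sort(key=lambda item: item[0])
    seeded = [] if problem.x0 is None else [np.log10(problem.x0.as_array())]
    seeded += [np.array(u) for _, u in nodes[:3]]
    rng = np.random.default_rng(seed)
    starts = seeded[:n_starts]
    starts += [rng.uniform(lo, hi) for _ in range(n_starts - len(starts))]
    u_first = starts[0]

    f_init = objective(np.clip(u_first, lo, hi))
    best_u, best_f, any_success = np.clip(u_first, lo, hi), f_init, False
    for u0 in starts:
        res = minimize(objective, np.clip(u0, lo, hi), method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options={"maxfun": max_evals, "ftol": ftol})
        if res.fun < best_f:
            best_f, best_u = float(res.fun), np.asarray(res.x)
            any_success = True

    params = ElectrodeParams(*(10.0 ** best_u))
    costs = engine.subject_costs(params)
    return FitResult(params=params, total_cost=float(np.sum(costs)),
                     per_subject_cost=[float(c) for c in costs],
                     n_evaluations=n_calls,
                     converged=bool(any_success or best_f <= f_init),
                     n_starts=n_starts)


def predict_measured(params: ElectrodeParams, in_body: MeanBeat,
                     skin: SkinParams, front: FrontEndParams,
                     measured: MeanBeat | None = None,
                     pad_factor: int = DEFAULT_PAD_FACTOR,
                     align: str = "shift",
                     max_shift_s: float = DEFAULT_MAX_SHIFT_S) -> MeanBeat:
    """Simulate the measured beat for one subject under ``params``.

    When ``measured`` is given and ``align="shift"``, the nuisance time shift
    is removed exactly as in the fitting cost (used by cross-validation so
    the reported error matches what the fit minimized).
    """
    from dataclasses import replace

    if measured is None or align == "none":
        tf = system_tf(params, skin, front)
        from .spectral_propagation import apply_tf
        return apply_tf(in_body, tf, pad_factor=pad_factor)
    pair = SubjectPair(subject_id=in_body.subject_id, in_body=in_body,
                       measured=measured)
    problem = FitProblem(pairs=[pair], skin=skin, front=front,
                         pad_factor=pad_factor, align=align,
                         max_shift_s=max_shift_s)
    v_sim, _ = problem.engine().simulate(params, 0)
    return replace(in_body, waveform=v_sim)
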