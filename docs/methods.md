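# Methods

`wovecg` characterizes woven textile ECG electrodes by fitting the unknown
parameters of a skin–electrode equivalent circuit to single-lead ECG
recordings. This note describes the model, the estimation procedure, the
synthetic data the package validates itself against, and the numerical
choices a maintainer would want to know about.

## The measurement model

### Skin–electrode interface

The interface follows the classical double-time-constant model: two parallel
RC stages in series with ohmic terms,

    Z_E(s) = R_lead + Rd / (1 + s·Rd·Cd) + Rs + Re / (1 + s·Re·Ce) + Ru

- `Cd`, `Rd` — electrode–electrolyte interface capacitance and
  charge-transfer resistance. For a dry textile electrode the "electrolyte"
  is the thin perspiration layer that accumulates after a few minutes of
  wear.
- `Rs` — electrolyte (perspiration-layer) series resistance; for textile
  electrodes this term also absorbs contact-pressure and moisture effects.
- `Ce`, `Re`, `Ru`, `R_lead` — epidermis capacitance/resistance, deep-tissue
  resistance and lead-wire resistance. These skin terms are treated as known
  constants, identical across subjects (defaults: `Ce = 0.9 µF`,
  `Re = 35.2 kΩ`, `Ru = 2.6 kΩ`, `R_lead = 10 Ω`). The unit of the `Re`
  figure in the source catalogue is ambiguous between Ω and kΩ; the package
  defaults to kΩ and exposes the value in the configuration rather than
  asserting it as ground truth.

The triple `(Cd, Rd, Rs)` is specific to an electrode type and is what the
package estimates.

### Acquisition chain

The recording front end is modelled as ideal second-order stages:

    H(s) = (Ramp/2) / (Z_E(s) + Ramp/2) · G · H_bpf(s) · H_notch(s)

- Input divider: each differential input loads its electrode with half the
  amplifier input impedance (`Ramp = 2 MΩ`); the two electrodes are assumed
  identical, so a single branch suffices.
- Gain: flat, `G = 10^(gain_db/20)` with 66 dB default.
- Band-pass: `H(s) = (ω₀/Q)s / (s² + (ω₀/Q)s + ω₀²)` with
  `ω₀ = 2π√(f_hp·f_lp)` and `ω₀/Q = 2π(f_lp − f_hp)` — the canonical
  second-order band-pass with unity peak gain and exactly −3 dB at the 1 Hz
  and 35 Hz cutoffs.
- Notch: `H(s) = (s² + ωₙ²) / (s² + (ωₙ/Q)s + ωₙ²)` at 60 Hz. The notch
  width is not published for the modelled hardware; the default `Q = 30`
  ("narrow band") is configuration-exposed.

A literal cascade of the divider (two poles from `Z_E`), band-pass and notch
is order six. The implementation keeps the full-order rational function; a
second-order print of the same chain can only be a display simplification,
and collapsing it would change the response.

## The analysis pipeline

1. **R-peak detection** — refractory-spaced local maxima
   (`scipy.signal.find_peaks`) with a self-scaling prominence floor: half
   the 80th percentile of candidate prominences. The R cluster occupies
   roughly the upper half of refractory-spaced candidates, so this floor
   falls in the gap between R peaks and lesser deflections (filtered T
   waves, noise) across electrode gains, and a percentile is robust to
   occasional artifact-scaled beats.
2. **Outlier-beat rejection** — a beat is dropped when its R amplitude or
   its preceding RR interval deviates from the median by more than 3 scaled
   median absolute deviations (the conventional robust default). Beats
   immediately following a rejected beat are also excluded from averaging:
   the artifact's ringing reaches into their window.
3. **Screening** — a dataset is excluded when its SNR is below 0 dB or
   fewer than 30 R peaks were detected. SNR is defined by template
   reconstruction: the mean beat tiled at the retained peaks, with signal
   and residual power evaluated over the samples the beat windows cover.
   (A sinusoid-referenced SNR is meaningless for a repetitive beat; the
   0 dB threshold semantics are preserved.)
4. **Beat averaging** — integer-sample alignment on the detected R index,
   default window 0.25 s before to 0.45 s after the R peak (covers PQRST at
   resting rates). The preceding one- and two-beat RR intervals of each
   averaged beat are kept as metadata (see *spill factor* below).
5. **In-body recovery** — the adhesive gel electrode's circuit parameters
   are known, so inverting its chain on the adhesive mean beat yields the
   subject's "in-body" waveform, used as the common input for all woven
   electrodes of that subject. Because the adhesive parameters are known
   *from the literature* rather than printed alongside the skin constants,
   the defaults (`Cd = 4.7 µF`, `Rd = 12 kΩ`, `Rs = 150 Ω`, typical wet
   Ag/AgCl values) are configuration entries, not asserted constants.
6. **Fitting** — for each woven electrode type, the cross-subject
   normalized cost

       cost = Σ_subjects Σ_t ((V_meas(t) − V_sim(t)) / max|V_meas|)²

   is minimized over `(Cd, Rd, Rs)`, where `V_sim` is the subject's in-body
   beat propagated through the candidate chain. One set of parameters is
   fitted per electrode type across all subjects.
7. **Validation** — leave-one-subject-out: refit without one subject,
   simulate that subject's beat through the refitted chain, record the RMSE
   `√(Σ(V_meas − V_sim)²/n)`, and average the folds per electrode type.

## Numerical design choices

**Spectral propagation.** Beats are short finite windows; applying or
undoing H is done bin-wise on the real FFT at the continuous bin
frequencies `H(j2πf_k)` (the Laplace-domain model evaluated directly, not a
discretized filter). Beats are zero-padded (default 4×) so the impulse
response tail decays inside the block and the circular product approximates
linear convolution; `pad_factor=1` is pure circular convolution at the beat
length, which is exactly invertible and is the mode the round-trip property
uses. Inversion is Tikhonov-guarded,
`Vin = Vout·conj(H)/(|H|² + (ε·max|H|)²)` with `ε = 10⁻⁴` by default,
because the band-pass and notch have true zeros where bare division is
undefined; with 1–35 Hz content the in-band effect is negligible.

**Spill factor.** A beat average cut from a filtered beat train is *not*
the response to an isolated beat: the chain's slowest pole (from the 1 Hz
high-pass corner, ≈ 0.15 s time constant) rings across the RR gap, so each
window carries the previous beat's decaying tail. For identical beats at
recorded intervals the averaged window equals the isolated-beat response
multiplied, in the frequency domain, by

    S(f) = 1 + mean_k e^{+j2πf·RR_k}  (+ the analogous two-beats-back term)

with `RR_k` the preceding intervals of the averaged beats. All forward
simulation against measured averages, and the in-body recovery, include
this factor; without it the model error floor sits at ~1% of the beat peak
and parameter recovery degrades by an order of magnitude.

**In-body recovery as windowed deconvolution.** The forward map from a
windowed in-body beat to a windowed measurement is convolution *followed by
cropping*, so its inverse is not bin-wise division (cropping couples the
bins, and the spill factor has interference nulls at odd multiples of
1/(2·RR) where division explodes into long narrowband components that
cannot belong to one beat). The recovery instead solves the damped
least-squares problem

    min_r ‖Crop(h_eff ∗ Embed(r)) − m‖² + (λ·max|H|)²‖r‖²,  λ = 10⁻³

matrix-free with LSMR (FFT-based operator and adjoint). The damping
suppresses the genuinely unobservable directions (DC of the AC-coupled
chain, the notch band) instead of amplifying them. Recovery of a known
beat through the adhesive chain is exact to ~10⁻⁶ relative in the
observable subspace.

On noisy data the recovered in-body beat is a noisy *regressor* for the
downstream fit, and regressor noise biases least-squares estimates
(errors-in-variables) — most visibly for electrodes whose cost valley is
nearly flat. The recovery therefore adds a curvature penalty λ²‖D²r‖²
(second differences) calibrated by the Morozov discrepancy principle: the
beat average's noise level is estimated from the between-beat variance
(σ/√N), and the largest λ whose reconstruction residual still sits at that
noise level is selected. The cardiac beat is smooth, so the curvature
penalty leaves its content essentially unbiased (a uniform ‖r‖² damping at
the same strength would shrink the low-frequency content that the
lowest-impedance electrodes are identified from) while strongly
suppressing jagged noise. Noiseless averages keep only the floor damping
and are reproduced essentially exactly.

**Alignment in the cost.** Every dataset's window is aligned on its own
detected R peak, and the divider delays the R peak by an
electrode-dependent amount that the adhesive reference chain does not
share. Measured and simulated beats therefore differ by a pure nuisance
time shift even at the true parameters. The cost removes one best
cross-correlation shift per subject (sub-sample, parabolic-vertex refined,
bounded to ±25 ms) before the residual. The search is global within the
bound at every evaluation — a warm-started local search makes the cost
history-dependent and traps the optimizer — and is iterated a few times
because cropping skews the correlation vertex slightly; the residual lag
converges below 0.01 samples. A pure delay leaves |H| untouched, so
parameter identifiability is not affected. Leave-one-out RMSE is computed
after the same alignment, matching what the fit minimized.

**Optimization.** Parameters are fitted in log10 space (positivity,
decade-spanning bounds; defaults `Cd ∈ [10 pF, 100 µF]`,
`Rd, Rs ∈ [1 Ω, 100 MΩ]`). The basin around the `Rd·Cd` corner is narrow
inside such bounds, so a coarse 6×6×6 log-grid prescan is evaluated first
and the three best nodes seed bounded L-BFGS-B runs, topped up with
log-uniform random starts from the given seed to 6 starts total; the best
result is returned. Convergence: relative cost improvement below 10⁻¹⁰ or
2000 evaluations per start. The whole procedure is deterministic given the
seed. Leave-one-out folds reuse the same settings with the seed offset by a
stable hash of the held-out subject's identity, so results do not depend on
subject ordering.

## The synthetic-data generator

The generator emulates the study design the analysis targets: 6 seated
subjects, ~2 minutes of single-lead ECG per (subject, electrode) pair at
2 kHz, 16 woven electrode types plus one adhesive reference.

- **In-body beat**: a per-subject sum of five Gaussians (P, Q, R, S, T)
  with amplitudes jittered ±20%, timings by a few ms and widths ±10% around
  a nominal resting beat (R ≈ 1 mV, P–R interval 160 ms, T ending ≈ 0.42 s
  after R). The component supports lie inside the averaging window, as the
  window definition requires. The beat is constant within a subject across
  electrode types.
- **Beat train**: beats tiled at jittered RR intervals (65 bpm nominal, 3%
  per-beat jitter), ground-truth R times retained.
- **Measurement**: the train propagated through the full chain for the
  electrode's true parameters (single zero-padded FFT block with the same
  continuous-frequency evaluation as the analysis), then occasional outlier
  beats (rate 2%, single beats scaled ×3–10 after the chain, emulating
  artifacts the screening stage should remove), then additive white
  Gaussian noise at a specified SNR relative to the chain-output power
  (default 20 dB; `None` for noiseless studies). Noise after the chain
  models sensor/amplifier noise.
- **Default truth table**: ids 1–8 follow the catalogue's area sweep with
  `Cd ∝ area`, `Rd ∝ 1/area`, `Rs ∝ 1/area` (parallel-plate and
  volume-conduction scaling; corner ≈ 2.7 Hz at every size). Ids 9–16 span
  `Cd ∈ [10 nF, 2 µF]` with corner frequencies log-spaced 15 → 3 Hz
  (larger capacitances paired with lower corners) and `Rs/Rd` ratios in
  [0.3, 3]. Two considerations drove this design: the `Rd·Cd` corner must
  lie inside the 1–35 Hz pass-band for all three parameters to leave a
  signature in the recorded band, and `|Z_E|` must sit in the
  hundreds-of-kΩ regime of real dry textile electrodes — an electrode whose
  impedance is negligible against the 1 MΩ divider is physically an ideal
  wire and its internal Rd/Rs split is not identifiable from voltage data
  in principle.

What the generator does *not* emulate: motion artifacts, baseline wander
and respiration, electrode polarization drift, skin-parameter variability
across subjects, and any beat-morphology change over time. Passing the
synthetic acceptance suite therefore demonstrates that the estimation
machinery is correct and well-conditioned under the stated model, not that
the model captures every property of ambulatory recordings.

## Problem sizes and expected accuracy

The validation suite runs the full six-subject study (102 recordings of
120 s at 2 kHz) noiselessly, ten further studies at 20 dB SNR, and
leave-one-out validation of all 16 electrode types. On the noiseless study
every fitted parameter lands within 5% of truth (typically within 0.1%);
at 20 dB SNR the per-parameter median error over ten studies stays within
20% (typically a few percent); leave-one-out mean RMSE stays below 10⁻⁴ of
the beat peak on noiseless data. Known limitation: electrodes whose corner
frequency approaches the band edges, or whose impedance is small against
the divider, lose identifiability gracefully — the resistance *sum* and
the corner remain recoverable where the individual factors are not (this
degradation is itself covered by a test).
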