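# Methods

This note documents the models, numerical choices and known limitations of
`soundpursuit`, in the order the pipeline runs.

## Stimulus model

A pursuit stimulus is a sum of five sines at integer multiples
p = [2, 3, 7, 13, 21] of a fundamental f₀ = 0.05 Hz whose period equals the
trial length (20 s), so the motion has a fixed, covert spectrum but is
unpredictable in the time domain once the per-trial phases are drawn uniformly
on [0, 2π). Each realisation is rescaled so its sampled peak is exactly 30°;
the realised per-harmonic amplitudes (identical across harmonics, varying
across trials) are recorded in the trace metadata. The 110 Hz sample rate is
chosen so a 20-s trial holds 2200 samples. Because the harmonics share one
fundamental spanning the trial, every harmonic lands on an exact DFT bin —
this is what makes the later FFT gain/phase extraction leakage-free.

The robot arm that physically carries the loudspeaker does not reproduce the
command perfectly. Its input–output transformation is emulated as (i) additive
sinusoids at extra multiples [1, 5, 15] of the fundamental, each at 3 % of the
command peak with random phases, and (ii) a first-order low-pass (default
corner 5 Hz, required to sit above the 1.05 Hz stimulus band) applied in the
frequency domain as a steady-state filter of the periodic trace. The distorted
("motor") trace is what all downstream stages treat as the true stimulus; its
realised peak is re-measured and reported, not re-normalised to 30°.

## Synthetic subjects

A synthetic subject is literally the second-order-plus-delay model: head
position is the discrete convolution of the motor trace with the subject's
impulse response, plus i.i.d. Gaussian measurement noise on position. Defaults
define the study conditions:

| parameter | default | meaning |
|---|---|---|
| f_C | 0.6 Hz | resonance frequency, fixed per subject |
| T_D | U(10, 98) ms | sensorimotor delay, fixed per subject |
| Q | 1.5 → 0.6, linear in trial | session-long adaptive damping drift |
| jitter | lognormal, sd 0.15 (log units) | trial-to-trial Q scatter |
| noise | 1° SD | additive measurement noise (coil resolution is ~0.1°; 1° is of the order of the residuals the model leaves on real traces) |

The convolution takes the stimulus as zero before onset (subjects start at
straight-ahead rest), so every trial carries a startup transient that decays
at rate ζω_C — exactly as a real first-sounding trial would. Passing
`warmup_periods=1` to `simulate_trial` instead prepends one period of the
periodic stimulus and discards it, yielding the settled (steady-state)
response; this is used to verify the frequency/time-domain equivalence of the
implementation without the transient (see below). Fractional-sample delays
need no rounding anywhere: the convolution kernel is sampled from the analytic
delay-shifted impulse response h(t − T_D). No head saccades are generated —
the behaviour being emulated contains none during pursuit.

What the generator does **not** emulate: gain nonlinearity or asymmetry,
non-stationary noise, drifts of the delay, or any deviation of the head plant
from the LTI model. Consequences for interpreting green tests are noted under
*Limitations*.

## Impulse response and normalisation

The second-order filter's impulse response is implemented in its unit-DC-gain
form: (ω_C/β)·e^(−ζω_C t)·sin(βω_C t) for ζ < 1 (β = √(1−ζ²)), the analogous
difference of exponentials with prefactor ω_C/(2γ) for ζ > 1 (γ = √(ζ²−1)),
and the analytic limit ω_C²·t·e^(−ω_C t) at critical damping (used within
|ζ−1| < 10⁻⁶ to avoid cancellation). With these prefactors ∫h dt = G0 and the
closed form ∫h² dt = ω_C/(4ζ) holds for underdamped systems, which is what
fixes the energy values E₁.₅(1.8 s) = 2.79 and E₀.₆(1.8 s) = 1.13 at
f_C = 0.6 Hz. A prefactor of T_C/β instead of ω_C/β (sometimes seen in print)
is dimensionally inconsistent with both properties.

The gain characteristic |H(iω)| has an interior maximum only for
ζ < 1/√2 (Q > 1/√2), at ω_max = ω_C√(1−2ζ²) with height 1/(2ζ√(1−ζ²));
otherwise the maximum is the DC gain at ω = 0. `peak_gain` returns this true
argmax (verified against dense grid search in the tests). Note that the
damped natural frequency ω_C√(1−ζ²) — where the *impulse response* rings — is
not the gain peak; evaluating |H| there understates the maximum (at Q = 1.5:
1.567 at 0.943 ω_C versus the true 1.591 at 0.882 ω_C).

Quadratures (kinetic energy, band-averaged gain) use a uniform trapezoid rule
with automatic grid halving until the result changes by < 0.1 % — simple,
deterministic and ample for smooth exponentially damped integrands. Energy and
effort are computed with T_D = 0: a pure delay only shifts the velocity
profile and, for windows much longer than the delay, leaves the integrals
unchanged.

## Discrete convolution

Predictions use FFT convolution of the stimulus with the sampled kernel
h(t_k − T_D)·dt, corrected by the trapezoid-rule end terms (with h(0) = 0 only
the onset-sample term −½·dt·h(t_n)·m(0) survives). This makes the discrete
convolution second-order accurate in dt; convolving a unit step reproduces the
analytic step response to machine precision on the same grid, and the DC gain
of the discrete operator matches the trapezoid integral of h. The kernel
length equals the trace length — samples beyond it can never influence the
returned window.

## Per-trial identification

The two free parameters (f_C, ζ) are fitted per trial by minimising the
time-domain MSE between the measured head trace and the model prediction,
with the subject delay clamped and G0 = 1:

1. **Coarse grid** — 40 × 40 log-spaced candidates over f_C ∈ [0.1, 3] Hz and
   ζ ∈ [0.05, 4] (generous around the empirical operating point f_C ≈ 0.6 Hz,
   ζ ≈ 0.33–0.83). For a whole session the candidate-kernel FFTs are computed
   once per subject, so scoring a trial is one batched spectral multiply and
   inverse FFT.
2. **Refinement** — Nelder–Mead on (log f_C, log ζ) from the grid argmin
   (xatol 10⁻⁴ in log units, i.e. ~0.01 % parameter resolution).

A solution pinned at the search boundary is flagged (`at_boundary`), never
silently returned. Ties anywhere break toward the smaller parameter value. On
noise-free synthetic trials this recovers (f_C, ζ) to ≪ 1 % with r² > 0.999;
the explicit grid + simplex scheme was chosen over an opaque process-estimation
routine so the behaviour is fully specified and testable.

**Subject delay.** T_D is estimated by brute force on a 0–200 ms grid in 2 ms
steps (bracketing the plausible 10–98 ms range with margin): each candidate
delay is scored by fitting every trial with the candidate clamped and summing
the minimal MSEs. For speed the scan runs in two stages — a 10 ms sweep using
coarse-grid-only fits, with the candidate delay applied to the precomputed
zero-delay kernel spectra as a pure phase ramp (exact for a time shift of the
decaying kernel), then the full 2 ms resolution with simplex-refined fits in a
±12 ms window around the coarse optimum. The refinement stage matters: with
grid-only inner fits, parameter quantisation lets neighbouring delays
compensate and biases the argmin by up to ~10 ms; with refinement the
noise-free recovery is exact to the grid step.

**Harmonic transfer.** Gain and phase at the five stimulus harmonics are the
DFT ratios R(f_k)/M(f_k) of head over motor trace at the exact harmonic bins,
phase wrapped to (−360°, 0] so lags up to one cycle read as negative phase.
Harmonics with stimulus power below 10⁻⁶ of the strongest are flagged
unusable. On a *settled* noise-free response this extraction equals the
analytic transfer function to ~0.01 %; on an onset-at-rest trial the startup
transient leaks a few percent into the harmonic bins (it is broadband and not
orthogonal to them) — an inherent property of single-period trials, present in
real recordings as well, not an implementation error.

## Pursuit-error metrics

The delay-optimised mean absolute error advances the head trace by every
candidate lead on the sample grid within a search window (default 0–600 ms,
covering the few-hundred-ms optimal delays these responses show), trims both
traces to the overlap, and keeps the lead minimising the mean absolute
difference — the mean is taken over the valid overlapping samples so shorter
trials are handled uniformly. Velocities are central differences after a
zero-phase 4th-order Butterworth low-pass at 5 Hz (well above the 1.05 Hz
stimulus band, well below the 55 Hz Nyquist frequency; the method is a
package choice — any zero-phase scheme with a cutoff in that window gives the
same regressions). The dissociation analysis pools every 15th aligned sample
across trials and regresses each response variable (head position, head
velocity) on each error (position error, velocity error) by OLS.

## Hierarchical trend inference

A per-trial quantity y (fitted Q, f_C, or effort) is regressed on trial
number n with subject-level intercepts and slopes:

y_{s,n} ~ Normal(a_s + b_s n, σ),  a_s ~ Normal(μ_a, τ_a),  b_s ~ Normal(μ_b, τ_b)

with weakly informative priors on standardized data — μ ~ Normal(0, 10²),
τ and σ ~ Half-Normal(0, 5²) — and results back-transformed to original
units. Because the model is linear-Gaussian, the subject effects are
integrated out analytically (per-subject marginal likelihood
y_s ~ N(X_s μ, σ²I + X_s T X_sᵀ), computed from 2 × 2 sufficient statistics),
so the ensemble sampler (emcee, 40 walkers, default 1500 post-burn-in steps
after an equal burn-in) explores only the five hyperparameters. This
marginalisation is what makes the sampler reliable here: the 27-dimensional
centred parameterisation has a funnel geometry that the affine-invariant
ensemble does not traverse. Subject-level slopes/intercepts are reported as
conditional posterior means averaged over thinned draws.

Convergence is monitored by split-R̂ computed over 8 pooled walker groups
(walkers are exchangeable members of one ensemble, not independent chains;
grouping denoises the diagnostic while still detecting drift); a fit with
max R̂ ≥ 1.05 is flagged `converged=False` and warned about, never silently
accepted. The 95 % HDI is the narrowest interval containing 95 % of the pooled
posterior draws. The group-slope HDI excluding zero is the criterion for a
systematic trend. Note the HDI estimates the *posterior* interval: more MCMC
draws reduce its Monte Carlo error but do not shrink the interval itself.

## Problem sizes used in the test suite

The default study scale is 11 subjects × 30 trials × 2200 samples. The
parameter-recovery acceptance check runs 5 seeded replicates at that full
scale; unit and property tests use shorter sessions (3–8 trials) chosen so
that the whole suite completes in a few minutes on a single core while still
exercising every code path at the study's trial length and sample rate.

## Limitations

* The synthetic subjects are exactly the LTI model being fitted, so
  identification tests demonstrate *consistency* (the pipeline is a fixed
  point on its own model class), not robustness to plant misspecification.
* After optimal alignment, a model-faithful subject's position error is
  dominated by measurement noise. The dissociation analysis therefore
  reproduces the *uncorrelatedness* of position and velocity errors, but the
  strong own-correlations seen in real data (where heads undershoot and
  deviate from any LTI description) do not emerge from this generator: the
  pooled head-position–on–position-error correlation is ≈ 0.06 and the
  velocity one ≈ 0.28 under the default conditions. Reproducing those
  magnitudes would require a generator with structured (non-LTI) response
  components, which is out of scope.
* The motor-distortion transformation is a stylised stand-in (additive
  harmonics + first-order smoothing); the real robot arm's nonlinearity is
  not characterised beyond the spectral signatures it leaves.
* `static_localization_regression` implements the baseline stimulus–response
  validation gate for imported recordings; the synthetic pipeline has no
  elevation channel to feed it.
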