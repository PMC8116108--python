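# soundpursuit

Analysis pipeline for **head pursuit of unpredictably moving sounds**: humans
track a sound source that moves along a pseudo-random horizontal trajectory,
and the smooth head movements they produce can be described — trial by trial —
by a second-order low-pass filter in series with a fixed sensorimotor delay.
The package implements the whole analysis chain for that paradigm, driven by a
synthetic-subject simulator in place of laboratory recordings:

* **Stimuli** — sum-of-sines trajectories (harmonics [2, 3, 7, 13, 21] of a
  0.05 Hz fundamental, random phases, normalised to a 30° peak over a 20-s
  trial sampled at 110 Hz), plus an emulation of the robot-arm distortion that
  adds small extra harmonics and low-pass smoothing.
* **Synthetic subjects** — second-order-plus-delay responders with a fixed
  idiosyncratic delay (10–98 ms), fixed resonance frequency near 0.6 Hz, and a
  quality factor that drifts across the session from ~1.5 (underdamped) toward
  ~0.6 (near-critically damped), observed through ~1° of measurement noise.
* **System identification** — per-trial estimation of the model, FFT-based
  gain/phase at the stimulus harmonics, convolution predictions, r²/MSE, and
  brute-force estimation of each subject's delay.
* **Pursuit metrics** — delay-optimised mean absolute error (MAE), and the
  position-error vs velocity-error dissociation regressions.
* **Trend inference** — hierarchical Bayesian regression of the fitted
  parameters against trial number (group and subject slopes with 95% highest
  density intervals), plus movement-effort trends.

It is intended for researchers in auditory psychophysics and sensorimotor
control who want a tested, reproducible reference implementation of this
analysis — or a parameter-recovery harness to power-check an experiment design
before collecting data.

## The model

Each trial's stimulus-to-head transfer is modelled in the Laplace domain as

```
H(s) = G0 · exp(−T_D s) · ω_C² / (ω_C² + 2 ζ ω_C s + s²)
```

with resonance frequency `f_C = ω_C / 2π` (Hz), damping ratio `ζ` (quality
factor `Q = 1/(2ζ)`), pure delay `T_D` (clamped per subject) and steady-state
gain `G0 = 1`. The two free parameters per trial, `(f_C, ζ)`, are found by
minimising the time-domain mean squared error between the measured head trace
and the convolution of the measured stimulus with the model's impulse
response. Movement effort is quantified either as the integral of the squared
step-response velocity, `E_Q(D) = ∫₀^D v²(t) dt`, or as the band-averaged gain
magnitude over the stimulus band (0.05–1.05 Hz). For `f_C = 0.6 Hz` the energy
over the 1.8-s response window falls from `E(1.8) = 2.79` at `Q = 1.5` to
`1.13` at `Q = 0.6` — a 60 % reduction, the quantitative signature of the
speed/effort trade-off the adaptation moves along.

## Worked example

Simulate a small synthetic study (4 subjects × 12 trials) and run every
analysis stage:

```bash
cat > config.json <<'EOF'
{"n_subjects": 4, "n_trials": 12, "seed": 1, "mcmc_samples": 1500}
EOF
soundpursuit all --config config.json --out out
```

which prints (numbers from this exact invocation):

```
soundpursuit analysis report
============================
subjects: 4, trials: 48
median r2 of per-trial model fits: 0.992
mean MAE: 3.39 deg (SD 0.39)
mean optimal alignment delay: 433 ms

hierarchical trends (per-trial slope, 95% HDI):
  f_c_hz: +0.0000 [-0.0004, +0.0005] (covers 0)
  q: -0.0786 [-0.0980, -0.0574] (excludes 0)
effort-vs-trial correlation of the group mean: r = -0.963

error-dissociation regressions (offset, slope, correlation):
  H~dE: -0.017, -0.216, r = -0.081
  Hdot~dEdot: -0.042, +0.330, r = +0.264
  H~dEdot: -0.024, -0.003, r = -0.006
  Hdot~dE: -0.064, +0.075, r = +0.011
```

Reading this: the per-trial model fits are excellent (median r² = 0.99); the
resonance frequency shows no trial trend (its 95 % HDI covers zero) while the
quality factor declines at −0.079 per trial — recovering the generating
schedule, which interpolates Q from 1.5 to 0.6 across the 12 trials
(−0.082/trial) — and the frequency-domain effort falls accordingly
(r = −0.96). The cross regressions (head position on velocity error and vice
versa) are near zero, reproducing the dissociation between the two error
signals. `out/` contains the tidy per-trial table (`results.csv`), the trend
summary (`trends.json`), the report, and the session itself as plain CSV trial
files under `out/session/`.

The same stages are available individually (`simulate`, `fit`, `metrics`,
`trend`, `report`) and as library functions (`soundpursuit.run_pipeline`,
`fit_session`, `hierarchical_trend`, ...).

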