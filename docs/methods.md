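# Methods

This note documents the models, algorithms and numerical choices
behind `songtool`, and what the synthetic fixtures do and do not show
about real recordings.

## Song simplification

### Analysis front end

Audio is mono, [-1, 1] float, 44.1 kHz by default (any rate is
accepted). The STFT uses a Hann window of 512 samples with a 128-sample
hop (11.6 ms / 2.9 ms at 44.1 kHz, ~86 Hz bins). These defaults resolve
the ~100 ms notes and ~1.5–6 kHz fundamentals of Java sparrow song;
both are configurable (`SynthesisConfig.window_length / hop_length`).

**Note segmentation** is energy-based: a frame is voiced when its RMS
is within `threshold_db` (default 30 dB) of the recording's loudest
frame. Voiced runs become notes after two clean-ups: gaps shorter than
`min_gap_ms` (10 ms) are merged, runs shorter than `min_note_ms`
(10 ms) are dropped. Because the first voiced frame usually catches
only the tail of its analysis window, the note onset is placed at the
end of the preceding unvoiced frame's window (symmetrically for
offsets); this keeps detected boundaries within about one hop of the
truth on synthetic songs. The threshold is relative, so segmentation is
invariant to global gain. This segmentation rule is this toolkit's own
operational definition; commercial analysis software ships its own,
undocumented one.

Segmentation smears voicing by one window length, so two notes
separated by less than roughly `window + min_gap` (~23 ms at defaults)
can merge. The random-song sampler draws gaps from 10–100 ms; tests
that compare against per-note ground truth use fixtures with gaps of
30 ms or more ("well-separated"), while whole-song guarantees (rhythm,
envelope, length) hold regardless.

### Contour scanning

The scanner produces one (time, frequency) point per voiced frame
(voicing here relative to the note's own peak,
`voicing_threshold_db`, default 25 dB). The fundamental is *acquired*
on the note's loudest frame as the **lowest-frequency spectral peak
within `peak_tolerance_db` (default 12 dB) of the frame's maximum**
inside the search band [`f_min`, `f_max`] = [500, 12000] Hz — this
rule makes the fundamental win over a louder harmonic (e.g. a 2·f0
partial at −6 dB) while a weak subharmonic at f0/2 (below the
tolerance) is ignored — and then *tracked* outward in both directions
with a continuity preference: each frame keeps the peak nearest the
previous frame's frequency, provided it lies within
`jump_threshold_hz` and within `voicing_threshold_db` of the frame
maximum. Where continuity is lost (a genuine jump or a voicing gap)
the tracker re-acquires with the lowest-qualifying-peak rule. The
continuity stage matters: a subharmonic hovering exactly at the
tolerance edge would otherwise make the raw per-frame rule flicker
between octaves from frame to frame, shredding the contour into
one-point sections and the resynthesis into frequency chaos.
Frequencies are refined by parabolic interpolation over the three
dB-scale bins around the chosen peak; ties resolve toward lower
frequency, for determinism and consistency with the fundamental
preference.

**Sectioning:** contour points are split into maximal runs that are
temporally adjacent (gap ≤ 1 hop, with 50% numerical slack) and
spectrally smooth (|Δf| ≤ `jump_threshold_hz`, default 400 Hz). A
section is therefore one continuous stroke of the contour; voicing
dropouts and octave-style jumps start new sections.

**Simplification** keeps each section's first and last point exactly —
this is the whole manipulation. A single-point section becomes a
constant-frequency pair one hop long.

### Resynthesis

Each note is rebuilt as a phase-continuous sine: the instantaneous
frequency interpolates linearly between the endpoints of each section
(held across unvoiced stretches so phase accumulates smoothly), and
`phase = 2*pi*cumsum(f)/fs` carries across section boundaries, so
boundaries add no clicks. Samples outside voiced sections are silent;
each section's voiced span is widened by half an analysis window so
frame-centring does not shave note onsets.

Amplitude is imposed in two stages: the note's frame-RMS envelope
(RMS over 4-hop frames sampled every hop — wide enough that a constant
tone shows sub-percent ripple) scaled by sqrt(2), then two passes of
per-frame RMS correction toward the original note, which brings every
frame — including steep onset frames — within 5% of the original frame
RMS. Frame-RMS matching is used instead of multiplying by a Hilbert
envelope because the original fine structure no longer exists in the
tonal signal. The envelope is carried per-frame, not per-note. Output
length equals input length to the sample; notes are written back at
their original positions. If the resynthesized song would clip, the
whole signal is rescaled to peak 0.999 with a logged warning (RMS
matching is preferred over headroom only up to the clipping point).
No dither is added at 16-bit output, keeping outputs bit-reproducible.

An empty contour (fully unvoiced note) resynthesizes as silence of the
correct length, with a warning rather than an error.

## Synthetic songs

The fixture generator renders notes by additive synthesis: a
fundamental gliding linearly between `f0_start` and `f0_end` plus a
sinusoidal FM "wiggle", optional harmonics at 2·f0, 3·f0 (dB offsets
≤ 0), an optional subharmonic at f0/2, and a flat/ramp/bell amplitude
shape with a 5 ms raised-cosine edge ramp (real notes do not start
with a discontinuity, and the ramp keeps fixtures free of broadband
clicks). The random sampler draws note counts from a Poisson with mean
29.48 truncated at ≥ 5 and note/gap durations (60–180 ms / 10–100 ms)
tuned so the expected song is about 5.16 s — the average size of the
Java sparrow songs this toolkit is meant to process. Fundamentals are
uniform on [1.5, 6] kHz, the band such songs occupy on a spectrogram;
this is a fixture choice, not a measurement. The FM wiggle is
sinusoidal because any smooth nonlinear modulation suffices to
exercise the simplification; wiggle depth ≤ 250 Hz at 20–80 Hz keeps
the per-hop frequency step below the 400 Hz section-split threshold.

What the fixtures do **not** emulate: background noise, reverberation,
amplitude-dependent timbre, nonstationary subharmonic windows, or the
syntax of real song lineages. Passing tests demonstrate that the
pipeline does what it claims on clean tonal material with known truth;
performance on noisy field recordings additionally depends on the
segmentation and voicing thresholds, which are exposed for that
reason.

## Playback schedules

Defaults encode the standard design: 2-minute trials, one stimulus
every 10 s, three songs per male cycling 1,2,3 (so 12 presentations,
4 per song), four trials per session strictly alternating the two
stimulus types, two sessions per comparison with opposite starting
types, 30 s between trials. Counterbalancing assigns starting types
alternately in subject-list order — deterministic by default, with an
optional seeded shuffle, since the assignment mechanism is otherwise a
free choice. An odd subject count is necessarily unbalanced by one and
is logged. The within-trial song order (cycling) is likewise this
toolkit's documented choice. Same-lineage vs different-lineage
sessions are supported through `stimulus_labels` but not modelled
further; multi-day spacing between sessions is metadata only.

## Zero-inflated Poisson GLMMs

See the model statement in the README. Key choices:

- **Coding:** `stimulus_type` reference level is *father* (preference
  for father songs ⇒ negative coefficient on the `non_imprinted`
  indicator); `step` reference is *artificial* (stronger responding to
  artificial songs ⇒ negative coefficient on `natural`). `trial_order`
  and `session_order` enter as numeric covariates — single slopes, the
  usual treatment when one slope per order is reported.
- **Random effects** are independent Gaussian intercepts per factor;
  the subject × song-owner "interaction" is an intercept per observed
  pair. No covariances are estimated.
- **Zero-inflation part** contains fixed effects only (the formula may
  be intercept-only or absent); restricting structural-zero terms to
  fixed effects keeps the inner optimization concave in practice and
  matches how such formulas are usually specified.
- **Estimation:** Laplace approximation over the stacked random
  effects. The inner mode is found by damped Newton with a line search
  (the joint log-density never decreases across iterations); the
  Newton system uses weights clipped to be positive, but the Laplace
  log-determinant uses the *true* curvature at the mode — the y = 0
  mixture term is locally convex in the linear predictor for moderate
  means, and using clipped curvature there biases the marginal
  likelihood (this implementation agrees with `glmmTMB` to ~1e-4 in
  log-likelihood once the true curvature is used). Linear algebra is
  dense Cholesky up to 500 random levels, sparse LU above. The outer
  problem (fixed effects, zero-inflation coefficients, log-sds) is
  L-BFGS-B with finite-difference gradients and warm-started inner
  modes; log-sds are bounded in [−7, 3].
- **Inference:** Wald z on the conditional-model coefficients
  (matching per-coefficient reporting), from the numerical Hessian of
  the Laplace marginal likelihood. Variance components at the zero
  boundary leave flat log-sd directions, so the fixed-effect
  covariance is obtained via a Schur complement with a pseudo-inverse
  over the log-sd block; genuinely unidentified fixed effects
  (collinear designs) still mark the fit as not converged.
  AIC = 2k − 2·logLik with k counting all estimated parameters.
- **Degenerate inputs:** an all-zero response raises with advice to
  exclude it (a subject that never responds makes the model
  unidentifiable); all-zero *subjects* are reported and excluded only
  via an explicit flag, supporting the usual sensitivity re-fit.
- **AIC-guided reduction:** if the full zero-inflation formula fails
  to converge, terms are removed one at a time, last-listed first,
  down to intercept-only and finally no zero inflation; the converged
  candidate with the lowest AIC wins, and every candidate's diagnosis
  is kept.

## Validation studies and sizes

`songtool.validation` packages three simulation studies; effect sizes
(−0.43 for familiarity, −2.46 for the step contrast) are realistic
magnitudes for imprinted-preference playback data.

- **Stimulus recovery:** 60 subjects × 16 trials, 12 owners, RE sds
  0.5/0.3/0.3, 30% structural zeros; 100 replicates in the test suite.
  Asserted: |mean bias| ≤ 0.1, 95% Wald CI coverage ≥ 90%.
- **Combined steps:** 40 subjects × 16 trials over both steps, step
  effect −2.46, interaction exactly 0; 100 replicates. Asserted: step
  effect mean within ±0.3, interaction mean within ±0.15, interaction
  CI coverage ≥ 90%.
- **Type-I error:** 32 subjects × 8 trials, null stimulus effect;
  200 replicates. Asserted: rejection rate at α = 0.05 within
  [0.02, 0.09] (Laplace approximation and finite owner pools justify
  the slack around 0.05).

Study sizes are chosen so that a single replicate resolves the target
effect (per-replicate sampling sd well below the asserted tolerance on
the mean) while a full study completes in minutes on one core. The
acceptance script (`scripts/acceptance.py`) reruns the same studies
with 30 recovery / 100 calibration replicates and reports the same
quantities, regenerating everything from the given seed.

In the important special cases the engine collapses onto independent
references, used as test oracles: with no random effects and no zero
inflation it matches a Poisson IRLS GLM to 1e-4; with no random
effects it matches `statsmodels`' zero-inflated Poisson likelihood;
with crossed random effects it matches `glmmTMB` (Laplace, ML) on
matched data. The zero-inflation diagnostic reproduces the analytic
ratio for half-structural-zero data, noting that the fitted Poisson
absorbs the zeros into its mean, so the asymptotic ratio for 50%
zeros over Poisson(2) is (0.5 + 0.5e⁻²)/e⁻¹ ≈ 1.54.

## Known limitations

- The contour scanner assumes one dominant fundamental per frame;
  biphonation (two simultaneous independent fundamentals) is not
  modelled and resolves to the lower qualifying peak.
- Segmentation merges notes closer than about one analysis window.
- The Laplace approximation is known to be slightly anticonservative
  for very small cluster sizes; per-subject models on a handful of
  trials may fail to converge, which is reported, not hidden.
- Wald inference carries the usual caveats for variance components
  near zero; the toolkit reports point estimates of RE sds without
  standard errors.
- Exactly reproducing contours from any particular commercial
  analysis tool is out of scope: window, overlap and peak-picking
  conventions differ and are not published.
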