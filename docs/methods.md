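# Methods

## The inference problem

Event-related potentials are smooth, strongly autocorrelated time series.
Testing a condition contrast at every sample point with uncorrected
t-tests produces many false positives, but classical corrections
(Bonferroni over 501 points) are hopelessly conservative because adjacent
points are nearly redundant. The run-length procedure implemented here
takes the middle road: pointwise two-tailed one-sample t-tests at
α = 0.05 are kept uncorrected, and familywise control is moved to the
*duration* criterion — only runs of consecutive significant points longer
than a simulated null threshold count as reliable.

### Null model and threshold

The null simulation draws, per simulated dataset, `n_subjects` independent
stationary Gaussian AR(1) series

```
x_t = φ x_{t−1} + ε_t,   ε_t ~ N(0, σ²),   x_0 ~ N(0, σ²/(1−φ²)),
```

with the same number of subjects and sample points as the observed
contrast and φ estimated from the data. t statistics are scale-free, so
σ = 1 without loss of generality. In each of `n_sims` datasets (default
1000) the longest run of consecutive significant points is recorded; the
threshold is the empirical 95th percentile of that distribution by the
nearest-rank rule (the smallest value with ≥95% of the distribution at or
below it) — percentile interpolation would fabricate non-integer run
lengths. Run duration converts to time as `length_samples × 1000/fs` ms
and the comparison against the threshold is a **strict** inequality.

φ is estimated per subject as the lag-1 Pearson autocorrelation of the
contrast waveform over the analysis window, combined across subjects by a
Fisher-z mean, and clamped to [0, 0.999] (with a warning) because the
null model assumes non-negative, stationary autocorrelation. This is the
minimal AR(1) reading of "noise matched to the observed autocorrelation";
estimating richer noise spectra is out of scope. Zero-variance time
points are treated as significant (|t| = ∞) but logged.

Calibration is a property of the whole procedure, not of any single test:
the acceptance suite pushes 500 complete null datasets (20 subjects, 501
points, φ = 0.8) through estimation + simulation + extraction and checks
that the fraction with at least one supra-threshold run is statistically
compatible with 5%.

### Component windows (collapsed localizer)

Windows are defined on the grand average across *conditions*, so window
selection cannot bias the between-condition comparison. Local extrema
with prominence ≥ 0.5 µV (configurable; component identification in the
field is usually by inspection) become peaks; consecutive same-polarity
peaks collapse to the larger one so polarities alternate. The boundary
between adjacent components is placed at the zero crossing of the
collapsed waveform between the peaks (choosing the crossing nearest the
latency midpoint when the waveform wiggles), or at the midpoint if no
crossing exists; the earlier window ends at the last sample before the
crossing and the next begins one sample later, so windows tile the search
interval with single-step gaps (e.g. …–354, 356–… on a 2 ms grid).
Per-component statistics are means over the window's closed sample range,
compared between conditions by a paired two-tailed t-test with
`dz = t/√n`. The KS normality diagnostic on the paired differences is
reported, never used to gate the t-test; both a fixed-parameter exact KS
and a Lilliefors-corrected variant are available because the two differ
when the normal's parameters are estimated from the same sample.

### Mixed models

Per component, amplitude ~ Condition (m1), + Age (m2), + Condition×Age
(m3), random intercept per participant, fitted by **maximum likelihood**
(statsmodels MixedLM). REML would be invalid for the likelihood-ratio
tests because the models differ in fixed effects. Age enters centered at
the sample mean, which keeps the Condition main effect interpretable at
the average age under an interaction. LRTs use the nominal χ² reference
with df = difference in fixed-effect counts (1, 2, 1 for m2 vs m1, m3 vs
m1, m3 vs m2); forward selection at α = 0.05 keeps the richest model
whose addition is significant. Fixed-effect p-values use the
between-subject residual df (n − 2); a Satterthwaite approximation is not
available in the fitting backend, and the convention is recorded in the
output log.

**Known limitation.** At this design scale (20 subjects × 2 conditions)
the ML LRT against the asymptotic χ²₁ reference is anti-conservative for
fixed effects: the acceptance suite measures an empirical m3-vs-m2 size of
≈0.07 at a nominal 0.05 (and lme4's `anova` of ML fits shows the same
inflation), consistent with the familiar n/(n−p) small-sample scaling of
the statistic. The package deliberately reproduces the field-standard
procedure rather than applying a small-sample correction, so model
selection is mildly liberal at n = 20; the corresponding size assertion
in the acceptance suite documents this honestly rather than relaxing the
nominal level.

### Power

Paired-t power is computed from the noncentral t distribution: with
df = n−1, noncentrality `dz·√n`, power = P(|T′| > t_crit) at the
two-tailed critical value. `required_n` walks n upward to the smallest
value meeting the target; at dz = 0.73, α = 0.05, target 0.85 this gives
n = 19 (power 0.831 at 18, 0.853 at 19).

## Synthetic cohorts

The generator emulates the study design: two conditions × two trial
types, fully crossed within subject, equal trial counts per cell, 500 Hz
sampling, epochs −300…1300 ms around tactile onset. Each trial is

```
visual(t) + 1[touch] · g(condition, age) · sep(t) + subject_offset + AR(1) noise
```

with `visual` and `sep` sums of Gaussian bumps (amplitude µV, peak
latency ms, SD width ms) — the simplest shape producing identifiable
alternating deflections. The condition effect is a multiplicative gain on
the somatosensory templates (`g = 1` for receding), because the effect of
interest is amplitude enhancement, not a latency shift. In the age-graded
preset the gain tilts linearly in age around the midpoint of the age
range, so the effect reverses sign across the cohort. Ages are drawn as
integer days uniform over the range. One master seed sequence spawns a
stream per subject, so enlarging the cohort never reshuffles existing
subjects, and a fixed seed fixes the epoch table byte for byte.

Preset parameters (units µV, ms, days):

| parameter | 4-month preset | 8-month preset | why |
|---|---|---|---|
| subjects / trials per cell | 20 / 10 | 20 / 10 | the study design |
| φ (AR(1) lag-1) | 0.8 | 0.8 | strong but sub-ERP smoothness; single-trial EEG after band-limiting |
| innovation SD | 4 | 4 | stationary SD ≈ 6.7 µV, realistic single-trial noise vs ~5 µV components |
| subject offset SD | 2 | 2 | between-subject amplitude spread (cancels in difference waves) |
| SEP bumps | P286/N398/P506/N560/P662, 3.5–6 µV | P240/N362/P470/N572, 4–5 µV | alternating late components in the 200–700 ms range |
| condition gain | 1.8, no age trend | 1.0 ± 0.05/day | strong enough that the run-length test detects the injected window in ≥90% of cohorts, and the interaction is recoverable at n = 20 — i.e. the presets represent a true effect the design is powered for |
| ages | 109–137 | 230–257 | the two cohorts' age ranges |

What the generator does **not** emulate: real scalp topography and channel
structure (inputs are assumed cluster-averaged; an optional pre-step
averages a `channel` column), ocular/motion artifact waveforms (artifact
rejection is exercised with a peak-to-peak surrogate), unequal trial
counts from attrition, non-Gaussian noise, and the 1/f spectrum of real
EEG beyond what AR(1) captures. Passing tests therefore demonstrate the
*statistical machinery* — calibration, power at the injected effect size,
recovery of injected structure — not fidelity to any real infant dataset.

## Numerical and scale choices

- Time grids are sample-aligned: all interval endpoints must lie on the
  1000/fs ms grid; intervals are closed on grid points. Default baseline
  −100…0 ms, default analysis window −100…900 ms (501 points at 500 Hz).
- All pipeline randomness flows from one config seed through named
  substreams (data-gen, null-sim), so stages are independently
  reproducible and the results bundle is bit-for-bit stable.
- The null simulator draws one AR(1) batch per simulated dataset in a
  fixed documented order, which is what makes exact brute-force
  replication (and the oracle-equivalence tests) possible.
- Acceptance-scale simulations use 500 null simulations per dataset for
  the calibration and detection studies and 1000 (the printed default)
  in the user-facing pipeline; 500/100/200 replicate counts for the
  calibration, detection and model-recovery studies match the design
  properties they verify.
- Degenerate inputs fail loudly and specifically: all-zero contrasts,
  emptied rejection cells, off-grid windows, missing cells and non-nested
  LRTs each raise a distinct, named error; a singular mixed-model fit is
  flagged in the output, not dropped.
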