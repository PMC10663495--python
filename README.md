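# perisep

Analysis pipeline for infant **somatosensory evoked potentials (SEPs)**
modulated by prior visual motion, for developmental EEG researchers who
need the full statistical chain — from trial-level epochs to
familywise-error-controlled inference — as tested, scriptable code.

The experimental logic: infants see an object approach or recede, then feel
(or don't feel) a vibrotactile stimulus. Subtracting the No-Touch from the
Touch response isolates the somatosensory response per condition; the
per-subject contrast between conditions,

```
c_i(t) = [Touch − NoTouch]_approaching(t) − [Touch − NoTouch]_receding(t),
```

is the object all inference acts on.

## What the package implements

- **Run-length Monte Carlo test.** Two-tailed one-sample t-tests of
  `c_i(t)` vs 0 at every sample (α = 0.05, uncorrected) would inflate the
  familywise error, so significance is granted only to *runs* of
  consecutive significant points longer than the 95th percentile of the
  longest-run distribution simulated from Gaussian AR(1) null data matched
  to the observed lag-1 autocorrelation, with the same number of subjects
  and sample points (1000 simulated datasets by default).
- **Collapsed-localizer components.** Latency windows are defined on the
  waveform averaged across conditions (unbiased for the comparison),
  labelled by polarity and peak latency (e.g. `P286`); per-component mean
  amplitudes are compared with a paired t-test, reported with Cohen's
  `dz = t/√n` and a Kolmogorov–Smirnov normality diagnostic.
- **Nested mixed models.** Per component, amplitude is modelled with a
  participant random intercept and fixed effects Condition (m1),
  + Age (m2), + Condition×Age (m3), all fitted by maximum likelihood;
  likelihood-ratio tests `χ² = 2Δℓ` select the model.
- **Power analysis.** Paired-t power from the noncentral t distribution
  (df = n−1, noncentrality `dz·√n`) and the smallest n reaching a target
  power.
- **Synthetic cohorts.** A generator producing epoch tables with the full
  design crossing, Gaussian-bump components, a multiplicative condition
  gain (optionally age-graded), and AR(1) noise — so every stage is
  testable against known ground truth.

## Worked example

```bash
perisep run --preset 4mo --seed 7 --out-dir demo --prominence 1.5
```

simulates a 20-infant cohort (10 artifact-free trials per cell, 500 Hz,
epochs −300…1300 ms) with an injected condition effect and runs every
stage. The log reports an estimated lag-1 autocorrelation of the contrast
waveforms of `phi_hat = 0.819` and a run-length threshold of 18 ms; the
resulting `runs.csv` is

```
start_ms,end_ms,length_samples,length_ms
264.0,330.0,34,68.0
378.0,422.0,23,46.0
468.0,530.0,32,64.0
632.0,660.0,15,30.0
```

four statistically reliable stretches of condition difference, all inside
the injected 196–742 ms somatosensory window. `components.csv` holds the
collapsed-localizer windows and paired tests (t, df, p, dz, KS D/p), e.g.

```
component  start_ms  end_ms  peak_ms      t  df     p     dz
     P272     202.0   352.0    272.0  7.122  19 0.000  1.593
     N408     354.0   440.0    408.0 -4.629  19 0.000 -1.035
```

— the approaching condition enhances each somatosensory deflection, and
`model_comparison.csv` selects `m1` (Condition only) for every component,
as it should for a cohort generated without an age trend. Re-running the
same command reproduces every file bit for bit. With `--preset 8mo`
(condition gain tilting by age so the effect reverses sign across 230–257
days) the selection moves to `m3`, the interaction model.

The sample-size calculation behind a 20-infant cohort:

```bash
$ perisep power --d 0.73 --alpha 0.05 --power 0.85
required n = 19 (achieved power 0.8528)
```

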