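# Methods

`pupilsem` implements a pupillometric analysis of auditory *semantic
salience*: do sounds whose meaning a damaged semantic system cannot resolve
carry an exaggerated autonomic (pupil-dilation) response?  The pipeline
compares pupil responses to meaningful (M+) natural sounds against
spectrally-inverted meaningless (M−) controls in healthy older adults and
four dementia syndromes (bvFTD, SD, PNFA, AD), and relates the differential
response to nonverbal auditory semantic competence.  This note documents the
models, the defaults and why they were chosen, the synthetic-data harness,
and the numerical decisions that matter.

## Stimulus construction

Stimuli are mono 44.1 kHz waveforms fixed to 2 s (short, naturally periodic
sounds are looped end-to-start with no crossfade; long ones truncated) and
normalised to a common RMS.  Meaningless controls are produced by **spectral
inversion**, implemented as sign alternation: sample *n* is multiplied by
(−1)ⁿ, a ring modulation by the Nyquist frequency that maps every component
*f* to *fs*/2 − *f*.  This choice — over, say, an FFT-domain bin reversal —
is exactly energy-preserving, bit-exact involutive (two applications return
the input sample for sample), and windowing-free, which makes the inversion
identities testable with zero tolerance.  Peak level is measured digitally
(dBFS of the maximum absolute sample) and treated downstream as an opaque
per-sound loudness covariate; nothing in the analysis depends on it being a
physical sound-pressure measurement.

A candidate sound survives pilot screening when fewer than the threshold
fraction of pilot raters misidentify it (strictly less; at 20 raters and a
10% threshold, two misidentifications exclude).  The experiment playlist
puts 4 familiarization trials (2 M+, 2 M−) ahead of 40 main trials — each of
10 M+ and 10 M− sounds twice, in a seeded uniform random order.

## Trial structure and preprocessing

A trial spans 11 s at 250 Hz (4 ms grid): 2 s silent baseline, 2 s sound,
7 s silent equilibration.  Intervals are half-open `[start, end)` ms,
0-based at trial onset.

**Artifact masking.**  Blinks collapse the measured pupil area rapidly
(usually to zero) and recover rapidly.  Samples are flagged when they are
invalid/zero, or when they border a first difference exceeding
`k × max(MAD, rel_floor × median valid area)` with `k = 8` and
`rel_floor = 0.01`, where the MAD is of the first differences over the
trial and only differences between two valid samples count.  The floor term
is load-bearing: on clean traces the MAD collapses to the derivative scale
of the smooth evoked dilation itself, and a pure `k × MAD` rule would flag
the physiological response; the floor (8% of the median area per 4 ms step
at the defaults) sits two orders of magnitude above the evoked derivative
and far below a blink ramp.  Flagged runs become intervals, each extended
50 ms backwards and 750 ms forwards (the forward margin covers the ensuing
light reflex), clipped to the trial and merged.  Masked samples are
discarded, never interpolated.

**Metrics.**  `baseline` is the mean valid unmasked area over [0, 2000) ms;
a trial needs at least 25% of its baseline samples to survive masking, else
it is excluded with a reason code.  `pupil_max` is the natural log of the
maximal valid unmasked area in [2000, 11000) ms divided by baseline.  The
search window starts at sound onset so that a pre-stimulus fluctuation can
never be the "response"; both the window and the log base are arguments.
The log-ratio is exactly invariant to rescaling all areas, so device units
never matter.  A QC step regresses per-trial artifact fraction on group and
on sound indicators and flags imbalance at p < .05.

## Confound adjustment

Loudness, pleasantness and arousal drive pupil dilation on their own, and
the design is deliberately imbalanced: M− sounds are louder (≈ +6 dB peak)
and less pleasant.  The adjustment model is

    pupil_max ~ 1 + condition + peak_db + pleasantness + arousal
                + (1 | participant) + (1 | sound),     (REML)

with the rating covariates being the **control group's** mean ratings per
sound (patients' ratings are collected but unused) and participant and sound
intercepts crossed.  The per-sound correction

    adjustment_s = b_loud (L_s − L̄) + b_pleas (P_s − P̄) + b_arous (A_s − Ā)

is subtracted from every crude response to sound *s*; covariates are centred
at the stimulus-set mean, so the corrections sum to ~0, the grand mean is
preserved, and within-sound variance is untouched.

The **condition fixed effect** in the model is essential and deserves
emphasis.  All three covariates are sound-level and correlated with
condition; without a condition term the true M+/M− effect loads onto the
covariate slopes and the "adjustment" then subtracts part of the real
differential (in simulation the entire cohort-mean effect disappears).  With
the condition term, the betas are identified from within-condition covariate
variation, and simulations show the adjusted group differentials unbiased to
~1% while unadjusted ones are biased by the full 6 dB × b_loud ≈ −0.12.  The
condition coefficient itself never enters the adjustment.

**REML engine.**  The crossed model is fitted by a profiled REML written for
this package (`pupilsem.mixedlm`): fixed effects and the residual variance
are profiled out, the two variance ratios are optimised by Nelder–Mead on
the log scale, and every criterion evaluation runs through the Woodbury
identity on the q×q latent system (q = participants + sounds), costing
O(q³) after one O(n·q) pass.  On a seeded crossed dataset the engine matches
an lme4 reference fit to ~6 significant figures in fixed effects, standard
errors, variance components and the REML criterion (frozen in the test
suite), and the balanced one-way case reproduces the classical closed-form
ANOVA estimators.  Confidence intervals for the confound betas use
t quantiles with `n_sounds − n_fixed` degrees of freedom, since these
covariates vary only between sounds and the effective replication is the
stimulus set, not the trial count.

## Group analysis

Participant summaries are per-condition means of adjusted `pupil_max` over
non-excluded trials; the **differential response** is mean(M+) − mean(M−).
Within-group condition effects use two-sided paired t-tests (a zero-variance
degenerate case returns p = 0 with an explicit warning rather than NaN).
Group contrasts regress the differential on group indicators plus gender and
education — the demographics that differ between groups — with controls as
reference.  Habituation is modelled as a linear trend of the adjusted
response on presentation index (1..40) per group × condition with
participant fixed effects (the within estimator; the dummy-variable OLS is
the test oracle); baseline drift is the same estimator applied to raw
per-trial baselines.  The semantic correlation is an OLS of the differential
on the 0–60 classification score, reported with slope, r² and p, plus the
battery of control correlations (severity, span, medication, per-condition
means) expected to be null.  All tests are two-sided at α = .05 with **no
multiplicity correction** — raw p-values are reported so users can correct
post hoc.

## Semantic classification task

Sixty pairs of real sounds judged same-source vs different-source: 21 same,
39 different, 14 pairs containing one of the ten pupillometry M+ sounds.
Scoring is +1 per response matching the key; missing responses count as
incorrect (forced choice); the subset score is over the 14 flagged pairs,
and total = subset + complement by construction.  Chance is 50%/trial
(30/60), quoted for orientation only.  The packaged key is a synthetic
stand-in (`make_classification_key`) reproducing the combinatorial
structure; the original pairs are not public.

## Synthetic cohort generator

The generator is the package's verification harness, not a physiological
claim.  It works natively on the `pupil_max` scale: trial amplitude

    R = alpha[group, condition] + u_i ± delta_i/2 + w_s + confound(s)
        + habituation[group, condition] · (index − 1) + eps_trial,

and renders a trace multiplicatively, `area(t) = B · exp(R · g(t)) ·
(1 + noise)`, with `g` a gamma-density kernel (shape 2, peak 930 ms after
sound onset, grid maximum normalised to exactly 1).  The multiplicative
construction makes ground truth live in metric units: with no noise and no
blinks the preprocessing pipeline returns `pupil_max = R` to machine
precision, which turns metric exactness into a zero-tolerance test.  Blinks
arrive as a per-trial Poisson process (rate 1.5), each zeroing a uniform
100–300 ms span bracketed by 2-sample steep ramps.  Semantic scores follow
`score_i = s0[group] − κ (true differential_i − group mean)`, realised as
binomially scored per-pair responses and clipped to [0, 60].

Defaults are the study conditions where stated and declared conventions
elsewhere, fixed before any validation run:

| parameter | default | basis |
|---|---|---|
| group sizes | 20/13/11/6/10 | the study cohort |
| amplitudes (M+, M−) | control (0.22, 0.20); bvFTD, PNFA (0.25, 0.20); SD, AD (0.32, 0.20) | magnitudes unreported; chosen to reproduce the qualitative ordering (largest excess in SD/AD, trend in controls) |
| habituation | control M− and AD M+ at −0.001/trial | the two attenuations the study reports |
| baseline drift | PNFA +2 units/trial | the one drift the study reports |
| confound betas | 0.02/dB, 0.01, 0.015 per rating unit | loudness beta is the recovery-study value; others same order |
| M− peak offset | +6 dB (SD across sounds 3 dB) | direction from the study; magnitude a convention |
| semantic baselines | 58/48/50/56/51 | the study's group means |
| coupling κ | 160 points per unit differential | chosen a priori so the population patient-cohort r² ≈ 0.2 (the study's value) under the model's variance algebra: cov² / (var(diff)·var(score)) with cov = −κτ², τ = 0.03, measurement variance 2σ²/20, and score variance κ²τ² + binomial + between-group |
| noise | participant SD 0.05, differential SD τ = 0.03, sound SD 0.02, trial SD 0.08, trace noise 2% | typical magnitudes for area-based pupillometry at this trial count |

What the generator does *not* emulate: light-reflex dynamics, pupil
foreshortening and gaze artifacts, non-Gaussian rating behaviour, serial
correlation within a trial beyond the smooth kernel, and real acoustic
variability.  Passing tests therefore demonstrate that the *pipeline* is
correct and well calibrated under a faithful statistical structure — not
that the physiological claims hold in new patients.

Two calibration details matter when simulating nulls.  First, with only ten
sounds per condition, a realised imbalance of *random sound effects* between
the M+ and M− sets acts as a shared condition shift across participants and
inflates any paired test (the language-as-fixed-effect problem); the null
configuration therefore zeroes sound intercepts, and users simulating nulls
with sound effects on should expect (correctly) inflated paired-test
rejection.  Second, the residual check "regress adjusted responses on
loudness" is performed on the same data used to estimate the adjustment, so
its naive SE understates the correlated sampling error; across simulations
the residual slope is unbiased (mean within 2 SE of zero, magnitude ~4% of
the injected effect), but the per-simulation |slope| < 2 SE event occurs in
only ~4 of 5 runs, which is expected, and both numbers are reported.

With the default effect sizes the synthetic control group's M+ − M−
difference often reaches significance (the real study saw a trend);
the qualitative target is the ordering and the SD/AD excess over controls,
not the control group's p-value.

## Reproducibility and problem sizes

Everything is driven by integer seeds through `numpy` `SeedSequence`
spawning; a cohort is bit-identical across regenerations of the same
(config, seed).  The validation studies run at 1000 masking traces, 200
confound/bias simulations, 1000 null simulations and 100 end-to-end seeds in
the test suite; `scripts/acceptance.py` reports the same quantities at
1000/100/100/500/50, sizes chosen so a full reproduction completes in a few
minutes on one core.

## Known limitations

* Artifact detection is tuned for area-collapse blinks; slow partial
  occlusions or gaze-dependent foreshortening are not modelled or detected.
* The adjustment is per-sound and linear; nonlinear loudness–dilation
  relations or trial-level affective state are out of scope.
* The habituation model is a linear trend; nonlinear (e.g. exponential)
  attenuation would be mis-specified, though the sign test is robust.
* Group contrasts adjust for gender and education only (the study's choice);
  age is assumed balanced.
* With 6 participants, PNFA-group inferences are fragile in any pipeline;
  simulations show correct calibration but low power for that group.
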