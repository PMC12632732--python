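# Methods

This note documents the models, numerical choices, and limitations of
mobikit's analysis stages and of the synthetic-session generator the
tests are built on.

## The experiment the package models

A cognitive-motor-sensory dual-task (MoBI) design: participants stand
(S) or walk (W) on a treadmill, with (F) or without (NF) optic flow in
the visual field, while performing (T) or not performing (NT) a visual
Go/NoGo task. Five conditions are realized — S-NF-T, W-NF-T, W-F-T,
W-NF-NT, W-F-NT; the standing-with-flow-and-task cell was never run, so
manifests hard-code the five labels and factorial ANOVAs on behavior use
condition (3 levels) rather than a motor x sensory crossing. Blocks hold
180 trials (20% NoGo, exact count 36), 400 ms stimuli, 200-400 ms
uniform inter-stimulus intervals. Data streams: button events, two heel
markers at 100 Hz, 64-channel EEG at 512 Hz.

## Behavior

A press is attributed to the most recent stimulus whose response window
(default 100-1000 ms after onset, capped at the next stimulus onset so
windows never overlap) contains it; only the first press per trial
counts. The defaults are configurable because anticipatory/late-press
handling is a genuine design choice: 100 ms excludes physiologically
implausible reactions, and the cap resolves the otherwise ambiguous
assignment when stimuli arrive faster than the window closes.

d' is computed as z(hit rate) - z(false-alarm rate). Some write-ups
print the formula with the opposite sign; above-chance performance is
positive under the convention used here, which is what reported positive
d' values imply. The log-linear correction (add 0.5 to each count, 1 to
each denominator) is applied by default so rate-0/rate-1 blocks stay
finite; it can be disabled for exact-rate calculations.

## Gait

Heel strikes are local maxima of the AP heel coordinate with a minimum
separation of 0.5 x expected stride time and a minimum prominence of
0.25 x the median AP peak-to-trough excursion (estimated from a
separation-only first pass). These two thresholds replace the manual
visual confirmation a human analyst would perform; both are exposed as
parameters. Heel lift is the AP minimum strictly between consecutive
strikes, ties resolving to the earliest sample for determinism. Event
times are reported at sample resolution (±10 ms at 100 Hz); no
sub-sample interpolation is attempted because all downstream definitions
are sample-based. Negative stride lengths (backward apparent travel) are
retained and flagged rather than dropped — there is no principled
exclusion rule, and silent dropping would bias CVs. Blocks with fewer
than 10 strides are summarized but warned about. Units are mm and ms;
AP is anterior-positive, parallel to the belt.

Stride metrics are driven by the right foot (strike-to-strike time,
lift-to-strike length), and step width is evaluated at right heel
strikes, matching the usual single-reference-foot convention.

## ERP processing

* **Filter**: Hamming-window linear-phase FIR, 0.25-40 Hz, applied
  forward-backward (zero net phase). Kernel length is 3.3 / transition
  cycles; the default 0.25 Hz low-edge transition gives a ~13 s kernel
  at 512 Hz, appropriate for multi-minute recordings. Short synthetic
  blocks must widen `transition_low` (the pipeline config exposes it);
  the filter refuses recordings shorter than its kernel rather than
  silently degrading.
* **Reference**: instantaneous channel mean subtracted (per-sample sum
  exactly zero; idempotent).
* **Bad channels**: spherical-spline interpolation (Perrin-style
  g-function, stiffness m = 4, 50 Legendre terms, ridge 1e-5 on the
  self-Gram matrix). Candidate detection (robust-z of log power > 5, or
  flatline) only proposes channels; the caller confirms the list
  explicitly. ICA is deliberately out of scope: component selection
  criteria are analyst-dependent, so the pipeline stays linear.
* **Epochs**: -100..800 ms around onset. At 512 Hz the bounds are not
  integer samples; the grid is start = round(tmin x fs) = -51 and
  length = round(900 ms x fs) = 461 samples, i.e. samples -51..409.
  Baseline is the -100..0 ms mean (disableable). Trials overrunning the
  recording edges are dropped with a count.
* **Averaging**: participant means first, then an unweighted mean across
  participants, so trial-count differences between participants do not
  weight the grand average. Difference waves are CR - Hit.
* **Peaks**: signed extremum of the component electrode within the
  window; ties to the earliest sample; window-edge extrema are flagged
  as boundary peaks (a monotone segment has no interior peak). A-priori
  windows are the default; per-group adjusted windows are configuration
  overrides, since which of the two a published analysis used is often
  ambiguous.

## Cluster statistics

Pointwise two-tailed t-maps (paired across participants, or pooled
two-sample for group contrasts on difference waves) with a run-length
criterion: a cluster is a maximal run of >= 10 consecutive samples, all
p < .05 *and all with the same t sign* — a sign flip implies a different
effect direction, so runs split there even when p stays below threshold.
Zero-variance samples get t = 0, are flagged, and can never be
significant. Channels are independent: there is no spatial clustering
and no cross-channel multiplicity control, so results are exploratory
descriptions. A label-shuffling permutation null for the largest run
length is provided as an optional extension but is not part of the core
procedure. At 512 Hz, 10 samples is ~19.5 ms.

## Split-plot repeated-measures ANOVA

Implemented as the classical multivariate-transform univariate
decomposition: subject cell means are projected onto orthonormal
within-subject contrasts (QR of the contrast space, Kronecker products
for effect combinations), a multivariate linear model is fit against the
effect-coded between design, and each within effect is tested with the
averaged F whose error stratum is the subject-by-effect interaction.
Effect coding plus generalized-inverse hypothesis matrices yields
Type III between effects under unequal group sizes, matching the
behavior of the major commercial package; under equal sizes the results
coincide with the weighted decomposition other open-source tools use
(verified against pingouin and statsmodels on balanced data, and against
R car::Anova — including Greenhouse-Geisser epsilon to 7 digits — on an
unbalanced case).

Greenhouse-Geisser epsilon is (tr S)^2 / (c tr S^2) on the
contrast-projected error covariance S, clipped to [1/c, 1]; it is
identically 1 for 2-level factors. Corrected and uncorrected p are both
reported, with Mauchly's W (chi-square approximation) as the flag for
when the correction matters: the choice of headline p is left to the
caller rather than silently automated. Partial eta squared is
F df1 / (F df1 + df2), and the implementation always reports the true
error df (published tables sometimes print (df1, n-2) instead; effect
sizes are only consistent with the error df).

Under null compound-symmetric data the uncorrected within test is exact
and calibrates at the nominal alpha (checked over 2000 replicates); the
GG-corrected test is slightly conservative there, as theory predicts.

Pairwise comparisons use paired t within factors and pooled-variance t
between groups, Bonferroni-corrected (p x number of pairs, capped at 1),
with pooled-SD Cohen's d throughout — difference-SD d for within
comparisons inflates with correlation and is not comparable across
designs.

## Synthetic data generator

* **Gait**: per-stride stride times T_i and lengths L_i are independent
  normal draws at the configured mean and CV (resampled, bounded, if a
  draw is non-positive). The AP trajectory is +L/2 at strike, a linear
  descent to -L/2 at heel lift (end of stance, duty factor 0.62 by
  default), and a half-cosine swing back up — guaranteeing a unique
  per-stride maximum/minimum so detector ground truth is well defined.
  Feet are phase-shifted half a stride; ML coordinates are piecewise
  constant at ±W/2 between right strikes with per-step width draws, so
  measured step width equals the drawn truth exactly. Defaults (1.30 s,
  1237 mm, 196 mm; CVs 3.0 / 2.7 / 9.0%) sit at the scale such treadmill
  studies report for adolescents. Belt speed is not modelled: stride
  time and length are primitives, since per-participant speeds are
  typically set by preference and only group means are published.
* **Behavior**: onsets accumulate stimulus duration plus uniform ISI;
  NoGo placement is exact-count by default (36 of 180) for test
  determinism, Bernoulli optionally. Responses occur with the configured
  hit/false-alarm probability at onset + lognormal RT (median 350 ms,
  sigma 0.2).
* **ERP epochs**: each trial is a sum of components — Gaussian time
  course (SD = width) at a per-trial jittered latency, scaled by a
  spatial map exp(-(d/spread)^2) in great-circle distance from the
  component's center electrode (weight exactly 1 there, so configured
  amplitudes are recovered exactly at zero noise) — plus lag-1
  autoregressive Gaussian noise (stationary SD, spatially independent).
  AR(1) is the simplest noise with temporal persistence, which is what
  the run-length cluster criterion is sensitive to. Per-cell
  (condition x response x group) multipliers set effects; a study helper
  adds per-participant amplitude multipliers ~ N(1, 0.12) as
  between-subject variability.
* **Electrode geometry**: an idealized spherical head. Midline
  electrodes at 10%-arc steps, row rims on the 72-degree circle,
  intermediate electrodes slerped along row arcs. Adequate for
  neighborhood structure (interpolation, spatial decay); not a real head
  model.

What the generator does **not** emulate: movement/EMG artifacts, eye
blinks, volume-conducted correlated noise, electrode drift, RT-locked
(rather than stimulus-locked) components, gait asymmetries or drift in
marker calibration. Passing recovery tests therefore demonstrates
correctness of the analysis code under the stated model, not robustness
to real-world artifacts.

## The canonical dual-task scenario

`mobikit.scenarios` defines a two-group study (12 TD vs 12 ASD) over the
three task conditions where Correct Rejections carry a P3 enhancement:
multipliers 1.9 / 1.25 / 1.30 (TD) and 1.35 / 1.15 / 1.20 (ASD) for
standing / walking / walking-with-flow on a 6 uV P3, 40 trials per cell,
8 uV AR(0.95) noise. The configuration encodes a direction — inhibitory
ERP modulation larger in TD and a group gap that shrinks under walking
load — and analyses of it are direction-only demonstrations; cluster
counts and extents depend on the configured effect sizes and are not
quantitative claims about any population.

## Problem sizes in tests and the acceptance script

Recovery and calibration runs use deliberately compact sizes — 50-200
strides, 12 participants per group, 40 trials per cell, 16-channel
montages, 2000 ANOVA null replicates — chosen as the smallest designs at
which the checked properties are statistically decidable. File-based
pipeline tests use still smaller sessions (3 participants per group, 14
trials) since they check plumbing, not power.

## Known limitations

* No spatial (channel-neighborhood) clustering or TFCE; the run-length
  rule controls only within-channel multiplicity.
* rm_anova supports at most two within factors and one between factor —
  the designs used here — not general mixed models.
* The EEG reader accepts delimited text matrices (and EDF when mne is
  installed); proprietary acquisition formats are out of scope.
* Epoch-grid rounding means off-grid configured latencies are recovered
  to the nearest sample (±0.98 ms at 512 Hz).
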