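# mobikit

Mobile brain/body imaging (MoBI) analysis in Python: synchronized
**Go/NoGo behavior**, **treadmill gait kinematics**, and **event-related
potentials (ERPs)**, with run-length cluster statistics and split-plot
repeated-measures ANOVA. The package targets cognitive-motor dual-task
experiments — participants stand or walk on a treadmill, with or without
optic flow, while performing (or not performing) a visual Go/NoGo task —
and ships a ground-truth synthetic session generator so every stage is
testable end to end without any recordings.

## What it computes

**Behavior.** Trials are scored Hit / Miss / FalseAlarm /
CorrectRejection by attributing each button press to the most recent
stimulus whose response window contains it. Sensitivity is

    d' = z(H) - z(F),   H = (n_hit + 0.5) / (n_go + 1),
                        F = (n_fa + 0.5) / (n_nogo + 1)

(log-linear correction, so ceiling/floor blocks stay finite); reaction
time is the onset-to-press interval averaged over Hits only.

**Gait.** On a treadmill the heel marker's anterior-posterior (AP)
excursion is periodic: heel strike is the most anterior point, heel lift
the most posterior within a stride. Stride time is the same-foot
strike-to-strike interval, stride length the AP distance from a heel
lift to the next strike, and step width the mediolateral heel separation
at right heel strike. Blocks are summarized by means and
CV% = SD/mean x 100.

**ERP.** Continuous EEG (512 Hz) is band-passed 0.25-40 Hz with a
zero-phase Hamming-window FIR, average-referenced, optionally repaired by
spherical-spline interpolation, and epoched -100..800 ms around stimulus
onset with baseline correction. Component peaks are signed extrema in
a-priori windows: P2 (FCz, 200-280 ms, +), N2 (FCz, 280-380 ms, -),
P3 (CPz, 350-500 ms, +); per-group window overrides are supported.

**Cluster statistics.** Pointwise two-tailed t-tests per channel and
sample (paired for Hit-vs-CR within a group, pooled two-sample for
between-group contrasts on CR-Hit difference waves); a cluster is a
maximal same-sign run of at least 10 consecutive significant samples
(about 19.5 ms at 512 Hz). Channels are treated independently — an
exploratory criterion, not a family-wise-corrected test.

**Inference.** Split-plot repeated-measures ANOVA (one or two within
factors plus an optional between-subjects group) with Greenhouse-Geisser
epsilon, Mauchly's sphericity flag, partial eta squared, Type III
between effects under unequal group sizes, Bonferroni pairwise
comparisons, pooled Cohen's d, and summary-statistic t-tests.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_gait_kinematics.py` simulates a 120-stride walking
block at known ground truth and recovers it:

```
strides analyzed  : 120
stride time       :  1294.2 ms (CV 2.58%)
stride length     :  1231.1 mm (CV 1.73%)
step width        :   193.4 mm (CV 8.07%)
```

(configured: 1300 ms / 1237 mm / 196 mm with CVs 3.0 / 2.7 / 9.0 — the
recovered means sit within sampling error of the generator settings).
And `python examples/03_erp_components.py` builds epochs in which
Correct Rejections carry an enhanced P3 and extracts the peaks:

```
component  electrode  window        Hit        CR
P2         FCz        200-280 ms  +4.54 uV @ 244.1  +3.21 uV @ 246.1
N2         FCz        280-380 ms  -2.18 uV @ 320.3  -2.36 uV @ 337.9
P3         CPz        350-500 ms  +5.83 uV @ 419.9  +9.99 uV @ 416.0
```

The CR P3 exceeds the Hit P3 and the CR-Hit difference topography is
maximal at CPz — the inhibition-related P3 enhancement the analysis is
designed to quantify. `examples/05_full_session.py` writes a complete
synthetic session (plain-text events, motion, EEG and a YAML manifest)
and runs the file-based pipeline, producing per-participant tables,
ANOVA CSVs, a cluster report, and a run log keyed by the configuration
hash.

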