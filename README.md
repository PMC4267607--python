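# ethoseg

Behaviour classification from animal-borne tri-axial accelerometers, built
around one methodological question: when a short acceleration bout is cut
into segments for classification, should the segment boundaries sit at
**fixed time intervals**, or should they **track the behavioural changes**
in the signal itself?

`ethoseg` implements both answers end to end for the standard biologging
setting — 10-second bouts of surge/sway/heave (x/y/z) acceleration at
20 Hz, annotated with an 8-class shorebird foraging ethogram (attack,
body_care, fly, handle, inactive, peck, search, walk) — plus a synthetic
bout simulator so the whole pipeline runs and is testable without any
field data.

## The method

**Variable-time segmentation.** A sequential change-point monitor runs
along the surge (x) axis. Within the current stretch `x[1..t]`, the
generalized likelihood ratio (GLR) statistic for a split at `k`

```
D_k = t·log σ̂²₀ − k·log σ̂²₁ − (t−k)·log σ̂²₂
```

(σ̂² are maximum-likelihood Gaussian variances of the whole stretch and its
two sides) detects mean and/or variance changes. At each new observation
the monitor maximises `D_k` over admissible splits and flags a boundary
when the maximum exceeds a threshold `h_t` calibrated by Monte-Carlo so
that false alarms on a change-free stream occur once per ARL₀ observations
on average (ARL₀ ∈ {500, 5 000, 50 000}; monitoring starts after a
20-observation startup). Fixed-time segmentation tiles the bout with 0.5,
1, 2 or 3 s windows.

**Classification.** Each segment gets its majority behaviour label, is
summarised by 31 statistics — per axis: mean, sd, max, min, skewness,
kurtosis, dominant power-spectrum value and its frequency, trend, dynamic
body acceleration (DBA); plus ODBA, the sum of the three DBAs — and rare
classes are up-sampled with SMOTE (attack/fly/peck ×6, body_care/handle/
search ×2). A 500-tree random forest is trained on a random 70% of
segments and scored on the rest at the level of individual acceleration
records: per class, the fraction of records whose segment-inherited
predicted label matches the annotation. Repeating the split (full scale:
1 000×) yields per-class means with percentile 95% confidence intervals,
and a two-tailed Z-test on logit-transformed per-repetition values
compares the two segmentation approaches.

## Worked example

`examples/04_evaluate_and_compare.py` (40 simulated bouts, 20 resampling
repetitions, a couple of minutes on one core) prints:

```
variable-time (ARL0=50000):
           n_valid_reps   mean  ci_low  ci_high
behavior
attack               20  0.279   0.000    0.764
body_care            20  0.794   0.000    1.000
fly                  18  0.872   0.000    1.000
handle               19  0.606   0.000    1.000
inactive             20  0.973   0.949    0.991
peck                 18  0.000   0.000    0.000
search               20  0.733   0.362    0.967
walk                 20  0.973   0.927    0.998

fixed-time (1 s windows):
           n_valid_reps   mean  ci_low  ci_high
behavior
...
walk                 20  0.910   0.821    0.957

logit Z-test, variable vs fixed (Z > 0: variable better):
   inactive: Z = -0.20  p = 0.838
     search: Z = +1.51  p = 0.131
     handle: Z = +0.26  p = 0.795
```

Reading: `mean` is the average record-level performance of a class over
repetitions (e.g. 97.3% of true-inactive records correctly recovered under
variable-time segmentation); `ci_low/ci_high` bracket the middle 95% of
per-repetition values — rare classes like fly span 0–100% because a single
test split may contain one flight that is either hit or missed;
`n_valid_reps` counts repetitions whose test split contained the class at
all. The Z line compares the two segmentation approaches per behaviour on
the same repetitions. The transient classes attack and peck stay poor in
every setting: they can switch within 0.25 s while the monitor cannot
place boundaries closer than the 1 s startup span — the method's intrinsic
floor.

The other examples each demonstrate one capability: `01` simulator
composition, `02` change-point detection on a known shift, `03`
segmentation + the 31 features, `05` the hourly time budget. A thin CLI
mirrors the stages (`ethoseg simulate | calibrate | segment | featurize |
evaluate | compare | run`).

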