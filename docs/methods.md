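# Methods

This note documents the models, numerical choices and limitations behind
`ethoseg`: what each stage assumes, which knobs matter, and what the
synthetic experiments do and do not demonstrate.

## Sequential GLR change-point monitor

Variable-time segmentation treats the surge (x) signal within a bout as
piecewise-stationary Gaussian. For the current stretch `x[1..t]` and a
candidate split `k`, the statistic

    D_k = t·log σ̂²₀ − k·log σ̂²₁ − (t−k)·log σ̂²₂

is twice the log-likelihood ratio of a two-regime fit against a single
fit, with σ̂² the maximum-likelihood (1/n) variances. It responds to mean
changes, variance changes, and combinations. Each variance is floored at
ε² = 10⁻¹² g² so constant stretches stay finite; the floor is part of the
definition and the test oracles use it identically.

The monitor processes one observation at a time. Admissible splits are
`k ∈ [startup, t−2]`: the lower bound enforces the startup contract (no
boundary within the first 20 observations ≈ 1 s of a stretch; segments
are consequently never shorter than the startup span), the upper bound
leaves two points for the right-side variance. On an alarm at time t the
split argmax is recorded as the boundary and monitoring restarts **at the
boundary**, re-reading the post-change observations with a fresh startup
count — so segments tile the bout exactly. A trailing stretch shorter
than startup + 2 can never alarm and stays attached to the final segment.
Bouts are segmented independently; recordings separated by unmeasured
gaps share no state.

Behaviours can switch faster than the startup span allows boundaries
(0.25 s vs 1 s), so sub-second transients (attack, peck) are structurally
hard for every segmentation setting; this floor is visible in every
evaluation.

## Threshold calibration (ARL₀)

`h_t` is calibrated so that on i.i.d. N(0, 1) streams the conditional
false-alarm hazard at every monitored t equals 1/ARL₀, making the null
run length approximately geometric with mean ≈ startup + ARL₀. The
construction simulates `n_reps` null streams jointly; at each t the
threshold is an upper order statistic of the max-GLR values among streams
that have not yet alarmed, with the order-statistic index randomised so
its expected out-of-sample exceedance probability is exactly 1/ARL₀
(probability integral transform — no distributional assumption). Streams
that cross the threshold are retired, which is what makes later
thresholds conditional on survival. Two regimes need extra care:

* **Large ARL₀.** When fewer than ~ARL₀ streams survive (always, for
  ARL₀ = 50 000), the 1 − 1/ARL₀ level lies beyond the sample; the
  threshold is then an exponential tail fit to the top ~50 excesses.
  Accuracy at 50 000 is therefore model-dependent; what is guaranteed
  (and tested) is pointwise monotonicity in ARL₀.
* **Beyond the table.** Thresholds are tabulated to `max_length`
  (default 400 observations). Past it, the survival-conditioned monitor
  is quasi-stationary, so the table continues at a constant estimated
  from the pooled surviving samples of the last 100 calibrated steps — a
  far larger sample than any single step provides.

Empirically (and re-measured by `scripts/acceptance.py`), thresholds
calibrated to ARL₀ = 500 yield mean null run lengths within a few percent
of 500. Calibration defaults: `n_reps = 2000` for segmenting 200-record
bouts; the acceptance script uses 6 000 reps and `max_length = 800`
because its null streams run far past one bout.

## Summary statistics

Ten statistics per axis plus ODBA (31 total). Conventions where the
standard names underdetermine the arithmetic:

* **sd** is the ddof-1 sample standard deviation; 0 for one sample.
* **skewness/kurtosis** use maximum-likelihood central moments
  (m₃/m₂^1.5, m₄/m₂²); kurtosis is non-excess (Gaussian → 3). A
  zero-variance segment reports 0 for both, and 0 for dps/fdps — the
  degenerate conventions guarantee finite features for any segment length
  ≥ 1, so the classifier never sees missing values and no imputation
  exists anywhere.
* **dps/fdps**: periodogram |DFT(x − x̄)|²/n of the demeaned samples,
  rectangular window, no zero-padding, DC excluded; fdps in Hz, bounded
  by the 10 Hz Nyquist.
* **trend**: least-squares slope of acceleration against time (g/s).
* **dba**: mean |x − x̄| within the segment — the static component is the
  per-segment mean, which is well-defined even for sub-second variable
  segments where a running-mean decomposition is not. ODBA is the sum of
  the three per-axis DBAs.

Scaling behaviour (demeaned samples × c: sd, dba, odba × c; dps × c²;
skew/kurt/fdps invariant) is property-tested.

## Class rebalancing and the forest

SMOTE multiplies each class count by its factor (attack/fly/peck ×6,
body_care/handle/search ×2 by default): synthetic rows are
`parent + u·(neighbour − parent)`, u ~ U(0,1), neighbour uniform among
the parent's k = 5 nearest same-class neighbours (k shrinks to class
size − 1 when needed). Inside resampling loops a class that reaches a
split with fewer than 2 members is passed through untouched rather than
aborting the repetition; the strict API raises instead. By default
oversampling is applied to the training portion only (leakage-safe);
`oversample_stage='before_split'` augments once before splitting — the
order described for the original workflow — in which case synthetic rows
join training folds but only real segments are ever scored.

The classifier is a 500-tree random forest, ⌊√31⌋ = 5 candidate features
per split, unlimited depth, seed-controlled. No feature selection: the
forest sees all 31.

## Evaluation

Record-level performance per class = (records truly c in test segments
predicted c) / (records truly c in test segments); each record inherits
its segment's predicted label, and a brute-force record tally is the test
oracle. Splits are by segment (70/30, unstratified); `split_unit='bout'`
is available to avoid within-bout correlation between folds, off by
default to match the standard workflow. Classes absent from a test split
contribute no sample that repetition (`n_valid_reps` records this), which
is why rare-class confidence intervals can span 0–100%.

Percentile confidence intervals (2.5th/97.5th over per-repetition values)
describe the spread of performance across splits, not the standard error
of the mean: their width grows toward the population quantile span as
repetitions increase. The reported band is widened to include the mean in
the degenerate case where >97.5% of values tie at one extreme. The
comparison between segmentation settings is a two-tailed Z-test on
logit-transformed values clipped to [10⁻³, 1 − 10⁻³] (exact 0% and 100%
have no logit; the clip is configurable), with unpooled (Welch) standard
errors. Zero pooled variance with unequal means raises an error rather
than reporting an infinite Z.

## Synthetic bout generator

Each bout is a semi-Markov dwell sequence rendered to
`baseline + A·sin(2πft + φ) + noise` per axis (φ fresh per dwell), with
shifted-exponential dwell durations (minimum + Exp(mean − minimum), so
the configured mean is exact) and i.i.d. state draws weighted by
`occupancy_weight / duration_mean` — occupancy weights are target **time**
shares. The shipped 8-class set mirrors a shorebird foraging repertoire:
quiet inactive (σ = 0.02 g); 2.5 Hz walking gait; 6 Hz heave-dominant
wingbeat with a strongly pitched posture; irregular aperiodic search and
handle sharing one posture and separated **only** by handle's 1.5×
noise variance (the deliberately confusable pair); brief 0.25–0.75 s
attack (forward surge) and peck (dropped heave) transients. Class groups
differ in x baseline because posture shifts are what make behavioural
transitions visible to an x-axis monitor — the premise of the
segmentation design; a variance-ratio-only contrast of 1.5 is
information-theoretically invisible to the GLR at these dwell lengths,
which is also why search↔handle boundaries are never detected directly
and the pair stays hard. All magnitudes are invented, documented
stand-ins; none is an estimate for a real species.

Known deviations from real accelerometry, hence limits on what passing
tests show: Gaussian noise (no impacts or heavy tails), a single
sinusoid per gait (no harmonics or frequency drift), i.i.d. state
transitions (no attack→handle sequencing), no sensor drift or
calibration error. Two small systematic effects of the bout construction
are expected and tolerated by the tests: bout-end truncation trims
long-dwell classes' realised time share (inactive realises ~38–41%
against a 43% target), and repeated draws of the same state merge into
longer runs (favouring the most probable states). The default occupancy
weights follow a realistic annotation tally (inactive 1177 : walk 853 :
search 299 : handle 169 : body_care 67 : peck 47 : attack 37) except
that fly is set to ~3.5% of time rather than its tally-proportional
<1%: at the 100-bout scale used throughout, the proportional share
yields one or two flight events per dataset, which no classifier can
learn from.

## Scaled-down experiment sizes

The shipped experiments use 100 bouts × 50 repetitions (evaluation), 2
000–6 000 streams (calibration), and 400–1 000 streams (run-length
measurement) — sizes chosen so every stage's statistical check retains a
clear margin while the whole suite runs on a single core in minutes. The
full grid (ARL₀ ∈ {500, 5 000, 50 000} × window lengths {0.5, 1, 2, 3} s,
arbitrary repetition counts) is available through `PipelineConfig.grid`.

## Degenerate inputs and tie-breaks

Majority labelling breaks ties toward the class occurring earliest in the
segment. Fixed windows keep a shorter trailing window so tiling is exact.
Single-record segments use the degenerate feature conventions above.
Identical samples compare as Z = 0, p = 1. Seeds: one master seed derives
per-stage seeds via `SeedSequence(master, spawn_key=(stage, index))`;
every pipeline artefact embeds its config hash and seed.
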