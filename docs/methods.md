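# Methods

## Signal model and synthetic cohorts

A cardiac cycle is modelled as a baseline plus three Gaussian pressure
components — systolic (main) wave, tidal wave, dicrotic wave — parameterised
by amplitude, centre and width (centres and widths as fractions of the
cycle). The superposition of three smooth bumps produces the seven
landmarks A–G analytically: the main peak B is the global maximum, the
dicrotic notch E is the unique local minimum between the tidal and dicrotic
centres, and C/D emerge as a shoulder pair between B and E when the tidal
component is distinct. Gaussians were chosen over hemodynamically motivated
kernels (Windkessel, log-normal) because their extrema are analytic and the
per-sample ground truth needed for detector validation is exact.

The three group presets were fitted (randomised local search on a dense
grid) so that each group's deterministic waveform reproduces that group's
median proportions: t1/T, notch time t4/T, h4/h1, w1/T and w2/T, with
secondary-wave heights (h2/h1 ≈ 0.8, h3/h1 ≈ 0.8, h5/h1 ≈ 0.53) in the
physiological range. Group 3 (highest BNP) therefore has a lower
dicrotic-notch ratio, a shorter cycle (T = 0.717 s vs 0.761 s) and narrower
pulse widths — the clinically observed direction. Note the published group
medians are marginal medians of different subjects, so they are not exactly
mutually consistent (median(w1)/median(T) differs from the median of w1/T
by ≈ 2%); one deterministic waveform can match either but not both, and the
presets favour the ratio features.

A recording concatenates cycles end-to-start (each cycle spans
round(period·fs) samples, so no cumulative drift), with:

* beat-to-beat period jitter, CV 4% — within the normal sinus-arrhythmia
  range;
* between-subject mean-period and secondary-amplitude variation
  (log-normal, CV 8% and 5%). This is deliberately smaller than the
  clinical between-subject spread (the published IQR of T implies CV ≈ 16%);
  the signal simulator prioritises clean per-cycle ground truth over
  population realism, and population-level spread is exercised by the
  feature-level generator instead;
* additive white Gaussian noise (SD 2% of the systolic amplitude) and one
  sinusoidal baseline-wander component (0.2 Hz, 10% of systolic amplitude) —
  the simplest contamination that exercises the detrending stage;
* sampling rate 200 Hz, duration 60 s. The acquisition hardware's rate is
  not public; 200 Hz puts ≈ 150 samples in a cycle, ample for ±1-sample
  landmark ground truth.

The feature-level generator draws each subject's features independently
from normal distributions centred on the group medians, with SD = IQR/1.349
for features with published quartiles and an 8% CV otherwise; covariates use
the published group demographics (age, BMI as mean ± SD; sex as the male
proportion). Independent sampling keeps every configured median exact but
ignores the correlation structure among features (a real h4/h1 correlates
with w1/T, etc.) and samples ratio features directly rather than as
quotients. Consequences: classifier results on these tables measure the
separability implied by the published marginal group contrasts — not the
clinical cohort's joint distribution — and passing tests show the pipeline's
mechanics, not clinical-accuracy replication. That the synthetic RF/DT
accuracies (≈ 92% / 77% on Dataset3) land near the published ones (90.9% /
79.1%) indicates the marginal contrasts carry most of the signal, but the
coincidence should not be over-read.

## Segmentation and fiducial detection

Onsets are detected scale-free: peaks of the first derivative (height ≥ 40%
of the largest upstroke, refractory distance 0.3 s) backtracked to the
nearest preceding local minimum. Consecutive onsets bound half-open cycle
windows; edge cycles are discarded; fewer than three cycles is an error.

Within a cycle, B is the global maximum (earliest index on ties). E is the
most prominent local minimum in the window (t_B + 0.15·T, 0.6·T] — a
conventional systole/diastole split, configurable via `NOTCH_WINDOW`. F is
the first local maximum after E. C and D are the first local-minimum /
last local-maximum pair between B and E; when the tidal wave has merged
into the main wave and no distinct extrema exist, C = D is placed at the
strongest negative-to-positive inflection of the first derivative in that
window and flagged `inferred_cd`. A cycle with no locatable notch is
excluded (not an error). Amplitudes are measured from the cycle's own onset
value — a per-cycle baseline is shift-invariant and robust to residual
wander.

Pulse widths are measured down from the peak: w at fraction f is the total
time the baseline-corrected waveform stays at or above (1 − f)·h1, with
linear interpolation at threshold crossings. This orientation is forced by
the data: the 1/3 width must exceed the 1/5 width.

Per-subject aggregation is the feature-wise median over usable cycles
(≥ 3 required); the published work reports one value per subject without
stating the rule, and the median is the standard robust choice.

On noise-free synthetic cohorts the detector recovers B and E within ±1
sample for 100% of cycles and all duration features within one sample
period; the residual one-sample offset comes from the onset backtrack
landing on the final sample of the preceding cycle.

## Multiscale entropy

Coarse-graining at scale s is the non-overlapping block average; trailing
remainder samples are discarded (output length ⌊N/s⌋). Sample entropy uses
the standard convention: templates of length m and m+1 drawn from the same
N − m starting positions, Chebyshev distance, self-matches excluded,
SampEn = −ln(A/B). Zero matches at either length yields NaN ("undefined"),
which propagates with a warning rather than being capped. The
implementation counts pairs with a KD-tree; tests verify exact equality
with a naive O(N²) double-loop oracle.

Defaults m = 2 and r = 0.15·SD follow the common convention for biosignal
MSE (the source analysis states neither); r is computed once from the
original series and held fixed across scales, so scales are compared on a
common amplitude criterion. The input is the full filtered 60-s recording,
not per-cycle pieces. On synthetic pulse strips the profile rises with
scale (MSE_1 < MSE_5), matching the published ordering of the group
medians, though absolute magnitudes depend on morphology, noise and (m, r)
and are not calibrated to the clinical values.

## Classification and evaluation

SMOTE is implemented directly (interpolation between a minority sample and
one of its k = 5 nearest same-class neighbours, Euclidean metric, uniform
gap); every class is raised to the majority count, so (249, 85, 85) → 747.
The default pipeline balances **before** cross-validation, reproducing the
published procedure — its aggregated confusion matrices have actual-class
totals of 249, which only happens when the folds partition the balanced
set. This ordering leaks information: synthetic minority samples in a test
fold interpolate training-fold neighbours, inflating minority-class recall
(visible in the published tables, where Groups 2 and 3 have the highest
recalls). The `smote_within_folds` option provides the leakage-free
variant, balancing each training fold only.

DT is CART with Gini impurity, unlimited depth; RF uses 100 trees,
√p features per split, unlimited depth; stratified fivefold CV with a
documented seed. All hyperparameters are conventions (none are published)
and are exposed in `classify.RF_PARAMS` / `DT_PARAMS`.

Metrics operate on a counts matrix indexed [predicted][actual]:
precision = diagonal / row total, recall = diagonal / column total,
accuracy = trace / total, F1 = harmonic mean; macro averages are unweighted
means; undefined per-class metrics (zero denominators) are excluded from
macros with a warning. Percentages are formatted at 3 decimals, half-up.

The six published confusion matrices are embedded, and
`verify_printed_tables()` recomputes all 72 printed metric cells. 63
reproduce exactly; the nine audited discrepancies (one swapped
average-precision/recall pair, one recall cell inconsistent with its own
counts, several dependent average cells, and two 0.001 rounding slips) are
reported as explicit diffs and never silently corrected.

Group comparison uses Kruskal–Wallis as the three-group omnibus test (it is
χ²-distributed, the natural three-group extension of the rank-sum test used
pairwise), pairwise Mann–Whitney U for significance flags at P < 0.05,
median (Q1, Q3) with linear-interpolation quartiles, and chi-square for
categorical covariates. Primary P values are unadjusted, as is usual in
clinical descriptive tables; a Holm-adjusted omnibus column is emitted for
transparency.

## Problem sizes and limitations

Tests and the acceptance script use 30-subject signal cohorts for landmark
recovery, full clinical group sizes (249/85/85) for classification, 25
cohort repeats for the RF-vs-DT comparison, and 20 repeats of 300 subjects
for the chance-level null; these sizes give Monte-Carlo error well inside
the asserted margins while keeping a full run to a few minutes.

Known limitations: no arrhythmia or motion artefacts beyond period jitter
and white noise; no multi-channel or pressure-swept acquisition; the
feature-level generator's independence assumption above; MSE magnitudes
are not calibrated to clinical values; classification results on synthetic
cohorts characterise the pipeline, not clinical performance.
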