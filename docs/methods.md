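# Methods

This note documents the models behind each stage of `equiasym`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Scale registry

Four composite equine pain scales are modeled as a flat item registry:
HGS (6 facial items, scores 0–2), EQUUS-FAP (9 facial items, 0–2), EPS
(9 behavior/facial items, 0–4) and CPS (9 behavioral items, 0–3, plus
physiological items).  Only item identity and score range are encoded;
the published scoring rubrics are not reproduced.  The physiological CPS
block is not fully enumerated in print anywhere we model from, so the
registry carries the four named parameters — rectal temperature (`temp`),
heart rate (`hr`), respiratory rate (`rr`) and digestive sounds
(`digest`) — scored 0–3 like the behavioral CPS items and flagged
`is_physiological` so the reliability stage can exclude them (they are
instrument readings, not observer judgements).  That yields 33 behavioral
plus 4 physiological = 37 items.  A packaged CSV additionally ships the
33 published behavioral inter-observer W coefficients; these are
reference *inputs* (used to validate the banding rule), never outputs.

## Synthetic gait signal

Pelvis (and poll) vertical displacement over a stride of period
T = 1/f is modeled as two phase-locked sinusoids

    z(t) = A cos(2ωt) + (d/2) sin(ωt),      ω = 2πf.

Substituting x = sin(ωt) turns this into the quadratic A − 2Ax² +
(d/2)x, so for |d| < 4A the two minima per stride sit exactly at ωt =
π/2 and 3π/2 with values −A + d/2 and −A − d/2: the right-minus-left
minima difference equals d *in closed form*.  This is why a harmonic
model was chosen over a biomechanical one — injected asymmetry is exact
ground truth, not an approximation.  Pelvic roll is a one-per-stride
sinusoid phase-locked to be positive during the right-stance
half-stride; this sign convention is the single shared contract between
the generator and the side-assignment step.  Tubera coxae channels are
the midline signal plus an antisymmetric roll contribution; yaw is
generated and ingested but not used by the default side rule.

Defaults (chosen once, as plausible for sound trot): base amplitude
A = 40 mm (the order of tens of mm of vertical pelvic motion), stride
frequency 1.3 Hz, sampling 200 Hz, 20 strides, additive white Gaussian
marker noise of 2 mm sd.  The model validity bound |d| < 4A admits
asymmetries far beyond the ~60 mm the study design needs.

## Synthetic scores

Scores follow a thresholded-Gaussian ordinal model.  For horse h at an
occasion with normalized true asymmetry a ∈ [0, 1] (occasion asymmetry
divided by the study-wide maximum), observer o's latent value for item i
is

    ℓ = effect_i · a + u_h + ε,   u_h ~ N(0, σ_horse²),  ε ~ N(0, σ_obs²)

cut into the item's score range by strictly increasing per-scale
thresholds (defaults 0.5, 1.5, … — one unit per score step).  Items with
`effect_i = 0` are pure noise; the returned ground truth records the
planted effects, per-horse trajectories and induced sides.  Defaults:
σ_obs = 1 (the "latent sd" unit for effect sizes), σ_horse = 0.3.  The
default effect map emulates the study system — posture items strongest
(EPS/CPS `pos`, 3.0), then temperature, focus, orbital tightening, heart
rate, location, interaction, flehmen/yawning, head position.

Trial structure: 8 horses, 5 occasions (baseline `b0` + 4 post-induction),
3 observers per assessment with observers 1–2 fixed and the third
rotating per horse among three others, pre and post phases per occasion.
Per horse the true total-asymmetry-score trajectory rises linearly from
0 to an individual peak (mean 61 mm, sd 24 mm, floored at 15 mm) at a
random interior occasion and declines toward baseline; three of eight
induced sides are left on average.  A second trot repeat occurs on a
post-induction occasion with probability 0.25 with slightly larger
asymmetry.  What the generator does **not** emulate: rescue analgesia
(and any post-rescue exclusions), drift or serial correlation in
observer behavior (fatigue, learning), item-specific observer biases,
missing assessments, and any nonlinearity between pain and asymmetry.
Passing recovery tests therefore show the *pipeline* is correct and
calibrated under these idealized conditions, not that the scales behave
this way on real horses.

## Kinematic chain

1. **Filter**: 4th-order Butterworth, zero-phase (forward–backward via
   second-order sections), cut-off = 6 × stride frequency (≥ 3 harmonics
   of the dominant 2/stride component; the multiplier is configurable).
2. **Stride frequency**: dominant FFT peak of the mean-removed,
   Hann-windowed pelvis signal within twice the physiologic stride band
   [0.5, 2.5] Hz, refined by parabolic interpolation of the
   log-magnitude spectrum, halved (two oscillations per stride).
3. **Segmentation**: `scipy.signal.find_peaks` with minimum spacing
   0.4/f s and prominence ≥ 20% of the signal IQR; a stride spans three
   successive peaks; incomplete edge strides are implicitly discarded.
4. **Side assignment**: the alternation phase (which halves are 'right')
   is chosen to maximize agreement with the per-half mean-roll signs; if
   every half's mean |roll| is below 0.1°, a warning is emitted and
   plain alternation is used.  Roll only; yaw is deliberately unused.
5. **Minima**: per half-stride, the discrete minimum refined by a
   3-point parabola (ties take the earlier sample; edge-sitting minima
   disqualify the stride, which is counted).  HDmin minima are located
   within the pelvis-defined windows — the poll signal is noisier and is
   not segmented independently.
6. **Aggregation**: HDmin/PDmin per measurement are *means* over
   strides (a median would be the robust alternative; the factor 1/2 on
   HDmin commutes with the mean so its placement is immaterial here).
   Total asymmetry = |HDmin/2| + |PDmin|; the total asymmetry score
   subtracts the horse's baseline total.

Measured operating characteristics (recomputed by the acceptance
script): noise-free recovery error < 1e-4 mm over injections {±5, ±20,
±60} mm × frequencies {1.1, 1.3, 1.5} Hz; with 2 mm marker noise and 20
strides, ≥ 95% of replicates recover PDmin within 2 mm.

## Reliability

Tie-corrected Kendall's W with mid-ranks within each observer,
χ² = m(n−1)W on n−1 df, assessments pooled across horses, occasions and
phases into a single n per item.  Because the third observer rotates,
rating matrices are built by observer *slot* (per-assessment sorted
observer ids); assessments scored by fewer than the modal observer count
are dropped and counted.  Items where every observer is completely tied
have an undefined W (zero denominator) and are flagged degenerate rather
than assigned a conventional value such as 1/m — any such convention
would be an unverifiable guess.  Banding places the boundary values 0.7
and 0.9 in "strong" and 0.5 in "moderate"; no published coefficient
falls on a boundary, so the convention is observationally neutral.
Chi-square p-values are not multiplicity-adjusted.

## Lasso item selection

Rows are (horse, occasion, phase, observer) assessments joined to their
occasion's total asymmetry score; with two trot repeats on an occasion
the pre-assessment pairs with the first and the post-assessment with the
second.  Per horse, occasions after the maximum total asymmetry score
are excluded (the analysis targets the rising phase of the induced
lameness).  Item scores are factor-encoded with level 0 as reference;
horse and observer indicators are penalized like all other columns (an
unpenalized-block solver is available via `fit_at_lambda`, implemented
as exact block coordinate descent).

The solver is scikit-learn coordinate descent on the standardized
problem (objective (1/2N)RSS + λ‖β‖₁, identical parameterization),
along a 100-point geometric path from λ_max = max|x_jᵀy_c|/N down 3
decades, warm-started; 10-fold CV with folds from a seeded permutation,
standardization re-estimated within each training fold; λ_min (not the
1-se rule) is reported, and the final fit at λ_min is re-solved at
KKT-grade tolerance (verified violations < 1e-6, typically ~1e-12).

**Ranking.**  Selected coefficients are reported on the original scale
(mm per indicator) but *ranked* by standardized magnitude
|β_j|·sd(x_j).  A rare score level observed in one or two rows acquires
an inflated mm coefficient (the indicator's sd appears in the
denominator of the back-transformation) and would otherwise top the
list ~10% of the time in planted-effect experiments; the standardized
magnitude is the coefficient of the unit-variance predictor and is the
meaningful "strength of association" ordering.

## MCA and the dimension regression

MCA is correspondence analysis of the complete disjunctive coding: one
row per observer-assessment (configurable to per-assessment median
consensus), one column per observed (item, level) category.  The
standardized residual matrix D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} is SVD-ed;
eigenvalues are squared singular values; raw (uncorrected) inertia
fractions are used (no Benzécri correction), and total inertia obeys
J/Q − 1 exactly.  Dimension signs are fixed by forcing the category with
the largest |coordinate| positive; all interpretation uses
sign(β_dim · coordinate) and is invariant to sign flips.  The Burt
matrix (ZᵀZ) route, whose CA eigenvalues must be the squares of the
indicator-route eigenvalues, serves as the independent numerical
cross-check.

Dimensions explaining ≥ 1% of inertia enter a linear model of the
asymmetry score.  Backward elimination is greedy single-drop by Gaussian
ML AIC computed on the fixed-effects (OLS) profile — eliminating from
~30–40 dimensions requires hundreds of fits, and iterating a crossed
random-effects solver that many times is slow and numerically fragile;
the retained set is then refit once as a linear mixed model with crossed
random intercepts for horse and observer (variance components;
ML), reporting betas, SEs, Wald z and p, and the random-effect
variances.  On singular or failed mixed fits the stage falls back to
OLS with a recorded warning.  Residual lag-1 autocorrelation within
horse is reported as a temporal-dependence diagnostic.

When no grouping factors are supplied (the OLS engine, used by the
calibration experiments), Wald inference for the retained dimensions is
computed **in the full included-dims model** with t-distribution
p-values: the reduced model's own RSS and covariance are both shrunk by
the AIC selection, which inflates the null significance rate at p < 0.01
from the nominal 1% to a measured 1.3–1.7%; full-model inference
restores the nominal rate (measured 0.93–1.0% over 10–20k null
dimension-tests).  MCA row coordinates are orthogonal across dimensions,
so the point estimates coincide with a refit.  The mixed engine keeps
the conventional final-model refit, matching how such models are usually
reported.

## Pipeline and reproducibility

`run_study` executes simulate → kinematics → truncate/pair →
reliability → lasso → MCA + regression, writing every intermediate
artifact (trajectory CSVs, `scores.csv`, `asymmetry.csv`,
`reliability.csv`, `lasso.json`, `mca.json`, `summary.json`,
`report.md`) so each number is traceable.  All randomness flows from the
single config seed through fixed offsets; two runs with the same config
produce byte-identical trees.  The per-horse maximum used for truncation
is an automatic argmax over measurements (the manual determination a
study team would perform is replaced by the argmax; an override can be
expressed by editing the asymmetry table before the analysis stages).

## Validation experiment sizes

The acceptance experiments use: a 6 × 3 grid (injections × frequencies)
for noise-free recovery and 200 seeded replicates for noisy recovery;
100 random 6×3 rating tables for the W oracle; 20 random designs for
KKT plus 100 replicates of the planted-posture experiment (effects of 2
latent sd on EPS and CPS `pos`, observer noise the only latent noise,
n = 160 rows, response = true trajectory); 20 random tables for the MCA
identities; and for regression calibration 1000 null replicates at 20
dimensions × 150 rows (20 000 dimension-tests) plus 100 planted-effect
replicates (β = 30 mm/unit, noise sd 10 mm).  These sizes give tight
binomial intervals while keeping the full validation run to about two
minutes on one CPU.

## Known limitations

- The gait model is harmonic, not biomechanical: no stride-to-stride
  timing variability, no surface or handler effects, no front-limb
  compensation patterns; walk, lunging and soft-surface conditions are
  out of scope.
- Side assignment relies on the roll sign convention shared with the
  generator; on real data the convention must be established against a
  reference measurement system.
- The ordinal score model is symmetric and stationary; real observers
  drift, anchor and interact with item order.
- Truncation at the maximum score assumes the maximum is well-defined;
  ties take the earliest occasion.
- The lasso provides no post-selection inference, and the
  dimension-regression calibration statement applies to the OLS engine;
  mixed-model Wald z p-values carry the usual small-sample caveats.
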