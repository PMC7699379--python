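# equiasym

Movement-asymmetry quantification and pain-scale item analysis for
induced equine orthopedic pain.

Mild orthopedic pain in horses is hard to assess at rest: lameness is
usually graded during movement, while composite pain scales score
behaviors and facial expressions in the box stall.  `equiasym`
re-implements, as a tested and reusable pipeline, the analysis linking
the two: objective movement asymmetry from motion-capture marker
trajectories is used as the pain proxy, and the items of four equine
pain scales — the Horse Grimace Scale (HGS), the Equine Utrecht
University Scale of Facial Assessment of Pain (EQUUS-FAP), the Equine
Pain Scale (EPS) and the Composite Pain Scale (CPS), 37 items in all —
are evaluated for inter-observer reliability and for their ability to
predict that proxy.  A synthetic-data module emulates the whole study
design (8 horses, baseline plus post-induction occasions whose asymmetry
rises to an individual maximum and declines, 3 observers per
assessment), so every stage is testable against known ground truth
without any animal data.

It is aimed at researchers in veterinary gait biomechanics and animal
welfare who want the statistical machinery of such a study — or its
power/calibration properties — without re-deriving it.

## The quantities at the core

**Movement asymmetry.**  At trot the pelvis describes two vertical
oscillations per stride, one per diagonal stance, and reaches a lower
position during the sound hindlimb stance.  After zero-phase 4th-order
Butterworth filtering (cut-off adjusted to the stride frequency) and
stride segmentation by peak detection on the tubera sacrale signal, the
per-stride difference between the two displacement minima is computed
for the head (HDmin) and pelvis (PDmin), signed so that left-sided
asymmetries are negative.  A measurement's total asymmetry is

    total = |HDmin / 2| + |PDmin|        [mm]

and the **total asymmetry score** is its change from the horse's
baseline measurement — the pain proxy for all downstream analyses.

**Reliability.**  Per item, agreement among the m = 3 observers over n
assessments is the tie-corrected Kendall coefficient of concordance

    W = 12 S / ( m²(n³ − n) − m Σⱼ Tⱼ ),     χ² = m (n − 1) W,  df = n − 1

banded as very strong (W > 0.9), strong (0.7–0.9), moderate (0.5–0.7) or
weak (< 0.5).

**Item selection.**  Factor-encoded item scores (one indicator per score
level, e.g. `eps_pos3`) plus horse and observer indicators predict the
total asymmetry score in a lasso, min (1/2N)‖y − β₀ − Xβ‖² + λ‖β‖₁,
with the λ minimizing the mean 10-fold cross-validated error selected.

**Co-occurrence structure.**  Multiple correspondence analysis of the
complete disjunctive coding of all items; the dimensions explaining
≥ 1% of the inertia enter a linear mixed model of asymmetry (random
intercepts for horse and observer), reduced by backward elimination on
AIC; categories loading on significant (p < 0.01) dimensions are
reported with the sign of their association.

## Worked example

```
$ python examples/01_simulate_and_measure_gait.py
PDmin (pelvis):   -29.99 mm   (injected -30.0)
HDmin (head):     -11.94 mm   (injected -12.0)
total asymmetry:   35.96 mm   (|HDmin/2| + |PDmin|)
strides used:    19
```

A horse simulated with a 30 mm left-sided pelvic minima difference and
2 mm of marker noise is recovered to within a few hundredths of a mm;
the negative sign says the left-stance minimum is the shallower one,
i.e. the horse unloads the left hindlimb.  The other examples walk
through each capability — `02_reliability.py` (per-item W and bands),
`03_lasso_item_selection.py` (planted posture effects are the top-ranked
columns), `04_mca_dimensions.py` (a significant dimension grouping
posture, focus and temperature categories with positive association)
and `05_full_study.py`, which runs everything end to end:

```
$ python examples/05_full_study.py
measurements: 46; assessments: 80
...
top lasso-selected items:
  hgs_orb2       +14.98
  cps_temp3      +14.47
  eps_pos4       +20.72
...
significant MCA dimensions: [1, 2, 4, 7, 8, 11, 12, 28, 32]
```

The same pipeline is scriptable from a shell:

```
equiasym run-all --out-dir run1 --seed 2
equiasym asymmetry --trajectories run1/trajectories --baseline-occasion b0 --out asym.csv
equiasym reliability --scores run1/scores.csv --out reliability.csv
equiasym select-items --scores run1/scores.csv --asymmetry run1/asymmetry.csv --seed 1 --out lasso.json
equiasym mca --scores run1/scores.csv --asymmetry run1/asymmetry.csv --out mca.json
```

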