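"""Which scale items predict movement asymmetry?  Lasso with 10-fold CV.

Latent effects are planted on the two posture items (EPS and CPS 'pos'):
their scores rise with the horse's true asymmetry, all other items are
noise.  Item scores are factor-encoded (one indicator per score level,
e.g. eps_pos3), horse and observer indicators are added, and the penalty
minimizing the mean cross-validated error is selected.  The top-ranked
columns should be posture levels.
"""

import pandas as pd

from equiasym import default_design, load_scales, simulate_scores
from equiasym.selection import build_design, fit_lasso_cv, select_items

scales = load_scales()
design = default_design(
    seed=3,
    horse_effect_sd=0.0,
    item_effects={("EPS", "pos"): 2.0, ("CPS", "pos"): 2.0},
)
scores, truth = simulate_scores(design, scales)
asymmetry = pd.DataFrame(
    [
        {"horse": h, "occasion": occ, "repeat": 1,
         "score_mm": truth.asymmetry_trajectory[h][oi]}
        for h in design.horses
        for oi, occ in enumerate(design.occasions)
    ]
)

dm = build_design(scores, asymmetry, scales)  # truncates at per-horse max
fit = fit_lasso_cv(dm, n_folds=10, seed=3)
selection = select_items(fit, dm)

print(f"lambda_min = {fit.lambda_min:.3f}  "
      f"({len(selection.items)} item columns selected)")
print("\ntop item columns (coefficient in mm per indicator):")
for col, coef in selection.items[:5]:
    print(f"  {col:12s} {coef:+8.2f}")
print("\nhorse/observer effect columns kept:")
for col, coef in selection.effects[:4]:
    print(f"  {col:12s} {coef:+8.2f}")
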