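"""Inter-observer reliability of pain-scale items with Kendall's W.

Three observers score 37 items from four pain scales for 8 horses over a
full induction study; each item's tie-corrected coefficient of
concordance W is computed over all assessments, with a chi-square test
and the agreement band (very strong > 0.9, strong 0.7-0.9, moderate
0.5-0.7, weak < 0.5).  Physiological CPS items are excluded: they are
instrument readings, not observer judgements.
"""

from equiasym import default_design, load_scales, simulate_scores
from equiasym.reliability import reliability_report, reliability_table

scales = load_scales()
design = default_design(seed=1)            # 8 horses, 3 observers, 5 occasions
scores, _ = simulate_scores(design, scales)

results = reliability_report(scores, scales)
table = reliability_table(results).sort_values("W", ascending=False)

print(table.head(8).to_string(index=False,
                              float_format=lambda v: f"{v:.3f}"))
print()
print(f"{len(table)} behavioral items analyzed; higher W = closer agreement")
print("between the three observers' rankings of the same assessments.")
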