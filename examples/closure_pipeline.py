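"""Full closure pipeline: fixtures -> images -> ROI -> 2-SD -> survival.

Generates contrast-MRI-like image series for all four study groups from the
canonical closure fixtures, quantifies each focal spot with a 3x3-voxel ROI,
classifies permeability by the 2-SD contralateral rule, and compares closure
curves by log-rank at the Bonferroni-corrected threshold (0.05/4 = 0.0125).
"""

from fusbbb import bonferroni_threshold, compare_all_groups
from fusbbb.pipeline import run_study_pipeline

table, curves = run_study_pipeline(seed=17)

print("percent of foci permeable at 0/6/12/20 h:")
for group, curve in curves.items():
    pct = " / ".join(f"{p:5.1f}" for p in curve.percent_permeable)
    print(f"  {group:12s} {pct}")

pairs = [
    ("TgCRND8-VT", "TgCRND8-PBS"),
    ("nonTg-VT", "nonTg-PBS"),
    ("TgCRND8-PBS", "nonTg-PBS"),
    ("TgCRND8-VT", "nonTg-VT"),
]
print(f"\nlog-rank comparisons (threshold {bonferroni_threshold(0.05, 4)}):")
for r in compare_all_groups(table, pairs):
    star = "*" if r.significant else " "
    print(f"  {r.comparison:28s} chi2 = {r.chi_square:6.2f}  p = {r.p_value:.4f} {star}")
# A significant pair means its closure-time distributions differ; the treated
# transgenic group closes markedly faster than its untreated counterpart.
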