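"""Sequentially plan experiments over a discrete condition grid.

A synthetic 6 x 5 x 6 x 2 full-factorial screen (360 conditions, 10
metrics, half maximized and half minimized) stands in for a multi-metric
assay panel.  The planner maps continuous optimizer proposals to the
nearest not-yet-run condition and re-normalizes the observed outcomes
into an ideal-point distance after every round.
"""

from paddyfield import run_campaign, synth_screen

table = synth_screen(seed=42)
n_experiments, campaign = run_campaign(table, threshold=5, s_max=10, seed=3)

print(f"grid size: {table.n_conditions} conditions")
print(f"globally best condition index: {campaign.target_index}")
print(f"experiments until it was run: {n_experiments}")
print(
    "The planner needed a fraction of the grid to reach the best condition "
    "because good conditions share factor levels: fitness around observed "
    "good conditions pulls sampling toward the optimum."
)
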