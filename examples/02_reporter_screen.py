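"""Simulate a dual-luciferase reporter screen and call repression.

One reporter per effective miRNA dose (cpm), four sub-20-cpm reporters
forming the group control, and empty-vector wells. The analysis normalises
Renilla/Firefly ratios to the empty vector, pools the group control, and
tests each reporter against it (unpaired Student's t, stars, and a
"detected" flag requiring significance plus a mean below the control band).
"""

import numpy as np

from miraudit import reporter_assay as ra
from miraudit.synthetic_data import SimulationConfig, simulate_reporter_screen

cfg = SimulationConfig(rng_seed=42)
plates, truth, profile = simulate_reporter_screen(
    [0, 50, 150, 500, 2000, 8000, 30000], cfg
)

activities = ra.relative_activity(plates)
dose_reporters = [r for r in truth.reporter_id if "dose" in r]
band = ra.build_group_control(activities, profile, cutoff=20.0,
                              exclude=dose_reporters)
seed_table = {r.reporter_id: (r.exact_cpm, r.seed_cpm)
              for r in truth.itertuples(index=False)}
calls = ra.call_repression(activities, band, seed_table)

print(f"group control: {len(band.member_ids)} reporters, "
      f"band [{band.lower:.3f}, {band.upper:.3f}]")
cols = ["target_mirna", "seed_cpm", "mean_activity", "p_value", "stars",
        "detected"]
print(calls[cols].round(4).to_string(index=False))
summary = ra.detection_vs_expression(calls)
print("\nDetection by effective dose band:")
print(summary.table.to_string(index=False))
# Reporters below ~200 cpm sit inside the control band (no detectable
# repression); far above 1000 cpm activity collapses and repression is
# called with high significance.
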