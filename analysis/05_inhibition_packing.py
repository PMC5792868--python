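#!/usr/bin/env python
"""Saturation (jamming) density of inhibited colonization.

Runs the sequential-inhibition sampler to give-up saturation across a range
of inhibition distances and checks the r^-2 packing law with windows scaled
proportionally to r.  Writes results/packing.csv.
"""

import numpy as np
import pandas as pd

from barkspat.geometry import Window
from barkspat.ssi import jamming_density

rng = np.random.default_rng(3)
GIVEUP, REPS = 5000, 8

rows = []
for r in (1.25, 2.5, 5.0):
    side = 40.0 * r  # window scales with r so edge effects cancel
    mean, se = jamming_density(Window.rectangle(side, side), r,
                               giveup=GIVEUP, reps=REPS, rng=rng)
    rows.append(dict(r_cm=r, window_cm=side, density_dm2=mean, se=se,
                     density_times_r2=mean * r * r))
    print(f"r = {r:4.2f} cm: saturation {mean:6.2f} +- {se:.2f} holes/dm^2 "
          f"(density x r^2 = {mean * r * r:.1f})")

table = pd.DataFrame(rows)
table.to_csv("results/packing.csv", index=False)
ratio = table.density_dm2.iloc[1] / table.density_dm2.iloc[2]
print(f"density(2.5 cm) / density(5 cm) = {ratio:.3f} (r^-2 law predicts 4)")
print("note: the field attack density (0.4-1.2 holes/dm^2) stays far below "
      "this packing bound, so inhibition alone does not set the plateau")
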