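"""Persistence times and dynamicity with and without the perturbation.

Compares three stochastic regimes of a 26-cell column over 300 h
(statistics on the final 150 h): uncoupled cells, lateral inhibition
alone, and lateral inhibition plus the differentiation-based
perturbation (DBP).
"""

import numpy as np

from hesdyn import (DBPConfig, LatticeSpec, ModelParams, SimConfig,
                    analyze_cells, simulate)

column = LatticeSpec(26, 1)
conditions = [
    ("uncoupled", ModelParams(coupling_enabled=False), None),
    ("LI only  ", ModelParams(p0_li=4000.0), None),
    ("LI + DBP ", ModelParams(p0_li=4000.0), DBPConfig()),
]

for label, params, dbp in conditions:
    highs, lows, dcs = [], [], []
    for seed in range(5):
        traj = simulate(params, column, SimConfig(duration_h=300.0, seed=seed),
                        dbp=dbp, eps_ratio=1.5)
        cells, runs = analyze_cells(traj, last_h=150.0)
        highs.append(runs["high"])
        lows.append(runs["low"])
        dcs.append(cells["dc"].mean())
    high = np.concatenate(highs)
    low = np.concatenate(lows)
    stuck = np.mean(np.concatenate([high, low]) >= 149.0)
    print(f"{label}: mean persistence high/low = "
          f"{high.mean():5.1f}/{low.mean():5.1f} h, "
          f"dynamicity = {np.mean(dcs):.2f}, "
          f"stuck whole window: {100 * stuck:.1f}% of runs")

# Uncoupled cells switch every few hours (noise and ultradian cycles);
# lateral inhibition freezes cells into high/low states for tens of hours
# with some stuck for the entire window; the perturbation from
# differentiating neighbours reorganises the pattern on an intermediate
# ~10 h timescale and removes the stuck fraction -- slow switching with
# fast oscillations nested inside it.
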