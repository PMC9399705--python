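"""How patterning regime shapes the rate and spread of differentiation.

Runs the probabilistic differentiation selection for 800 h on a 26-cell
column in three regimes and reports the population rate and the shape of
the per-cell event-frequency distribution.
"""

import numpy as np

from hesdyn import (DBPConfig, LatticeSpec, ModelParams, SimConfig,
                    differentiation_rate, per_cell_frequency, simulate)

column = LatticeSpec(26, 1)
conditions = [
    ("stationary pattern", ModelParams(p0_li=3500.0),
     DBPConfig(perturbation_enabled=False)),
    ("dynamic pattern   ", ModelParams(p0_li=3500.0), DBPConfig()),
    ("uncoupled         ", ModelParams(coupling_enabled=False),
     DBPConfig(perturbation_enabled=False)),
]

for label, params, dbp in conditions:
    traj = simulate(params, column, SimConfig(duration_h=800.0, seed=3),
                    dbp=dbp, eps_ratio=1.5)
    rate = differentiation_rate(traj.events, 26, 800.0)
    freqs = per_cell_frequency(traj.events, 26, 800.0)
    quiet = np.mean(freqs < 0.2 * freqs.mean())
    print(f"{label}: {rate:.2f} % of population per hour; "
          f"{100 * quiet:.0f}% of cells near-silent")

# A frozen pattern differentiates fastest but only in its fixed
# low-expression rows (bimodal per-cell frequencies, many near-silent
# cells). Perturbation-driven switching spreads events across all rows at
# a somewhat lower rate. Without coupling the expression contrast -- and
# with it the differentiation rate -- collapses.
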