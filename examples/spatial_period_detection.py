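"""Spatial periodicity of lateral-inhibition patterns.

Simulates a 26-cell dorsoventral column deterministically with
nearest-neighbour coupling only, then with protrusion-mediated distal
coupling, and measures the dominant spatial period of the final
expression profile with the Fisher g-test.
"""

from hesdyn import LatticeSpec, ModelParams, SimConfig, power_spectrum, simulate

params = ModelParams(p0_li=4000.0)
cfg = SimConfig(duration_h=200.0, seed=1, stochastic=False,
                record_interval=60.0)

for label, spec, eps in [
    ("proximal only      ", LatticeSpec(26, 1, include_distal=False), 0.0),
    ("proximal + distal  ", LatticeSpec(26, 1), 1.5),
]:
    traj = simulate(params, spec, cfg, eps_ratio=eps)
    res = power_spectrum(traj.p[-1, :, 0])
    print(f"{label}: dominant period {res.peak_period:.2f} cells, "
          f"g = {res.g:.2f}, p = {res.p_val:.3f}")

# Nearest-neighbour inhibition alone makes the classic alternating
# (two-cell) pattern; extending signalling to second-ring cells at 1.5x
# efficiency lengthens the period to three to four cells, the periodicity
# observed along the dorsoventral axis of the neural tube.
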