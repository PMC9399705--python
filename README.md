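# hesdyn

Stochastic modelling of **dynamic HES5 spatial patterning** in neural
progenitor tissue: coupled delayed auto-repression oscillators on a
hexagonal cell lattice, linked by Notch/Delta lateral inhibition with
protrusion-mediated distal signalling, perturbed by differentiating
cells — together with the statistics needed to tell *periodic* and
*mobile* patterns apart.

## The problem

In the developing neural tube, the transcription factor HES5 oscillates
in individual progenitors (ultradian, ~3 h period) and is organised in
space into microclusters with a dorsoventral periodicity of three to
four cells whose high/low domains *switch places* over hours — unlike
classic lateral inhibition, which freezes into a static
salt-and-pepper pattern. `hesdyn` implements a multicellular model that
reproduces both features with two additions to plain lateral
inhibition:

1. **Distal signalling** — second-ring neighbours reached by cellular
   protrusions, weighted by an efficiency ratio `eps_d/eps_p`, which
   lengthens the spatial period from two cells to three–four; and
2. **Differentiation-based perturbation (DBP)** — low-HES5 cells
   stochastically commit to differentiation and transiently boost the
   HES5 transcription rate of contacting cells (fold change `F_pert = 3`
   for `T_pert = 7 h`, the Delta/Mib1 signature of a delaminating cell),
   which unfreezes the pattern and drives regular state switching.

## The model

Per cell (row i, column j):

    dm/dt = -mu_m m + alpha_m * H_auto(p(t - tau_auto)) * H_LI(pbar(t - tau_LI)) + eta_m
    dp/dt = -mu_p p + alpha_p m + eta_p

with decreasing Hill functions `H(x) = 1/(1 + (x/P0)^n)`, `pbar` the
capacity-normalised weighted mean protein of the signalling neighbours,
and chemical-Langevin noise terms (variance = sum of reaction
propensities), integrated by Euler–Maruyama with a delay buffer.
Analysis statistics: Fisher g-test spatial periodicity and *occurrence*,
the *dynamicity coefficient* `Dc = 2 min(alpha_up, alpha_down)`,
persistence times of smoothed high/low states, and population /
per-cell differentiation rates. See `docs/methods.md` for details and
defaults.

## Worked example

```sh
python examples/spatial_period_detection.py
```

prints

```
proximal only      : dominant period 2.00 cells, g = 0.51, p = 0.003
proximal + distal  : dominant period 3.25 cells, g = 0.32, p = 0.138
```

— nearest-neighbour inhibition alone locks into the two-cell
alternating pattern, while distal coupling at 1.5x efficiency produces
the three-to-four-cell periodicity seen in tissue (in the smooth
deterministic profile the period mass spreads over adjacent modes;
stochastic runs give a significant mean period of ~3.5 cells).

```sh
python examples/dynamic_switching.py
```

prints

```
uncoupled: mean persistence high/low =   3.4/  3.7 h, dynamicity = 0.91, stuck whole window: 0.0% of runs
LI only  : mean persistence high/low =  21.7/ 23.2 h, dynamicity = 0.23, stuck whole window: 4.7% of runs
LI + DBP : mean persistence high/low =  10.1/ 11.4 h, dynamicity = 0.70, stuck whole window: 0.2% of runs
```

— lateral inhibition freezes cells into long-lived states (a fraction
stuck for the entire 150 h window); the differentiation perturbation
restores switching on an intermediate ~10 h timescale with fast
ultradian oscillations nested inside, and removes the stuck fraction.
Further examples cover differentiation-rate contrasts
(`differentiation_rates.py`) and the parameter-space classification of
dynamic patterning (`parameter_sweep.py`). A thin CLI wraps the same
library calls: `hesdyn simulate | analyze | sweep | fixtures --help`.

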