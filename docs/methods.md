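# Methods

## Model

`hesdyn` simulates HES5 expression in a sheet of neural progenitor cells
arranged on a hexagonal lattice. Each cell carries two state variables,
HES5 mRNA `m` and protein `p` (molecule counts), obeying delayed
negative-feedback kinetics coupled between cells by Notch/Delta lateral
inhibition:

    dm/dt = -mu_m m + alpha_m * H_auto(p(t - tau_auto)) * H_LI(pbar(t - tau_LI)) + eta_m
    dp/dt = -mu_p p + alpha_p m + eta_p

`H_auto` and `H_LI` are decreasing Hill functions
`1 / (1 + (x / P0)^n)`: the first is transcriptional auto-repression by
the cell's own protein, delayed by `tau_auto`; the second represents
lateral inhibition, driven by the weighted mean protein `pbar` of the
cell's signalling neighbours. Noise follows the chemical Langevin form:
each species receives Gaussian white noise with variance equal to the sum
of its production and degradation propensities, so fluctuations scale
with the square root of the reaction fluxes. Integration is
Euler–Maruyama with a constant-history delay buffer; negative excursions
(possible for the Langevin approximation at low copy number) are clamped
to zero, a negligible correction at the ~10^4-molecule protein levels the
default parameters produce.

Default kinetics (single-cell values inferred for mouse neural-tube
progenitors): `alpha_m = 0.77 /min`, `alpha_p = 26 /min`, mRNA half-life
30 min, protein half-life 90 min, `P0_auto = 25000` molecules,
`n_auto = 3.5`, `n_LI = 3`, `tau_auto = 30 min`, `tau_LI = 0` (a delayed
LI variant is supported through `tau_li`). The LI threshold `P0_LI`
(smaller = stronger coupling) and the distal efficiency (below) are the
two parameters the sweeps explore.

## Lattice and signalling reach

Rows run dorsoventrally; even rows are offset by half a cell. Each cell
has up to six *proximal* (touching) neighbours and, when
protrusion-mediated signalling is enabled, four *distal* second-ring
neighbours two rows up/down. Distal contacts are weighted by the
efficiency ratio `eps_d/eps_p` (default 1.5); the exact distal offsets
are configurable (`LatticeSpec.distal_offsets`). A single-column lattice
reduces to two proximal (i±1) and two distal (i±2) neighbours.

The neighbour input is `pbar = (1/|N|) * sum(eps_k * p_k)`. `|N|` is the
**full contact capacity** of the geometry — 10 with distal signalling,
6 without — for every cell, not the per-cell realised neighbour count: a
simulated strip or boundary cell is treated as embedded in surrounding
tissue whose unsimulated contacts contribute no signal, so missing
neighbours dilute the input rather than renormalise it. For interior
cells of a full 2-D lattice the two conventions coincide. This choice is
load-bearing: renormalising instead (available as
`coupling_norm="count"`) makes the effective coupling in a single column
2.5x stronger at the same `P0_LI`, drives the patterns to extreme
contrast in which adjacent high-expressing pairs are linearly unstable
(only isolated high cells survive), freezes the pattern almost
permanently, and leaves the transcription-rate perturbation unable to
flip any cell. Under the capacity convention the same printed parameter
values produce moderate-contrast two-high/two-low-type patterns, and all
of the switching phenomenology below follows with no further tuning.

## Differentiation-based perturbation (DBP)

Differentiation is a probabilistic event process on top of the dynamics.
At every step each cell below the differentiation threshold (the
instantaneous population-mean protein) fires with hazard
`R * (D_thresh - p)/D_thresh` per hour, discretised as `hazard * dt`.
A firing cell defines a perturbation group — itself plus a random
adjacent cell in 1-D; a 2x2 block in 2-D — whose transcription rate is
multiplied by `F_pert = 3` for `T_pert = 7 h`, representing the elevated
Delta/Mib1 signalling that a newborn differentiating cell exerts on the
progenitors it touches before delaminating. Cell movement is not
modelled. Event selection can run with the perturbation disabled (the
stationary-pattern control), and a refractory variant (no re-selection
inside an active group) is available but off by default: the plain
hazard is applied to every sub-threshold cell each step.

The rate constant `R` is not fixed by the kinetic parameters; it only
sets the absolute event-rate scale, and (with the perturbation disabled)
event counts are exactly linear in it. The packaged default
`R = 0.2026 /h` was calibrated once so that the stationary-pattern
reference condition (`P0_LI = 3500`, `eps_d/eps_p = 1.5`, 26-cell
column, 800 h) yields a population differentiation rate of 5.5% of cells
per hour, the scale reported for strongly patterned neural-tube tissue
models; every other condition then uses the same value, so rate
contrasts between regimes are calibration-independent.

## Pattern statistics

**Spatial periodicity.** A spatial signal is the protein profile along
the rows at one recorded time (for 2-D lattices, one-cell-wide selection
regions average the two straddling cells on offset rows). Each signal is
mean-removed and Fourier transformed; the tested band holds the
two-sided periodogram mass at spatial frequencies `k/I`,
`k = 1..floor(I/2)` — interior ordinates carry their ±frequency pair
(factor 2) while the Nyquist ordinate of an even-length signal appears
once, keeping the band Parseval-consistent. Fisher's g statistic (peak
over sum) is referred to the exact null
`P(g_noise > g) = sum_j (-1)^(j-1) C(N,j) (1 - j g)^(N-1)`. Equal
weighting of the Nyquist ordinate would inflate the 5% test to a
measured size of 6.3% on 26-cell white-noise profiles (the Nyquist
ordinate is chi-squared with one degree of freedom, not exponential);
the two-sided band brings the measured size to 5.8%, and the residual
mild anticonservatism is a known limitation. Dropping the Nyquist bin
entirely would be exactly calibrated but blinds the test to two-cell
alternating patterns, the signature output of nearest-neighbour lateral
inhibition, so it is not done. The dominant period is reported as
`I/k_peak` cells without interpolation; *occurrence* is the fraction of
signals with `p < 0.05`.

**Temporal switching.** Per-cell traces over the analysis window
(default: final 150 h of a 300 h run, discarding the patterning
transient) are smoothed with an order-1 Savitzky–Golay filter, 165-min
frame (frame length `round(165/dt)` forced odd), then segmented at one
relative threshold per simulation — the population-mean protein over the
window, so the measure tracks high/low structure at any coupling
strength. Runs strictly above threshold are high states; exact-threshold
samples count low (a measure-zero tie-break). Persistence times are the
run durations; runs censored by the window edges are kept at their
observed length, so a never-switching cell contributes one 150 h run —
which is how frozen patterns appear as a mass at the window length in
persistence histograms. The dynamicity coefficient is
`Dc = 2 min(alpha_up, alpha_down)` with `alpha` the time fractions in
each state: 0 for stationary traces, 1 for balanced switching. For a
perfect switcher observed for a half-integer number of cycles `n_c`, the
expected value is `2(n_c - 1/2)/(2(n_c - 1/2) + 1)`, which the tests
verify empirically.

**Parameter sweeps.** Replicated simulations on a
`P0_LI x eps_d/eps_p` grid are summarised per point by the
replicate-mean significant spatial period, occurrence, and cell-mean
dynamicity; a point supports *dynamic spatial patterning* when
`period > 3`, `occurrence > 0.4` and `Dc > 0.4`, all strict. Replicate
seeds derive deterministically from a master seed and the grid indices,
so any subset reruns identically.

## Numerical choices

* `dt = 1 min` (delays are integer multiples); convergence checked
  against `dt = 0.5 min` (deterministic trajectories agree to <5%), and
  uncoupled fluctuation statistics are step-size independent down to
  0.25 min.
* Delay history initialised constant at the initial condition.
* Initial conditions: per-cell protein uniform in `[0.5, 1.5] x P0_auto`,
  mRNA at translation balance; seedable and configurable.
* Four RNG streams (initial condition, Langevin noise, event selection,
  group choice) spawn independently from one seed, so switching the
  perturbation on/off or setting `F_pert = 1` leaves the dynamics stream
  untouched (bit-identical trajectories, a tested invariant).
* Overlapping perturbation windows extend to the latest expiry.

## Problem sizes and what the tests show

The shipped tests use desk-scale protocols: 26-cell columns, 200–800 h
of simulated time, 5–10 replicates for the persistence and rate
contrasts, and a 5x5 grid with 5 replicates for the sweep property;
the acceptance script scales the persistence protocols to 30 replicates.
The synthetic-signal generator (sines, square waves, white noise)
validates the statistics independently of the simulator; it emulates
idealised periodic or null inputs, not the amplitude drift, spatial
heterogeneity or measurement noise of imaging data, so passing tests
demonstrate correctness of the estimators and the model's internal
phenomenology, not agreement with any particular experimental recording.

## Known limitations

* With lateral inhibition only (no perturbation), pooled persistence
  times measure ~21–23 h here; regimes with somewhat longer freezing
  (~27–31 h) are reported for closely related models, and the uncoupled
  differentiation rate lands at ~0.85%/h against a reported ~0.7%/h —
  both within roughly 25% but sensitive to the coupling-normalisation
  and threshold conventions described above.
* The Fisher test's residual size of ~5.8% at the 5% level on 26-cell
  profiles (see above).
* No cell movement, division, or removal of differentiated cells; no
  cis-inhibition or lateral-induction ligands; protrusion contacts are
  static weights rather than dynamic extensions.
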