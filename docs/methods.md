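# Methods

This note documents the models, conventions, and design choices behind
`dendrofire`: what is simulated, which parameters matter, what the
synthetic data do and do not emulate, and where the numerical edges are.

## Morphology and morphometry

Morphologies are standard 7-column SWC point tables (coordinates and radii
in µm; column 6 is the radius). Validation enforces a single root, strictly
positive radii, known structure codes (1 soma, 2 axon, 3 basal, 4 apical),
and topological sorting (`parent_id < id`), which also excludes cycles.
The *section partition* groups non-root points into maximal unbranched
same-structure runs; every section stores its proximal attachment point so
inter-point geometry is complete, and each inter-point segment's diameter
is attributed to its **distal** endpoint (the SWC reading: a point's radius
describes the cable arriving at it). A stem section attached to the soma
therefore never inherits the soma's radius.

Soma conventions differ across archives; both the one-point (sphere) and
multi-point forms are accepted and reduced internally to a cylinder of
equal lateral area (`L = D = 2r` for a sphere), which is what the
simulator uses as the isopotential somatic compartment.

Five features are computed per tree (a "tree" is the full same-class
forest of a cell — a basal tree with several stems is one tree):

| feature | definition | units |
|---|---|---|
| total length | Σ section lengths | µm |
| volume | Σ π·Lᵢ·(Dᵢ/2)² over sections | µm³ |
| median diameter | median of per-section length-weighted diameters | µm |
| branch number | topological segments (stem→fork, fork→fork, fork→tip) | — |
| MEP | mean over tips of Σ lᵢ/λᵢ along the tip→stem-root path | — |

with `λᵢ = √(bᵢ·rₘ/(2·rₐ))`, `rₘ = 30 kΩ·cm²`, `rₐ = 210 Ω·cm` held
constant for the MEP (the position-dependent membrane resistance used in
simulation deliberately does not enter this passive summary). For a
radius of 1 µm, λ ≈ 845.2 µm; a single cable of exactly that length has
MEP = 1, which is the calibration fixture used in the tests. Paths stop
at the stem root (the somatic attachment), not inside the soma, and an
even section count takes the midpoint of the two central diameters.

Grafting translates each donor subtree rigidly so its root keeps its
original offset from its attachment point; all inter-point distances are
conserved exactly, so every per-tree feature of a chimeric cell equals
the donor's (to floating-point roundoff introduced by the coordinate
translation, below 1e-12 relative in practice).

`split_section` refines the partition without moving any geometry. With
the section-level cylinder reduction, feature invariance under splitting
is exact only for sections of uniform owned radius; all shipped
generators produce such sections (taper is applied at branch points), and
the inserted point takes the distal radius of the split segment. For
reconstructions with within-section taper the section-level reduction is
split-dependent at the scale of the taper — a limitation inherited from
reducing tapered cables to cylinders.

## Passive membrane and channels

Soma and axon have uniform `Rm = 30 kΩ·cm²`; dendritic `Rm` decreases
sigmoidally with path distance `x` (µm) toward half the somatic value:

    basal:  Rm(x) = 30 − 15/(1 + e^((10−x)/5))      [kΩ·cm²]
    apical: Rm(x) = 30 − 15/(1 + e^((300−x)/50))

with `Ra = 210 Ω·cm`, `Cm = 1.2 µF·cm⁻²`, rest at −66 mV.

Twelve current types are modelled with first-order Hodgkin–Huxley gates
(`ds/dt = (s∞ − s)/τ`): transient and persistent Na⁺ (Naf, Nap);
delayed-rectifier, A-type and D-type K⁺ (Kdr, KA, KD); fast and slow
Ca²⁺-activated K⁺ (fAHP, sAHP); the hyperpolarization-activated cation
current (h); and low/high-voltage-activated Ca²⁺ currents (CaT, CaN,
CaR, CaL). Calcium currents feed a per-compartment single-pool
concentration (submembrane shell 0.2 µm, decay τ = 20 ms, rest 50 nM)
from which the calcium reversal is Nernst-computed each step.

The kinetic constants are standard textbook formulations — they are not
a reproduction of any published parameter table — and the conductance
densities are the tunable layer, shipped as a JSON-serializable
configuration. Qualitative ordering constraints are enforced on any
configuration: Naf highest in the axon, then soma ≥ apical > basal;
every K⁺ current weaker apically than at the soma; AHP currents somatic
and reduced apically; the h conductance rising sigmoidally along the
apical tree to 10× its somatic density, with no such rise basally.

The default densities were tuned so the reduced reference cell
reproduces the RS↔IB dichotomy as a function of basal load. The burst
machinery is somatic — persistent Na⁺ (5·10⁻⁴ S·cm⁻²) and low-threshold
Ca²⁺ (10⁻³) sustain an after-depolarization following each spike — and
the counterweight is a slowly deactivating D-type K⁺ current in the
basal dendrites (2.5·10⁻³ S·cm⁻², activation τ = 20 ms, half-activation
−30 mV): each back-propagated spike switches it on, and because its
total conductance scales with basal membrane area, larger basal trees
leave a larger hyperpolarizing tail that delays the second spike. Small
trees let the after-depolarization win (first ISI < 20 ms, IB); the
boundary falls near 1.5 mm of basal length, between the two population
classes. `basal_mode="nonuniform"` rewrites the basal Na⁺/K⁺ rules into
a linear distance-dependent scaling (floor 50% by 250 µm) and changes
nothing outside basal dendrites.

## Numerics

Space: every section becomes `ceil(L/20 µm)` iso-diameter compartments
(override `max_seg_length`); the soma is one equivalent-cylinder
compartment, electrically attached at its midpoint. Total membrane area
equals the analytic lateral areas to 1e-6 relative; halving the
compartment length moves the passive input resistance by < 0.5%.

Time: backward-Euler with the channel conductances frozen at
gate-updated values, solved each step by tree-ordered (Hines)
elimination — unconditionally stable on the tree; gates advance by the
exact exponential update at the current voltage; the calcium pool is
explicit. Default `dt = 0.025 ms`. Against an adaptive high-accuracy
reference integrator on a soma-only cell, spike times agree within
0.5 ms at the default step and converge first-order under refinement.
Passive behaviour matches closed forms (isopotential RC charging with
τ = Rm·Cm = 36 ms; sealed-cable input resistance R∞·coth(L/λ)) within
0.05%. Every run starts from rest with gates at steady state and settles
for 200 ms before any stimulus, so slow states (h gate, calcium pool)
reach their true rest. Traces are bit-deterministic for identical
inputs.

## Protocols

Input resistance: steady-state deflection under a 500 ms, −0.1 nA
somatic pulse (the sign convention for the printed 0.1 nA magnitude),
with a convergence guard on |dV/dt| at pulse end. Firing assay: a
somatic step of `0.35 nA × Rin_cell/Rin_control` for 1000 ms; spikes are
upward 0-mV crossings (linear interpolation, 2 ms refractory); the cell
is IB if the first interspike interval is strictly below 20 ms, RS
otherwise, and Q with fewer than two spikes (the ISI rule is undefined
there, and exactly one spike is treated as quiescent). The 1 s window is
a deliberate choice: slow regular spikers can take hundreds of
milliseconds to emit their second spike, and a shorter window censors
them into Q.

Two readings of the normalization are implemented. The default scales
the current by the **cell/control** ratio of input resistances, so
electrically large (low-Rin) cells receive proportionally less current;
the alternative `equal-dv` uses the control/cell ratio, equalizing the
steady somatic depolarization `I·Rin` across cells. The default was
chosen on behavioural grounds: it produces the characteristic dependence
of the firing dichotomy on dendritic load — including its reversal when
a compact apical tree (high Rin, more current, more bursting) replaces
an extensive one — whereas equalizing the steady depolarization feeds
the extra current straight back into the largest cells and largely
cancels the load effect on the first ISI in this reduced model. Both
modes are tested; flipping them is a keyword argument everywhere.

## Population analysis

The grid experiment crosses basal trees with apical trees on the fixed
control soma; each basal tree's majority-vote *profile* is RS only if
strictly more than half of its row fired RS (quiescent and failed cells
count in the denominator). Feature contrasts between groups use the
Mann–Whitney U test: exact by full enumeration of rank assignments for
tie-free samples with min(n,m) ≤ 8, the tie-corrected normal
approximation otherwise (the exact branch is cross-checked in the tests
against an independent implementation). Single-feature classification
uses Gaussian class-conditional densities with equal priors (a
kernel-density option exists behind `density="kde"`); evaluation
balances classes by downsampling without replacement, splits each class
80/20, repeats 10 times with seeds spawned from one master seed, and
reports mean sensitivity/specificity/accuracy over the held-out sets
only. IB is the positive class for sensitivity; posterior ties go to IB;
both are documented arbitrary constants. The ≥10-per-class floor can be
lowered (`min_per_class`) for small grid experiments whose profile
groups split unevenly.

## Synthetic morphologies

The generator emulates the statistical structure the analysis needs, not
any particular archive. Trees are strictly binary with straight
constant-radius sections; diameters follow a fixed child/parent taper
(default 0.8) with optional per-section lognormal jitter; randomness is
PCG64, so a seed reproduces a tree bit-identically on any platform.

Two-class populations draw, per tree, one lognormal *size factor*
(σ = 0.20) that scales total length, stem count and branch count
together — the allometry of real dendritic populations, in which bigger
arbors are bushier rather than deeper. This matters twice: it makes
total length, volume and branch number strongly co-vary across the
population (as they do in real data), and it keeps large trees shallow,
so their membrane stays within about one length constant of the soma and
their electrical load tracks their length. Growth with a fixed branch
budget therefore bifurcates the shallowest open tips (depth-balanced
arbors). Class targets are: RS-like 1739 µm / 16 branches, IB-like
1152 µm / 10 branches — a two-standard-deviation separation in log
length. Stem calibres differ only slightly between classes (1.62 vs
1.54 µm, within-class σ = 0.06): the empirical diameter contrast between
firing groups is largely an *outcome* of the mechanism (thicker trees
load the soma more and fire RS), so imposing it fully on the input
classes would double-count it; with a modest input gap the realized
RS/IB-profile groups still separate in diameter, weakly, while median
diameter stays a poor predictor — the empirical pattern. Per-section
diameter jitter (σ = 0.10) additionally keeps the measured median a
noisy summary of the stem calibre, as in real reconstructions.

What passing tests therefore show: that the pipeline recovers a
morphology→firing relationship when one exists and ranks features by
their true discriminative power. What they do not show: that real
layer V reconstructions would yield the same boundary position or effect
sizes — real arbors are non-binary, tortuous, spiny, within-section
tapered, and their feature covariances are not fully captured by one
size factor.

## Problem sizes and scale

The shipped experiments are sized for a single CPU: the load ladder uses
5 rungs (0.7–2.4 mm), the population grid 20 basal × 2 apical trees
(10 per class), the classifier 10 repeats, and compartmental runs use
20 µm compartments at dt = 0.025 ms with ~1.2 s of simulated time per
cell. These sizes resolve the direction and ranking questions the
package asks; population-level percentages (e.g. the fraction of RS
profiles) carry the sampling noise of 20 trees and are reported, not
asserted.

## Known limitations

- Channel kinetics are generic formulations; no claim of kinetic-level
  fidelity to any published cell model is made or needed for the
  morphology questions the package addresses.
- The calcium pool is a single compartment-local shell with first-order
  decay; no buffering, diffusion, or store dynamics.
- Backward-Euler is first-order in time; spike times at the default step
  are accurate to ~0.5 ms, which is ample for a 20 ms ISI criterion but
  not for sub-millisecond timing studies.
- The section-level cylinder reduction makes volume/MEP split-dependent
  for within-section-tapered reconstructions (see above).
- Synthetic populations are a statistical stand-in, not fitted to any
  reconstruction archive.
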