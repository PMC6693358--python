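# Methods

This note describes the models implemented in `neuromotor`, the reasoning
behind the numerical and design choices, and what the shipped synthetic
fixtures do and do not demonstrate.

## Scope and architecture

The package models desk-scale spinal sensorimotor circuits end to end:
curated CSV tables → enumerated model definition (cell groups, net
connections, positions) → vectorized spiking-network simulation →
electrophysiological analysis (FI curves, adaptation, reflex recruitment
curves, hysteresis) → optional closed-loop ankle biomechanics, LFP forward
modeling, and coordinate-ascent model integration. Everything a simulation
consumes is explicit in two JSON documents: the *model definition* (five
sections: `info`, `regions`, `segments`, `cell_groups`, `net_connections`,
plus `aux`) and the *simulation definition* (`inputs`, `responses`,
`setup`, `runs`, `plots`). JSON schemas ship under
`src/neuromotor/schemas/`.

## Random realization

Cell counts, synaptic weights, and convergence ratios are normal random
variables; counts are rounded then clipped at zero, and truncation at a
lower bound is implemented by resampling (rejection), which preserves the
distribution's shape near the mean instead of piling mass at the clip.
Cell positions are uniform over their region's volume (boxes directly,
extruded polygons by rejection from the bounding box). All randomness in
model building flows through a single `numpy` generator seeded by the
caller, so a fixed seed reproduces the model JSON byte-for-byte while
different seeds support Monte-Carlo re-instantiation of positions and
wiring.

Coordinates are right-handed micrometres with z increasing rostrally; a
segment occupies `[offset, offset + length)` in z and segments tile the
neuraxis, aligned on the central canal.

## Circuit generation

Connections are generated from three curated tables. Muscle synergy rows
map muscles to movement types and declare antagonistic movement-type pairs
(closed under symmetry); agonists of a muscle share at least one movement
type with it (a muscle is its own agonist, so "homonymous" is a subset of
"agonist"), antagonists drive an antagonistic movement type. Connection
rules are motifs over neuron types (source type, destination type, muscle
relation, laterality, synaptic defaults) expanded against every matching
pair of cell groups, in deterministic sorted order, with rule provenance
recorded on each generated connection. Peters'-rule generation proposes a
directed candidate wherever one group's axonal box overlaps another's
dendritic box beyond a volume threshold (default 0); when both methods
run, rule-generated synaptic properties win for duplicated pairs.

Group names follow `{species}_{segment}_{lamina}_{side}_{type}_{muscle}`
with three-letter title-case muscle abbreviations ("Gas"), overridable per
row.

## Cell models

### Two-compartment conductance motoneurons

Motoneurons are reduced two-compartment models (spherical soma + lumped
dendritic cylinder) in the style of the classic reduced vertebrate
motoneuron: somatic fast Na (instantaneous cubed activation, slow
inactivation), delayed-rectifier K, N-type Ca, and K(Ca); dendritic N- and
L-type Ca and K(Ca); per-compartment first-order calcium pools driven by
the local Ca current density, with K(Ca) activated by `Ca/(Ca+Kd)`. The
K(Ca)/Ca-pool pair produces the post-spike AHP, spike-rate adaptation, and
the steady-state FI gain. The perisomatic placement index `range` (number
of dendritic compartments carrying the Ca/K(Ca) mechanisms, ordered by
path distance from the soma) scales the effective dendritic densities by
`range / n_compartments` on the lumped dendrite.

The S / FR / FF size classes share kinetics and differ in membrane area,
leak density, K(Ca) strength and calcium-pool constants. Because the
source literature distributes the underlying channel kinetics as simulator
mechanism files rather than printed equations, the maximal conductances
here were **calibrated** so the classes express their canonical
electrophysiology:

| class | rheobase (nA) | basal rate | conditions |
|-------|---------------|-----------|------------|
| S (`M_cell_Slow`) | ≈ 2.4 (repetitive) | ≈ 22 Hz | 12 nA step |
| FR (`M_cell_FR`) | ≈ 13.3 | ≈ 32 Hz | 18 nA step |
| FF (`M_cell_FF`) | ≈ 24.2 | ≈ 32.5 Hz | 25 nA step |

so that on a 3–30 nA grid in 3 nA steps the classes are recruited at 3,
15, and (integer-refined) 25 nA — the size principle. Calibration searched
leak density (rheobase), `gkcabar` (rate gain) and calcium-pool influx/
removal constants (adaptation speed and type-2 onset rate) per class; the
resulting constants are the package's default templates. The S-type soma
diameter is 82 μm.

The reflex-network motoneuron `M_cell_srr` is a separate cell model with
moderate adaptation, calibrated so its first-spike rheobase under a
0–50 nA / 1 s ramp is 3.0 nA with type-2 FI onset near 27 Hz. It cannot
share the Slow-type calibration: a flat FI (22 Hz at ~5× rheobase)
requires K(Ca) adaptation so strong that an isolated spike appears about
1 nA below the repetitive-firing threshold, which would drag the ramp
rheobase far below the repetitive one — the two behaviors belong to two
different cells.

### Bistable (plateau) motoneuron

`M_cell_bistable` keeps the S-type soma but an electrotonically tighter
dendrite whose L-type Ca current has a reachable activation fold
(half-activation −52 mV, slope 5 mV, τ 60 ms; dendritic leak 0.1 mS/cm²;
coupling 0.35 μS). With the conventional depolarized half-activation (−40 mV) the lumped
dendrite of this reduction never enters the activation range during
somatic firing — verified numerically — so the fold was re-specified at a
reachable voltage; this is a calibrated re-parameterization, not a copy of
any published kinetics. The serotonergic condition is modeled as a 40%
reduction of every `gkcabar` (`CellTemplate.with_serotonin()`). With 5-HT
the dendritic plateau persists through the descending limb of a triangular
current ramp, producing counterclockwise FI hysteresis (descending rates
exceed ascending at matched current, mean Δf ≈ +6 Hz under a 2 s/limb,
12 nA ramp); without 5-HT the K(Ca) brake suppresses the plateau and the
loop collapses (Δf < 0).

### Interneurons and afferents

Interneurons are leaky integrate-and-fire cells (τ 10 ms, R 100 MΩ,
threshold −50 mV, reset −65 mV, 1 ms refractory) integrated exactly
between events. Afferents are spike sources driven either by explicit
event times (EES volleys) or by rates from the biomechanics loop
(inhomogeneous Poisson per cell, or a deterministic integrate-to-threshold
generator).

### Synapses and stimuli

Synapses are single-exponential conductances `g(t) = w·Σ exp(−(t−t_s−d)/τ)`
with reversal-potential sign convention. Piecewise-linear current clamps
interpolate between breakpoints and hold the last value. Periodic EES
pulses fall at `delay + k·(1000/rate)` for k ≥ 1 — 8 Hz with a 10 ms delay
puts the first pulse at 135 ms.

## Numerics

Conductance compartments advance with an exponential-midpoint
(predictor–corrector) rule: gates use the exact exponential update with
kinetics frozen at the midpoint voltage, membrane voltages use the
exponential update with midpoint-averaged coefficients, and the calcium
pools are re-advanced with midpoint gating so the per-spike Ca influx —
which sets the steady firing rate through K(Ca) — is second-order
accurate. Cells whose soma is above −50 mV are advanced with 10× finer
substeps; cells in a batch are mutually independent (synaptic coupling is
handled by the network layer), so this split is exact. Spike times are
linearly interpolated −10 mV upcrossings subject to each class's absolute
refractory period (5 ms S, 2.5 ms FR/FF, 1 ms interneurons). With the
default dt = 0.025 ms the steady rate is accurate to well under 1%;
halving dt from 0.015 ms shifts spike times of a 1 s run by < 0.1 ms
(second-order convergence; the suite checks this at dt 0.015 → 0.0075).

Network synaptic events travel through a step-indexed queue; an event
lands on the first step at or after `t_spike + delay`, so no synaptic
effect ever precedes spike + delay. Rest states are computed once per
distinct template (300 ms relaxation) and cached.

## EES recruitment model

Stimulation amplitude is dimensionless. A pulse of amplitude A recruits a
fraction `f_aff(A)` of afferent fibers (piecewise linear, threshold 9.5,
saturation 15) which fire once per pulse, and a fraction `f_mn(A)` of
motoneuron axons (threshold 10.5, saturation 20) which are invaded
antidromically 0.6 ms after the pulse — the *early* response — and whose
somata are synaptically refractory for 12 ms, suppressing their
contribution to the *medium-late* (reflex) response. Both thresholds sit
between points of the conventional 7–29 (step 2) amplitude grid, so below
the on-grid motor threshold (the lowest amplitude with an early response)
neither response is visible; the early response then grows monotonically
to saturation while the medium-late response rises and collapses — at
twice motor threshold it falls to a few percent of its own peak, because
nearly the whole pool is refractory at the reflex latency. Evoked
responses are classified by post-pulse latency: early < 3 ms, medium
4.5–5 ms, late 9–11 ms, with the joint medium-late analysis window 3–12 ms
bracketing the last two. Response magnitude is the windowed peak-to-peak
of the group-averaged soma potential (deflections under 0.05 mV count as
absent); each response series is normalized to its own maximum.

## Biomechanics and afferent feedback

The ankle is a planar rigid foot hinged at O with toe Q, heel R, and a
fixed shank insertion P; tibialis anterior spans P–Q, gastrocnemius P–R,
and `M = I·θ̈` drives the joint (semi-implicit Euler; dorsi-flexion = θ
increasing, recorded in output metadata; lengths are dimensionless model
units since no physical dimensions are prescribed). Motor-unit force is
the LTI twitch convolution with kernel `P·(t/T)·e^(1−t/T)` (peak P at
t = T, default T = 30 ms); pool activation is the windowed per-cell firing
rate divided by a 50 Hz saturation rate, clamped to [0, 1], and scales the
twitch sum. Spindle rates follow the normalized power-law form
`Ia = α₁v^γ₁ + β₁·disp + η₁·act + base` and `II = β₂·disp + η₂·act +
base` with velocity in rest-lengths/s (rectified stretch-positive) and
displacement in fractional stretch; the default constants live in
`AFFERENT_DEFAULTS` as data, adapted from the normalized spindle
regression literature. The closed loop runs on a 1 ms control step
(network dt subdivides it exactly): spikes → activation → force → joint →
lengths/velocities → afferent rates → afferent spike generation.

## LFP forward models

Extracellular potentials assume an infinite homogeneous medium (σ = 0.3
S/m by default): point-source `V = ΣI/(4πσr)` and the closed-form
line-source integral (`asinh` form), with a 1 μm minimum distance clamp
and an optional first-order RC low-pass. Compartment membrane currents of
the two-compartment cells are the equal-and-opposite axial coupling
currents, so each cell is a current-conserving dipole; point
integrate-and-fire cells, which lack distributed currents, contribute
their net input current as a monopole — a documented approximation.

## Model integration

`compare_cells` diffs two templates over the union of their dotted
parameter paths (missing entries render as `KeyNotFound`). The objective
is the sum of Pearson correlations between candidate and reference series,
resampled onto the union of their x-supports within the overlap (identical
supports therefore reproduce the textbook point-wise Pearson). Constant
series score 0 with a warning; failed evaluations score −N and the search
continues. Coordinate ascent runs per-subspace first (adaptive step: ×1.5
on improvement, ×0.5 and direction flip on deterioration, floored at 10⁻³
of the bound range), then ascends the joint space from the top-2 subspace
seeds. `range` is searched as an integer by rounding.

Because the Pearson objective is invariant to affine transformations of a
response series, parameters whose main effect is to scale firing rates are
only identifiable through *shape*: reference experiments must be chosen so
each parameter leaves a distinct non-affine signature. The planted-recovery
problem in the test suite uses a spike-rate-adaptation profile (adaptation
shape pins somatic gKCa) together with the serotonin-condition FI table
spanning the plateau recruitment threshold (the position and sharpness of
the plateau's onset pin dendritic gCaL); both are smooth in the parameters
at the sampled operating points.

## Synthetic fixtures and what they show

`fixtures.ankle_l4l5` generates the two-segment ankle circuit: per
segment, 169 motoneurons, 60 Ia + 60 II afferents, and 400 interneurons
(200 Ia-inhibitory + 200 excitatory), with gastrocnemius motoneurons in
the left crural-extensor lamina-9 region of L5 and tibialis anterior in
the crural-flexor region of L4; Ia afferents excite homonymous/agonist
motoneurons and Ia interneurons, II afferents drive excitatory
interneurons, excitatory interneurons excite agonist motoneurons, and Ia
interneurons inhibit antagonist motoneurons. Regions are axis-aligned
boxes, not atlas contours. A `scale` factor shrinks all counts
proportionally; network-level tests and the acceptance script run at
scale 0.2 (≈ 138 cells per segment) over 3 wiring seeds with dt 0.025 ms
and 160 ms runs — one EES pulse per run. Synaptic weights are deterministic
(sd = 0) in the fixture because the source tables state no dispersions;
Monte-Carlo variability enters through positions and wiring.

Passing tests on these fixtures demonstrate the mechanisms (recruitment
order, reflex window structure, plateau hysteresis, loop closure), not
quantitative fidelity to any particular animal: real afferent dispersion,
heterogeneous conduction delays, and atlas-accurate geometry are out of
scope.

## Known limitations

- Channel kinetics are calibrated reductions, not fits to voltage-clamp
  data; absolute conductance values should not be read as measurements.
- The EES recruitment curve model is phenomenological (piecewise-linear
  fiber recruitment), not a field simulation of the epidural electrode.
- Integrate-and-fire LFP contributions are monopole approximations.
- No Hill-type force–length/velocity muscle properties, Ib (tendon organ)
  feedback, gravity, or ground contact in the ankle model.
- Axonal conduction is a lumped synaptic delay; no myelination biophysics.
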