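# neuromotor

Desk-scale modeling of spinal sensorimotor circuits: table-driven model
definition, muscle-synergy-based circuit generation, spiking-network
simulation with virtual electrophysiology, closed-loop ankle biomechanics
with spindle afferent feedback, extracellular (LFP) forward models, and
coordinate-ascent integration of cell models.

The package is for computational neuroscientists who want to build and
probe spinal reflex circuits the way an experimenter would — current
clamps, epidural stimulation sweeps, recruitment curves — without a heavy
simulation stack. Everything is plain Python + NumPy/SciPy; models are
plain CSV tables and JSON documents.

## The models

**Circuit generation.** Cell groups are enumerated from a curated table of
neuron types (one group per unique segment × side × lamina × neuron type ×
target muscle, e.g. `Human_L5_CEx9_L_AlphaMoto_Gas`). Connections come
from stereotyped rules over neuron types resolved through muscle synergy:
agonists share a movement type, antagonists drive opposed movement types.
The shipped L4/L5 ankle fixture yields the classic reflex motifs — Ia
afferents monosynaptically excite homonymous/agonist motoneurons, Ia
inhibitory interneurons project to antagonist motoneurons, group-II input
returns through excitatory interneurons — with 169 motoneurons, 60 Ia +
60 II afferents and 400 interneurons per segment at full scale.

**Cell models.** Motoneurons are reduced two-compartment conductance
models (somatic Na, K-dr, Ca-N, K(Ca); dendritic Ca-N, Ca-L, K(Ca);
calcium-pool–driven AHP). The S/FR/FF size classes are calibrated so
rheobase and steady firing rates follow the size principle (recruitment
at 3, 15, 25 nA on a 3 nA grid); a bistable variant expresses a dendritic
L-type plateau that, under the serotonergic condition (`gkcabar` × 0.6),
produces counterclockwise FI hysteresis. Interneurons are
integrate-and-fire; afferents are spike sources.

**Epidural stimulation (EES).** A pulse train of amplitude *A* recruits a
fraction of afferent fibers (reflex, medium-late response at 3–12 ms
latency) and, above the motor threshold, motoneuron axons directly (early
response, < 3 ms, with a refractory pool that suppresses the reflex
response at high amplitude). An 8 Hz train with a 10 ms delay fires its
first pulse at 135 ms.

**Biomechanics.** A planar rigid-foot ankle (`M = I·θ̈`) driven by
twitch-convolved, activation-scaled muscle force; spindle afferents follow
`Ia = α₁v^γ₁ + β₁·disp + η₁·act + base`, `II = β₂·disp + η₂·act + base`,
closing the loop back into the network.

**Model integration.** `compare_cells` diffs templates parameter by
parameter; an integrated model is searched by coordinate ascent (subspace
passes, then the joint space from the top seeds) on the sum of Pearson
correlations to constituent reference responses.

## Worked example

```bash
# materialize the ankle-circuit tables (20% scale), build the model,
# run a 3-amplitude EES sweep and emit the recruitment curve
neuromotor fixtures ankle_l4l5 --out tables --scale 0.2
neuromotor define tables --out model.json --seed 1
python - <<'EOF'
from neuromotor.fixtures import reflex_sim_definition
reflex_sim_definition([9.0, 13.0, 21.0]).save("setup.json")
EOF
neuromotor simulate model.json --setup setup.json --out out --seed 1
```

```
wrote fixture ankle_l4l5 -> tables
wrote model.json: 276 cells in 10 groups, 10 net connections
completed 3 runs -> out
```

`out/recruitment_curve.csv` then holds the normalized responses — at this
scale and seed:

```
amplitude,amplitude_mt,early,medium_late
9.0,0.6923076923076923,0.0,0.0
13.0,1.0,0.26470593555868166,1.0
21.0,1.6153846153846154,1.0,0.011061951107421421
```

Below the motor threshold (13 here, on this 3-point grid) both responses
are zero; at higher amplitude the early (direct) response saturates while
the medium-late (reflex) response collapses to a few percent of its peak
as the recruited motoneuron pool becomes refractory.

The same protocols are available as library calls
(`neuromotor.fixtures.run_reflex_sweep`,
`neuromotor.ephys_analysis.fi_curve`, `sra_curve`,
`recruitment_thresholds`, `triangular_ramp_fi`, …); see `docs/methods.md`
for the model details.

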