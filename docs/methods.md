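# Methods

## Membrane model

Each neuron is a single isopotential compartment with potassium (n⁴),
sodium (m³h), leak, and a two-gate calcium current (mCa²·hCa).  The m/n/h
kinetics use the classical squid-axon rate functions; their removable
singularities (V = −40 and −55 mV) are replaced by the analytic limits.
The calcium gates use Boltzmann steady states with voltage-independent
time constants (activation: half −30 mV, slope 6 mV, τ 2 ms; inactivation:
half −50 mV, slope 6 mV, τ 40 ms) — a deliberately generic parameterization,
since no specific worm channel kinetics are pinned down; the default
ḡCa = 0 keeps the calcium term inert unless expression data or explicit
parameters enable it.

Two parameter sets matter.  The network constants (Cm = 3.1 µF/cm²,
ḡl = 0.289 mS/cm², VK = −75, VNa = 55, Vl = −84, VCa = 45 mV) apply to all
worm-network neurons, with ḡK/ḡNa/ḡCa varying per neuron (gene-scaled or
explicit).  The classical squid set (Cm = 1, ḡNa = 120, ḡK = 36, ḡl = 0.3,
VNa = 50, VK = −77, Vl = −54.4) is used for the bifurcation analysis.

**Units.** Internally mV / ms / µF/cm² / mS/cm² / µA/cm².  Stimuli are
quoted in nA at the interface with a configurable scale, default
1 nA ≡ 1 µA/cm²; this keeps the interface numbers (51, 91, 94 nA …) and
current densities interchangeable.  The leak constant is tabulated as
"0.289 nS" in the source material while every other conductance is a
density; we read it as 0.289 mS/cm² under the same convention.

**Initialization.** Runs start at the true resting potential — the most
hyperpolarized zero of the steady-state I–V curve, found by grid scan plus
bisection — with every gate at its steady state there.  Starting at the
leak reversal instead is not a fixed point once the other channels carry
steady-state current; for the squid set Vl = −54.4 mV is so depolarized
that the loaded K gate suppresses firing entirely, which would break the
bifurcation scan.

**Integration.** Fixed-step synchronous update: gates take an exact
exponential step toward x∞(V) at frozen V, then V takes an explicit Euler
step; default dt = 0.01 ms.  The exponential gate update keeps every gate
in [0, 1] unconditionally.  The hot loop is a numba kernel; the
plain-Python functions in `wormbot.synapse` and `wormbot.membrane` define
the reference semantics and the tests assert both agree.

## Leak-conductance bifurcation

Below a critical leak conductance the neuron responds to a sustained
suprathreshold step with periodic firing rather than a single spike.
`find_critical_leak` classifies "sustained oscillation" as a periodic
spike train persisting through the second half of a 500 ms window and
bisects the leak conductance between brackets that classify differently.
The default probe current is 6.25 µA/cm², just above the classical model's
onset of repetitive firing from rest at standard leak (the fold of limit
cycles near 6.26 µA/cm²); with that probe the boundary falls at
0.2992 mS/cm², matching the literature value near 0.2994.  The boundary
moves with the probe (≈ +0.09 mS/cm² per extra µA/cm²), so the probe
amplitude is part of the definition and is exposed as an argument.

## Circuit discovery

A stimulus sweep drives one sensory neuron with a strictly increasing
amplitude grid (default spacing 1 nA), each amplitude from a fresh resting
network (500 ms horizon, stimulus on [50, 450] ms), and classifies every
motor neuron inside the stimulation window: 0 spikes → silent, 1–2 →
single spike, ≥3 with inter-spike-interval CV < 0.2 → oscillation with
frequency 1/mean ISI, ≥3 irregular → burst.  The per-sensory report gives
the first non-silent amplitude (activation threshold), the maximal
contiguous oscillation run, and the response mode.  "Responsive" requires
at least one spike; sub-threshold depolarization does not count.
Reproducing the real network's printed threshold table requires the
deposited whole-brain connectome with its exact channel parameters, which
is treated as an optional data-dependent integration exercise; the bundled
synthetic circuits reproduce the table's *shape* and, in the calibrated
control fixtures, its printed threshold values.

## Synapses

g′ = −g/τ decays exactly (g·e^(−dt/τ)); the increment g ← g + w is
edge-triggered — once per upward crossing of the −30 mV presynaptic
threshold, re-arming when the voltage falls back below — so conductance
cannot grow with the step count while a neuron sits above threshold
(dt-invariance).  Polarity encodes the reversal: +1 → 0 mV, −1 → −80 mV.
The synaptic current g(V_post − e) is subtracted in the membrane equation
with a global gain (default 1).  Network coupling is Jacobi-style: every
synapse reads its presynaptic voltage from the previous step, making
results independent of evaluation order and bit-reproducible; the one-step
delay's effect is bounded by the dt-halving tests.

## Convergence criteria

Pointwise voltage tolerances are only meaningful on smooth trajectories:
on a regeneratively spiking trace, an O(dt) phase shift of a ~100 mV spike
dominates any pointwise norm.  The suite therefore checks (i) pointwise
agreement (< 0.5 mV) against an independently written forward-Euler
integration at dt/10 on a *graded* three-neuron chain (high ḡK suppresses
the regenerative upstroke but transmission still occurs above −30 mV), and
(ii) spike-count and spike-time agreement (< 1 ms) on the spiking chain.

## Synthetic connectomes and calibrated fixtures

The generator wires a three-layer feed-forward network (every
sensory→inter and inter→motor pair drawn with probability 0.3 by default,
weights U(0.2, 1), 80 % excitatory) plus explicit two-hop motifs through
dedicated relay interneurons; it is a pure function of its arguments
including the seed.  It emulates the statistical shape of the real wiring
— three layers, signed weighted contacts, duplicate contacts kept distinct
— but not its actual topology, neuron identities, or gene-expression
profile, so tests passing on synthetic data show the machinery is correct,
not that the real worm's circuit values are reproduced.

The control fixtures (ASHL→VB1 and the four OLQ→RMD circuits) set the
sensory neurons' ḡK by offline bisection so that each one first reaches
the −30 mV transmission threshold — and hence first activates its motor
neuron — exactly at the printed stimulus values (51 nA for ASHL, 91 nA for
OLQDL/OLQDR/OLQVL, 94 nA for OLQVR) under the 200 ms decision protocol.
The high ḡK values this requires (≈1000–1600 mS/cm²) make those sensory
units graded-response cells, which is convenient: the activation boundary
is sharp and monotone in the stimulus.  The source material quotes both
51 nA (foraging encoder baseline) and 60 nA (ASHL row of the circuit
table) as ASHL-circuit activation numbers; the two are kept in their
respective contexts — the fixture used by the foraging loop calibrates to
the encoder's 51 — and are not reconciled here.

## Foraging controller

Concentration f(x) = A·e^(−k·x²) with A = 10⁷ and k = 2 m⁻²; the huge
amplitude keeps even centimeter-scale displacements above the encoder's
activation margin near the target.  The stimulus I = 51 + (f_now − f_prev)
is clamped to [0, 200] nA because the raw difference is unbounded for
large jumps and the membrane model is only characterized in that range.
Each decision runs the network from a fresh resting state for a 200 ms
window (stimulus on [10, 190] ms); ≥1 VB1 spike keeps the heading, silence
draws a new one uniformly on the circle from the episode's seeded
generator.  The default mover is a point mass with 0.1 m steps and a
0.15 m arrival radius; episode defaults (starts ~2.5 m out, ≤400 steps)
keep the whole concentration signal well above the calibration margin.
Far beyond ~4 m the Gaussian tail underflows the margin and the controller
degenerates into an unbiased random walk — a property of the encoder, not
of this implementation.  All sensing and commands round-trip through
line-delimited JSON control messages over an in-process queue or a local
socket pair; both transports yield identical trajectories for a fixed
seed.

## Robot dynamics

Uniform-sphere rigid body (mass 10 kg, J = 0.36 kg·m² per axis by
default), quaternion attitude λ̇ = ½Ω(ω)λ, full Euler equations (reducing
exactly to ω̇ᵢ = Mᵢ/Jᵢ for equal moments).  Ground contact is a per-tip
spring–damper normal force (k = 2·10⁴ N/m, c = 500 N·s/m, clamped
non-negative) with tangential friction capped by the Coulomb cone
(µ = 0.8) and regularized by a viscous slope below the cap; the central
shell (r = 0.2 m) contacts the same way as a fallback.  No contact law is
given in the source material; this is the standard penalty formulation.
Integration is RK4 with quaternion renormalization each step (default
dt = 2 ms for episodes, 1 ms in the conservation tests).  Leg lengths slew
toward commands at ≤0.25 m/s within [0.24, 0.50] m (expansion ratio ≈2.08).

**Leg layout.**  Twelve axes at icosahedron vertices, yawed 15° about +z
by default: with the raw vertex layout several axes lie exactly in the
region-boundary planes for cardinal headings and the four-region gait
degenerates into a symmetric vertical bounce; the yaw removes the
degeneracy for all tested headings.

**Four-region partition.**  Each leg's world axis gets an angle θ in the
vertical plane spanned by the heading and up, measured from the heading
toward up.  Quadrants: [0°, 90°) front-upper = C, [90°, 180°) rear-upper
= B, [180°, 270°) rear-lower = D, [270°, 360°) front-lower = A; boundary
ties join the lower-θ region.  Extending B and D while shrinking A and C
moves the support underneath backward and tips the body forward, rolling
it toward the heading; under forward rolling a leg cycles C → A → D → B,
which is exactly shrink-before-touchdown, extend-while-loaded.  The
quadrant centers (rather than boundaries) on the heading/up axes is this
package's interpretation of the region geometry, validated by the
emergent rolling: 60-step episodes land within ~7° of each commanded
heading in {0°, 45°, 90°, 135°}.

## Problem sizes and defaults

Simulation horizons and sizes used by the test and acceptance suites —
500 ms single-neuron probes at dt = 0.01 ms; a three-neuron chain for
engine/oracle comparisons; 20 foraging episodes of ≤400 decisions; four
60-step walking episodes (15 s of simulated robot time each at
dt = 2 ms) — were chosen as the smallest configurations at which every
quantity of interest is converged (dt-halving and step-count doubling
change no conclusion).

## Known limitations

- Gap junctions, synaptic plasticity, and multi-compartment morphology are
  out of scope by design.
- The bundled connectomes are statistical stand-ins; claims about the real
  worm's circuit thresholds require the deposited whole-brain data.
- The continuous spike-frequency → leg-length decoder is provided
  (`decode_frequency_to_length`) but, as in the source system, it does not
  produce useful locomotion on this robot geometry and is not wired into
  the episode runners.
- Flat ground only; no terrain meshes, no actuator electrical dynamics.
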