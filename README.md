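# wormbot

A whole-brain, conductance-based neural-network simulator for
*Caenorhabditis elegans*, coupled to a rigid-body model of a 12-legged
spherical robot that the network controls.

The package is for researchers in computational neuroscience and
neurorobotics who want to (i) simulate the worm's 302-neuron nervous system
at the level of membrane currents and chemical synapses, (ii) discover
sensory→motor control circuits by stimulus sweeps, and (iii) close the loop
between the biological network and a legged robot through explicit
encoding/decoding rules — a binary "foraging" orientation controller and a
four-region locomotion controller.

## The model

**Neurons** follow Hodgkin–Huxley dynamics with an added two-gate calcium
channel:

```
Cm dV/dt = I − ḡK n⁴(V−VK) − ḡNa m³h(V−VNa) − ḡCa mCa²hCa(V−VCa) − ḡl(V−Vl)
dx/dt    = αx(V)(1−x) − βx(V) x            x ∈ {m, n, h}
```

with per-neuron maximal conductances optionally scaled linearly from gene
expression (ḡc = unit_c · Σ expression of the channel's genes).  Network
constants: Cm = 3.1 µF/cm², ḡl = 0.289, VK = −75, VNa = 55, Vl = −84,
VCa = 45 (mV).  Internal units are mV / ms / µF/cm² / mS/cm² / µA/cm², with
stimulus amplitudes quoted in nA (1 nA ≡ 1 µA/cm²).

**Synapses** are chemical only (no gap junctions): a conductance g decays
as g′ = −g/τ, jumps by the weight w once per upward crossing of the −30 mV
presynaptic transmission threshold, and injects I = g(V_post − e) with
e = 0 mV (excitatory) or −80 mV (inhibitory).

**The robot** is a uniform sphere with 12 telescoping legs at icosahedral
directions; its 13-component state (position, unit-quaternion attitude,
velocity, body angular velocity) evolves under Newton–Euler dynamics with
spring–damper/Coulomb ground contact, integrated by RK4.

**Control.** Foraging: the distance x to a target maps to a concentration
f(x) = 10⁷·e^(−2x²), encoded as a stimulus I = 51 + (f_now − f_prev) nA on
sensory neuron ASHL; motor neuron VB1 firing ⇒ keep heading, silence ⇒ new
random heading.  Locomotion: legs partition into four heading-relative
regions A–D; each region stimulates one OLQ neuron, each OLQ drives exactly
one RMD motor neuron, and active RMDs extend the trailing (B, D) and shrink
the leading (A, C) legs, rolling the robot toward the heading.

## Worked example

```python
from wormbot.membrane import classical_squid_params, find_critical_leak
from wormbot.control import ForagingEnv, run_foraging_episode

gl_star = find_critical_leak(classical_squid_params(),
                             amplitude=6.25, bracket=(0.25, 0.35), tol=1e-6)
print(f"critical leak conductance: {gl_star:.6f} mS/cm^2")

result = run_foraging_episode(ForagingEnv(), seed=1, start=(2.5, 0.0))
print(f"foraging: converged={result.converged} in {result.steps} steps")
```

prints

```
critical leak conductance: 0.299176 mS/cm^2
foraging: converged=True in 29 steps
```

The first number is the leak conductance below which the classical
squid-axon neuron fires periodically instead of spiking once — the
bifurcation that makes spike-frequency decoding possible.  The second line
is a closed-loop episode: the point-mass robot starts 2.5 m from the
target and reaches it in 29 decisions, keeping its heading whenever the
sensed concentration rises and reorienting randomly when it falls.

The same functionality is available from the shell:

```
wormbot forage --seed 1 --start 2.5 0.0 --out forage_out
wormbot walk --heading 90 --steps 60 --out walk_out
wormbot sweep --sensory SN00 --lo 40 --hi 80 --step 5 --out sweep_out
```

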