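# lpnet — simulation of the fly lobula-plate tangential-cell network

`lpnet` simulates the network of motion-sensitive tangential cells in the
lobula plate of the blowfly visual system and the theory that explains
their ego-motion tuning.  It is written for computational neuroscientists
who want to probe how the known electrical and chemical connectivity
between these cells shapes their receptive fields and their selectivity
for rotational over translational optic flow.

## The model

**Cells.**  44 neurons (22 per hemisphere: VS1–VS10, V1, V2, Vi, the
postulated Vi2, HSN/HSE/HSS, dCH/vCH, H1, H2, Hu), each reduced to two
passive RC compartments — a dendrite and an axon — joined by a fixed
conductance.  The axons of V1, V2, Vi, Vi2, H1, H2 and Hu fire
integrate-and-fire spikes: the potential is set to 100 mV when it crosses
threshold and reset to rest the next 2-ms step, capping rates at 250 Hz.

**Input.**  A retinotopic array of correlation-type (Reichardt) motion
detectors covers an equirectangular retina at 2° spacing, four direction
channels per node (first-order low-pass τ = 20 ms against high-pass
τ = 50 ms, mirror subunits subtracted, half-wave rectified).  Each cell's
dendrite pools the channels of its preferred and null direction through an
anisotropic Gaussian sensitivity field S(x, y) =
exp(−(x−x₀)²/2σₓ² − (y−y₀)²/2σᵧ²), driving excitatory (E = +60 mV) and
inhibitory (E = −30 mV) conductances.

**Coupling.**  Cells connect through gap junctions (the axo-axonal VS
chain, VS→V1/Vi, VS1→H1/H2, HS→CH, VS10–dCH, …) and through rectifying
chemical synapses with conductance g = gain·[V_pre]₊ (0.01 µS/mV, reduced
to 0.002 for Vi→VS1).  Each 2-ms step solves the backward-Euler system
M(t)·V(t) = I(t) over all 88 compartments, where M adds the momentary
synaptic conductances to the static leak/capacitive/gap-junction matrix.

**Measurements.**  Receptive fields are mapped exactly as in the rig: a
4×8° bright bar swept back and forth at 1000 °/s, responses attributed to
bar position, giving a vector field (h, v) over azimuth/elevation.  Action
fields — the response as a scalar function of the ego-motion axis — come
from ray-cast movies of a checkerboard-lined virtual box rotating about
(or translating along) each axis of a grid on the sphere.

**Theory.**  `lpnet.flow` provides the closed-form rotational and
translational optic-flow fields on the unit sphere, their inner products
(the six basis flow fields are mutually orthogonal with norm² = 8π/3), and
ideal matched-filter sensors: a rotation sensor is exactly blind to every
translation (and vice versa), with cosine tuning in the inter-axis angle —
also when its receptive field is windowed to a sub-domain.  These closed
forms serve as oracles for the simulated fields.

## Worked example

Response of all ten left VS cells to full-field downward motion, with the
lobula-plate connectivity intact versus removed:

```bash
lpnet fig fig10 --outdir results
```

prints `fig10: {'max_deficit_cell': 'VS1'}` and writes
`results/fig10_downward_responses.csv`:

```
cell,connected,disconnected
VS1,3.11,8.57
VS2,5.27,8.57
VS3,6.36,8.57
VS4,7.35,8.57
VS5,7.70,8.57
VS6,7.59,8.57
VS7,6.99,8.57
VS8,6.63,8.57
VS9,6.23,8.57
VS10,5.43,8.57
```

(units mV, rounded).  Disconnected, every VS cell responds identically —
they all pool the same downward-selective detectors, only shifted in
azimuth.  Connected, the response is suppressed most in VS1–2 and VS8–10,
whose receptive fields the network curls into rotation templates, and
least in VS4–6, which remain nearly pure downward sensors: the
connectivity trades translational sensitivity for rotation selectivity.

Other entry points: `lpnet rfmap --cell L:VS10 --compartment ax` (moving-
bar receptive field), `lpnet afmap --cell L:VS5 --kind rotation` (axis
sweep), `lpnet stim ego --kind rotation --azimuth 0 --elevation 90`
(stimulus movies), `lpnet fig fig2|fig3|fig5|fig6|fig7|fig8|fig9|fig10`,
and `lpnet verify` (quick calibration checks, nonzero exit on failure).
The default circuit lives in `src/lpnet/data/default_circuit.yaml`; every
model constant can be edited there and passed via `--circuit`.

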