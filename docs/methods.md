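# Methods

This note records the model equations, the parameter choices and their
rationale, what the synthetic stimuli do and do not emulate, and the
numerical decisions a maintainer would want to know.  Everything stated
here is computed by the test suite or the experiment runners; nothing is
asserted beyond what the code reproduces.

## Network model

Each of the 44 neurons is a two-compartment RC model.  With voltages
relative to rest (0 mV), conductances in µS, capacitances in nF, currents
in nA and time in ms, one backward-Euler step of length Δt = 2 ms solves

    M(t) · V(t) = I(t)

over all 88 compartments.  The static part of M holds, per compartment,
the leak conductance plus the capacitive conductance C/Δt on the diagonal
and −g for every gap junction (including the intra-cell dendro-axonal
link), with the summed coupling conductances added back to the diagonal;
it is symmetric and strictly diagonally dominant, so the solve cannot go
singular.  At each step the time-dependent synaptic conductances are added
to the diagonal: the visually driven g_exc/g_inh of each dendrite and the
chemical conductances gain·[V_pre(t−1)]₊ of each synapse.  The right-hand
side holds injected currents, the synaptic driving terms g·E, and the
capacitive history (C/Δt)·V(t−1); no leak term appears because the leak
potential is the zero of the scale.

Spiking axons (V1, V2, Vi, Vi2, H1, H2, Hu) are integrate-and-fire: when
the solved voltage crosses threshold the compartment is set to 100 mV for
one step and reset to rest the next (one-step refractoriness — the
2-step period caps rates at exactly 250 Hz, which the strongly driven f–I
curve reaches).  Spike values feed chemical synapses through the same
rectified-gain rule; no separate spike-transmission rule is used.

Voltage clamp replaces the clamped cell's two rows with identity rows
(V = 0) but leaves its columns intact, so a clamped cell still sinks
current from its neighbours — this is the in-silico analogue of
photoablation controls.  A global disconnect switch removes every
inter-cell connection while keeping the dendro-axonal links; disconnected,
the system is block diagonal and cells evolve independently (tested).

### Compartment parameters

The two-resistor algebra fixes the passive parameters against two
observables: a dendritic input resistance of 6.7 MΩ for a synaptically
isolated cell, and ≈3 mV axonal depolarization during 1 nA dendritic
injection.  With dendrite leak G_d = 0.104 µS, axon leak G_a = 0.100 µS
and dendro-axonal coupling g_c = 0.081 µS,

    V_den = I (G_a+g_c) / (G_d G_a + G_d g_c + g_c G_a) = 6.72 mV at 1 nA
    V_ax  = V_den · g_c/(G_a+g_c)                       = 3.01 mV

Membrane capacitances are set so the time constant τ = C/G equals one
timestep (C_d = 0.208, C_a = 0.200 nF): spikes back-propagating into the
dendrite are then strongly attenuated by the capacitive load, as expected
for these cells, without resolving sub-millisecond dynamics the 2-ms grid
cannot represent.

### Coupling parameters

Gap junctions fall into three conductance groups — strong 0.3 µS (the
axo-axonal VS chain, HS→CH, VS10–dCH), medium 0.1 µS (VS1–3→V1,
VS7–10→Vi, VS1→Vi2, VS1→H1/H2, HS→Hu) and weak 0.05 µS (H2→HSE).  The
group values are free parameters of the model; the strong group was
calibrated once against two qualitative signatures and then frozen:
(i) current injected into VS1 must decay gradually along the chain and
reverse sign at the far end (through the end-to-end inhibitory loop),
with no reversal for hyperpolarizing current; (ii) the rotational
action-field peaks of the VS cells must be essentially the same with and
without network connectivity (≤ one 15° axis-grid step).  At 0.5 µS the
second signature fails — the end-to-end inhibition drains the strongly
coupled chain at VS1's preferred axes and drags its peak — while 0.3 µS
satisfies both.

Chemical synapses have gain 0.01 µS per mV of rectified presynaptic
depolarization; the single exception is Vi→VS1 at 0.002 µS.  The
postulated mirror pathway (VS1→Vi2 electrical, Vi2→VS7–10 inhibitory)
uses the 0.01 default: Vi pools four VS axons and inhibits one cell,
Vi2 pools one axon and inhibits four, so the higher output gain keeps the
two ends of the mutual inhibition functionally balanced — and it makes
VS10's frontal upward sensitivity clearly visible in the measured
receptive field.  Vi2 spikes with Vi's threshold (5 mV); thresholds are
3 mV for H1/H2/Hu and 4 mV for V1/V2.  Reversal potentials are +60 mV
(excitatory) and −30 mV (inhibitory) relative to rest — conventional
values for these cells; only E_exc ≫ responses ≫ E_inh matters for the
saturation behaviour.

HS→CH coupling is implemented as all three HS cells onto both dCH and
vCH; the experimental literature resolves the pathway only at the
HS-class level, and VS10's dorsal horizontal sensitivity requires no more
than HSN→dCH, which this superset contains.

## Detector array and pooling

Each retinal node carries four Reichardt channels.  Per pixel, a
low-pass (exact exponential update, τ = 20 ms) and a high-pass
(input minus a 50-ms low-pass) are maintained; a channel's unrectified
output at node x is LP(x)·HP(x+Δ) − LP(x+Δ)·HP(x) with Δ the 2° neighbour
along the channel axis (azimuth wraps at ±180°; the bottom elevation row
has no downward neighbour and outputs zero), signed so motion in the
channel's named direction is positive, then half-wave rectified.  The
closed-form steady-state mean for a drifting sinusoid,

    A² · Im[H_HP conj(H_LP)] · sin(2πΔ/λ),

with the exact discrete-filter frequency responses, matches the simulated
array to ~1e-10 and anchors the absolute output scale: outputs are scaled
so the reference grating (λ = 20°, 1 Hz, contrast 1) yields a mean channel
output of 0.02.  The value 0.02 is a calibration: full-field checkerboard
ego-motion pools to roughly ten times the reference mean, so this scale
puts the visually driven dendritic conductance near the compartment's
resting conductance — responses sit in the upper graded range with the
mild saturation characteristic of tangential cells.  (Normalizing the
reference output to 1.0 pins every dendrite at E_exc under full-field
drive and visibly distorts the population's action-field tuning.)

Pooling is mass-normalized: g_exc = 2 µS · ΣS·D_PD / ΣS and
g_inh = 3 µS · ΣS·D_ND / ΣS over the grid, so the gains are the
conductances reached when every detector under the field outputs 1.0 and
results are independent of grid resolution.  Cells without a sensitivity
field receive no direct input.  One global detector array serves both
hemispheres; laterality lives entirely in the sensitivity-field centers
(azimuth sign) and in the hemisphere-dependent mapping of the
front-to-back/back-to-front direction labels onto the leftward/rightward
channels.

## Stimuli

*Moving-bar probes* — a bright bar (1.0) on mid-gray (0.5), 4×8° for
horizontal sweeps and 8×4° for vertical ones, at 1000 °/s (2°, one grid
node, per frame).  *Virtual box* — a unit cube, observer at the center,
checkerboard walls with 10° checks as seen from the center; frames are
nearest-ray equirectangular projections (180×89 pixels at 2°).  Rotation
rotates the view rays, translation moves the eye point; default speeds
45 °/s and 0.5 box-units/s place the dominant detector temporal frequency
(≈2.25 Hz at the 20° check period) at the optimum of the 20/50 ms filter
pair.  *Uniform motion* — rigid drift of a periodic pattern with azimuth
wraparound.

Coordinates: x forward, y rightward, z up; azimuth positive to the
animal's right, elevation positive above the horizon.  A positive
rotation about an axis moves the frontal image along axis × view — under
this convention an upward-pitch axis sits at +90° azimuth, where VS1's
rotational action field peaks.  Translation axes point along the
observer's motion, so the focus of expansion sits at +T.

What the synthetic stimuli do **not** emulate: photoreceptor optics and
adaptation, hexagonal sampling, natural-scene statistics, luminance noise,
and mixed rotation–translation trajectories.  Passing tests therefore
show that the *connectivity* produces the right field structure under
idealized optics, not that the model reproduces responses to natural
scenes.

## Receptive-field measurement

Each track is swept in both directions and the two responses are
differenced (h = (r_right − r_left)/2, v = (r_up − r_down)/2, so h > 0
means rightward-preferring and v > 0 upward-preferring).  The differencing
cancels the direction-independent luminance-transient responses a bar
passage evokes in the orthogonal channels, which otherwise masquerade as
receptive-field structure.  Horizontal sweeps prepend a 200° lead-in lap
segment so the bar-onset transient decays before the attributed lap
begins; probe tracks and attribution nodes stay within |elevation| ≤ 80°,
away from the one-sided detector border rows where the sweep starts.
Responses are attributed to the bar position a fixed number of frames
earlier; the lag is calibrated once per grid from a single horizontal
sweep across the disconnected VS5 dendrite (narrow 12° sensitivity
stripe) and reused.  A residual protocol artifact remains: the filter
tails of a strong passage response smear ~5–10% of the peak into the
orthogonal component along the sweep direction; it is inherent to
back-and-forth probing and small relative to every effect the tests
assert.

Spiking compartments are mapped through a 20-ms boxcar-smoothed
instantaneous rate instead of the raw voltage.

## Action fields

One simulation per axis (500 ms movies, the first 150 ms discarded as
transient; responses are the mean axonal depolarization over the
remaining window); all requested cells are read out from the same run, so
mapping the whole VS population costs one sweep.  Default axis grids:
15° rings for horizontal-plane tuning, 30° whole-sphere grids for the
rotation/translation comparisons.  These resolutions are desk-scale
choices; the measured peak locations are stable one grid step under
refinement.

## Analytics

With x(φ,θ) the unit viewing direction and the tangent basis
(e_φ, e_θ), the flow of a rotation about unit axis R with rate ω is
ω·R×x, and of a translation along unit T with speed v and constant
nearness μ is μv·((T·x)x − T).  In components:

    rotation:     f_φ = ω (cosθ sinθ_R − sinθ cosθ_R cos(φ−φ_R))
                  f_θ = ω cosθ_R sin(φ−φ_R)
    translation:  f_φ = μv cosθ_T sin(φ−φ_T)
                  f_θ = μv (sinθ cosθ_T cos(φ−φ_T) − cosθ sinθ_T)

(verified against the 3-D construction at random points to 1e-12).  The
inner product of two fields is the cos(θ)-weighted midpoint-rule integral
of their pointwise dot product (default 1° spacing, second-order
convergent — tested).  On the full sphere the six basis flow fields are
orthogonal with norm² = 8π/3.  For a sensor whose receptive field is the
flow of its own kind about the +x axis, windowed to the symmetric domain
|φ| ≤ π−ε_φ, |θ| ≤ π/2−ε_θ, the squared norm is

    ‖A‖² = Area(Ω) − J_x(Ω),
    Area = 4(π−ε_φ)cos(ε_θ),
    J_x  = ∫ cos²θ cos²φ dΩ
         = 2(sin a − sin³a/3)(b + sin 2b/2),   a = π/2−ε_θ, b = π−ε_φ,

the cross-kind action field is exactly zero, and the same-kind action
field is ‖A‖²·cos γ with γ the inter-axis angle (μ² accompanies the
translation sensor).  These were re-derived from the integrals above and
are cross-checked against quadrature to 1e-6 relative in the tests.
μ = 1 throughout the analytics (constant nearness); note the simulation's
cubic box does *not* have constant nearness (corners are √3 farther than
face centers), which is one reason simulated action fields deviate from
the analytic cosine in detail.

## Known limitations

- The contralateral excitatory loops (H1/H2 → CH) carry small
  second-order responses into VS cells during bar probing (~5% of the
  main lobes); they are genuine network effects of the model, not
  measurement artifacts, but they have no experimental counterpart at
  this amplitude.
- The equirectangular retina over-samples high latitudes and truncates at
  ±88°; hard-edged textures plus nearest-ray sampling leave ~1–2% of
  pixels ambiguous at check borders under exact-symmetry rotations.
- Conductance-based saturation compresses full-field responses; the
  detector output scale places the model in the mildly saturated regime,
  and conclusions about absolute response amplitudes should not be drawn.
- No synaptic kinetics or delays: chemical transmission acts with a
  one-step (2 ms) lag, electrical coupling instantaneously within a step.
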