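# Default lobula-plate circuit: 22 tangential cells per hemisphere, 44 total.
#
# Every number that defines the model lives in this file; the builder in
# lpnet.circuit only expands the per-hemisphere templates below into the
# full two-hemisphere cell/connection lists.
#
# Units: conductances in uS, capacitances in nF, voltages in mV relative to
# rest (rest = 0), time in ms, angles in degrees of visual space.

dt_ms: 2.0

compartments:
  dendrite: {leak_uS: 0.104, capacitance_nF: 0.208}
  axon:     {leak_uS: 0.100, capacitance_nF: 0.200}

# uniform conductance linking the two compartments of every cell
dendro_axonal_uS: 0.081

# gap-junction conductance groups (strong calibrated so current injected
# into VS1 decays gradually along the chain and reverses in VS10, while
# full-field rotational tuning stays essentially unchanged when the
# network is disconnected)
electrical_groups:
  strong: 0.3
  medium: 0.1
  weak:   0.05

# chemical synaptic gains (uS per mV of rectified presynaptic depolarization)
# The reduced gain applies to Vi->VS1 only; the postulated mirror synapses
# Vi2->VS7..10 use the default gain, which also balances the two ends of the
# loop (Vi pools four VS axons, Vi2 only one).
chemical_gains:
  default: 0.01
  vi_vs1: 0.002

reversal_mV:
  excitatory: 60.0
  inhibitory: -30.0

spike_value_mV: 100.0

# axonal compartments of these cells fire all-or-none spikes
spiking_cells: [V1, V2, Vi, Vi2, H1, H2, Hu]
spike_thresholds_mV:
  H1: 3.0
  H2: 3.0
  Hu: 3.0
  V1: 4.0
  V2: 4.0
  Vi: 5.0
  Vi2: 5.0

# gains applied to the pooled motion-detector input of each dendrite
visual_gains_uS:
  excitatory: 2.0
  inhibitory: 3.0

# Dendritic sensitivity fields (left hemisphere; the right hemisphere is the
# mirror image with the azimuth center sign-flipped).  Cells not listed here
# (V1, Vi, Vi2, dCH, vCH) receive no direct motion-detector input.
# pd/nd: dn=downward, up=upward, ftb=front-to-back, btf=back-to-front.
sensitivity_fields:
  VS1:  {x0: -10,  y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS2:  {x0: -26,  y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS3:  {x0: -42,  y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS4:  {x0: -58,  y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS5:  {x0: -74,  y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS6:  {x0: -90,  y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS7:  {x0: -106, y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS8:  {x0: -122, y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS9:  {x0: -138, y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  VS10: {x0: -154, y0: 0,   sigma_x: 12, sigma_y: 60, pd: dn,  nd: up}
  V2:   {x0: -80,  y0: 0,   sigma_x: 60, sigma_y: 60, pd: up,  nd: dn}
  HSN:  {x0: -80,  y0: 50,  sigma_x: 60, sigma_y: 40, pd: ftb, nd: btf}
  HSE:  {x0: -80,  y0: 0,   sigma_x: 60, sigma_y: 40, pd: ftb, nd: btf}
  HSS:  {x0: -80,  y0: -50, sigma_x: 60, sigma_y: 40, pd: ftb, nd: btf}
  H1:   {x0: -80,  y0: 0,   sigma_x: 60, sigma_y: 60, pd: btf, nd: ftb}
  H2:   {x0: -80,  y0: 0,   sigma_x: 60, sigma_y: 60, pd: btf, nd: ftb}
  Hu:   {x0: -80,  y0: 0,   sigma_x: 60, sigma_y: 60, pd: ftb, nd: btf}

# Connections within one hemisphere, written for the left side and
# instantiated identically for the right.  Compartments: den / ax.
# strength refers to electrical_groups / chemical_gains keys above.
connections_ipsilateral:
  # axo-axonal VS chain
  - {pre: VS1.ax,  post: VS2.ax,  kind: electrical, strength: strong}
  - {pre: VS2.ax,  post: VS3.ax,  kind: electrical, strength: strong}
  - {pre: VS3.ax,  post: VS4.ax,  kind: electrical, strength: strong}
  - {pre: VS4.ax,  post: VS5.ax,  kind: electrical, strength: strong}
  - {pre: VS5.ax,  post: VS6.ax,  kind: electrical, strength: strong}
  - {pre: VS6.ax,  post: VS7.ax,  kind: electrical, strength: strong}
  - {pre: VS7.ax,  post: VS8.ax,  kind: electrical, strength: strong}
  - {pre: VS8.ax,  post: VS9.ax,  kind: electrical, strength: strong}
  - {pre: VS9.ax,  post: VS10.ax, kind: electrical, strength: strong}
  # frontal VS cells onto the spiking V1
  - {pre: VS1.ax,  post: V1.den,  kind: electrical, strength: medium}
  - {pre: VS2.ax,  post: V1.den,  kind: electrical, strength: medium}
  - {pre: VS3.ax,  post: V1.den,  kind: electrical, strength: medium}
  # distal VS cells onto Vi, and Vi's inhibition of VS1
  - {pre: VS7.ax,  post: Vi.den,  kind: electrical, strength: medium}
  - {pre: VS8.ax,  post: Vi.den,  kind: electrical, strength: medium}
  - {pre: VS9.ax,  post: Vi.den,  kind: electrical, strength: medium}
  - {pre: VS10.ax, post: Vi.den,  kind: electrical, strength: medium}
  - {pre: Vi.ax,   post: VS1.den, kind: chemical_inhibitory, strength: vi_vs1}
  # mirror path: VS1 onto Vi2, Vi2 inhibits the distal VS cells
  - {pre: VS1.ax,  post: Vi2.den, kind: electrical, strength: medium}
  - {pre: Vi2.ax,  post: VS7.den,  kind: chemical_inhibitory, strength: default}
  - {pre: Vi2.ax,  post: VS8.den,  kind: chemical_inhibitory, strength: default}
  - {pre: Vi2.ax,  post: VS9.den,  kind: chemical_inhibitory, strength: default}
  - {pre: Vi2.ax,  post: VS10.den, kind: chemical_inhibitory, strength: default}
  # VS1 onto the spiking horizontal cells
  - {pre: VS1.ax,  post: H1.den,  kind: electrical, strength: medium}
  - {pre: VS1.ax,  post: H2.den,  kind: electrical, strength: medium}
  # HS onto the CH cells
  - {pre: HSN.ax,  post: dCH.den, kind: electrical, strength: strong}
  - {pre: HSE.ax,  post: dCH.den, kind: electrical, strength: strong}
  - {pre: HSS.ax,  post: dCH.den, kind: electrical, strength: strong}
  - {pre: HSN.ax,  post: vCH.den, kind: electrical, strength: strong}
  - {pre: HSE.ax,  post: vCH.den, kind: electrical, strength: strong}
  - {pre: HSS.ax,  post: vCH.den, kind: electrical, strength: strong}
  # HS onto Hu
  - {pre: HSN.ax,  post: Hu.den,  kind: electrical, strength: medium}
  - {pre: HSE.ax,  post: Hu.den,  kind: electrical, strength: medium}
  - {pre: HSS.ax,  post: Hu.den,  kind: electrical, strength: medium}
  # CH inhibition of the spiking horizontal cells
  - {pre: dCH.ax,  post: H1.den,  kind: chemical_inhibitory, strength: default}
  - {pre: dCH.ax,  post: H2.den,  kind: chemical_inhibitory, strength: default}
  - {pre: vCH.ax,  post: H1.den,  kind: chemical_inhibitory, strength: default}
  - {pre: vCH.ax,  post: H2.den,  kind: chemical_inhibitory, strength: default}
  # VS10's gap junction with dCH
  - {pre: VS10.ax, post: dCH.ax,  kind: electrical, strength: strong}

# Connections crossing the midline, written as left-side presynaptic cell
# onto right-side postsynaptic cell; instantiated in both directions.
connections_contralateral:
  - {pre: H1.ax, post: dCH.den, kind: chemical_excitatory, strength: default}
  - {pre: H1.ax, post: vCH.den, kind: chemical_excitatory, strength: default}
  - {pre: H1.ax, post: HSN.den, kind: chemical_excitatory, strength: default}
  - {pre: H1.ax, post: HSE.den, kind: chemical_excitatory, strength: default}
  - {pre: H2.ax, post: dCH.den, kind: chemical_excitatory, strength: default}
  - {pre: H2.ax, post: vCH.den, kind: chemical_excitatory, strength: default}
  - {pre: H2.ax, post: HSE.ax,  kind: electrical, strength: weak}
  - {pre: Hu.ax, post: dCH.den, kind: chemical_inhibitory, strength: default}
  - {pre: Hu.ax, post: vCH.den, kind: chemical_inhibitory, strength: default}
  - {pre: V1.ax, post: vCH.den, kind: chemical_excitatory, strength: default}
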