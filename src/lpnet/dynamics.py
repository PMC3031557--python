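"""Time-stepping engine for the lobula-plate network.

Each 2-ms step solves the backward-Euler linear system  M(t) V(t) = I(t)
over all 88 compartments.  M(t) is the static conductance matrix (leaks,
capacitive conductances C/dt, gap junctions) plus, on the diagonal, the
time-dependent synaptic conductances: the visually driven excitatory and
inhibitory input of each dendrite and the rectified chemical conductances
gain * [V_pre(t-1)]+ contributed by presynaptic cells.  The right-hand side
collects injected currents, synaptic driving terms g*E, and the capacitive
history (C/dt) V(t-1).  The resting potential is the zero of the voltage
scale, so no leak term appears on the right-hand side.

Spiking axonal compartments use an integrate-and-fire rule: when the solved
voltage exceeds threshold the compartment is set to 100 mV for one step and
reset to rest on the next (one-step refractoriness, which caps the firing
rate at 1/(2 dt) = 250 Hz).  Voltage clamp of a cell replaces its two rows
with identity rows (V = 0) while leaving its columns intact, so a clamped
cell still sinks current from its neighbours, mimicking photoablation
controls.  A global disconnect switch removes every inter-cell connection
but keeps each cell's dendro-axonal link.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import CircuitSpec, assemble_static_matrix
from .detectors import Pooler, ReichardtArray
from .stimuli import Movie

__all__ = [
    "ExperimentControls",
    "SimulationResult",
    "Network",
    "Simulation",
    "run",
    "measure_response",
]


@dataclass
class ExperimentControls:
    """Current injections, voltage clamps and the global disconnect switch.

    ``injections`` maps compartment ids (e.g. ``'L:VS1:den'``) to a constant
    current in nA or an array of per-step currents.  ``clamps`` holds cell
    keys (e.g. ``'L:dCH'``) whose both compartments are held at rest; a
    clamp overrides any injection into the same cell.
    """
    injections: dict = field(default_factory=dict)
    clamps: set = field(default_factory=set)
    disconnect_all: bool = False


@dataclass
class SimulationResult:
    """Voltage traces (mV, relative to rest) for every compartment."""
    traces: np.ndarray            # (T, n_compartments)
    dt: float                     # ms
    compartment_ids: list[str]
    spiking_mask: np.ndarray      # bool per compartment
    spike_value: float
    stimulus_log: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.traces.shape[0] + 1) * self.dt

    def trace(self, comp_id: str) -> np.ndarray:
        return self.traces[:, self.compartment_ids.index(comp_id)]

    def spike_times(self, comp_id: str) -> np.ndarray:
        i = self.compartment_ids.index(comp_id)
        if not self.spiking_mask[i]:
            raise ValueError(f"{comp_id} is not a spiking compartment")
        return self.times[self.traces[:, i] == self.spike_value]


class Network:
    """Stateful stepping core over a fixed circuit and controls."""

    def __init__(self, circuit: CircuitSpec, controls: ExperimentControls | None = None):
        self.circuit = circuit
        self.controls = controls or ExperimentControls()
        connected = not self.controls.disconnect_all
        self.static = assemble_static_matrix(circuit, connected=connected)
        n = circuit.n_compartments
        self.n = n
        comps = list(circuit.iter_compartments())
        self.c_over_dt = np.array([c.capacitance for c in comps]) / circuit.dt
        self.spiking_mask = np.array([c.spiking for c in comps])
        self.thresholds = np.array(
            [c.spike_threshold if c.spiking else np.inf for c in comps])
        # chemical gain matrices G[post, pre]; inactive when disconnected
        self.g_chem_exc = np.zeros((n, n))
        self.g_chem_inh = np.zeros((n, n))
        if connected:
            for con in circuit.chemical_connections():
                i = circuit.compartment_index(con.post)
                j = circuit.compartment_index(con.pre)
                if con.kind == "chemical_excitatory":
                    self.g_chem_exc[i, j] += con.strength
                else:
                    self.g_chem_inh[i, j] += con.strength
        self._has_chem = connected and (
            self.g_chem_exc.any() or self.g_chem_inh.any())
        self.clamp_idx = np.array(sorted(
            circuit.compartment_index(f"{key}:{role}")
            for key in self.controls.clamps for role in ("den", "ax")), dtype=int)
        self.e_exc = circuit.e_exc
        self.e_inh = circuit.e_inh
        self.spike_value = circuit.spike_value
        self.reset()

    def reset(self, v0: np.ndarray | None = None):
        self.v = np.zeros(self.n) if v0 is None else np.array(v0, dtype=float)
        self.spike_flags = np.zeros(self.n, dtype=bool)
        self.t = 0.0

    def step(self, g_exc: np.ndarray | None = None,
             g_inh: np.ndarray | None = None,
             inj: np.ndarray | None = None) -> np.ndarray:
        """Advance one timestep; conductances/currents are per-compartment."""
        v_prev = self.v
        v_rect = np.maximum(v_prev, 0.0)
        if self._has_chem:
            gce = self.g_chem_exc @ v_rect
            gci = self.g_chem_inh @ v_rect
        else:
            gce = gci = 0.0
        ge = gce if g_exc is None else gce + g_exc
        gi = gci if g_inh is None else gci + g_inh
        diag_extra = ge + gi
        rhs = self.e_exc * ge + self.e_inh * gi + self.c_over_dt * v_prev
        if inj is not None:
            rhs = rhs + inj

        m = self.static.copy()
        if np.ndim(diag_extra):
            m[np.diag_indices(self.n)] += diag_extra
        if self.clamp_idx.size:
            m[self.clamp_idx, :] = 0.0
            m[self.clamp_idx, self.clamp_idx] = 1.0
            rhs = np.asarray(rhs, dtype=float).copy()
            rhs[self.clamp_idx] = 0.0

        v = np.linalg.solve(m, rhs)
        if not np.all(np.isfinite(v)):
            raise RuntimeError(f"non-finite membrane potential at t={self.t} ms")

        # integrate-and-fire: reset compartments that spiked last step, then
        # fire those crossing threshold now
        v[self.spike_flags] = 0.0
        new_spikes = self.spiking_mask & ~self.spike_flags & (v > self.thresholds)
        v[new_spikes] = self.spike_value
        self.spike_flags = new_spikes
        self.v = v
        self.t += self.circuit.dt
        return v


class Simulation:
    """Full pipeline: movie frames -> detector array -> pooling -> network.

    Reusable across movies; the detector array and the pooled sensitivity
    weights are built once per (circuit, grid) pair.
    """

    def __init__(self, circuit: CircuitSpec, grid=None,
                 controls: ExperimentControls | None = None):
        self.circuit = circuit
        self.controls = controls or ExperimentControls()
        self.detectors = ReichardtArray(grid, dt=circuit.dt)
        self.grid = self.detectors.grid
        self.pooler = Pooler(circuit, self.grid)
        self.network = Network(circuit, self.controls)
        # dendritic compartment row of each pooled cell
        self._dend_idx = np.array(
            [circuit.compartment_index(f"{key}:den") for key in self.pooler.cell_keys],
            dtype=int)
        self._inj = self._expand_injections()

    def _expand_injections(self):
        inj = {}
        for cid, cur in self.controls.injections.items():
            inj[self.circuit.compartment_index(cid)] = cur
        return inj

    def _injection_vector(self, k: int) -> np.ndarray | None:
        if not self._inj:
            return None
        vec = np.zeros(self.network.n)
        for i, cur in self._inj.items():
            vec[i] = cur[k] if np.ndim(cur) else cur
        return vec

    def reset(self):
        self.detectors.reset()
        self.network.reset()

    def run_movie(self, movie: Movie | None = None, n_steps: int | None = None,
                  reset: bool = True) -> SimulationResult:
        """Simulate through a movie (or for n_steps without visual input)."""
        if movie is not None:
            if not np.isclose(movie.dt, self.circuit.dt):
                raise ValueError("movie frame interval must equal the circuit dt")
            n_steps = movie.n_frames
        if n_steps is None:
            raise ValueError("need a movie or an explicit number of steps")
        if reset:
            self.reset()
        n = self.network.n
        traces = np.empty((n_steps, n))
        g_exc = np.zeros(n)
        g_inh = np.zeros(n)
        for k in range(n_steps):
            if movie is not None:
                fld = self.detectors.step(movie.frames[k])
                ge_cells, gi_cells = self.pooler.pool_vectors(fld)
                g_exc[self._dend_idx] = ge_cells
                g_inh[self._dend_idx] = gi_cells
            traces[k] = self.network.step(g_exc, g_inh, self._injection_vector(k))
        return SimulationResult(
            traces=traces, dt=self.circuit.dt,
            compartment_ids=self.circuit.compartment_ids,
            spiking_mask=self.network.spiking_mask,
            spike_value=self.circuit.spike_value,
            stimulus_log=dict(movie.log) if movie is not None else {},
        )


def run(circuit: CircuitSpec, movie: Movie | None = None,
        controls: ExperimentControls | None = None,
        duration: float | None = None) -> SimulationResult:
    """One-shot convenience wrapper around :class:`Simulation`."""
    sim = Simulation(circuit, movie.grid if movie is not None else None, controls)
    n_steps = None if duration is None else int(round(duration / circuit.dt))
    return sim.run_movie(movie, n_steps=n_steps)


def measure_response(result: SimulationResult, comp_id: str,
                     window: tuple[float, float] | None = None) -> float:
    """Steady-state response: mean depolarization (mV) for graded
    compartments, spike rate (Hz) for spiking ones.

    ``window`` is (t_start, t_end) in ms; default = the last half of the
    trace.
    """
    i = result.compartment_ids.index(comp_id)
    t = result.times
    if window is None:
        window = (t[-1] / 2.0, t[-1])
    sel = (t > window[0]) & (t <= window[1])
    if not np.any(sel):
        raise ValueError("empty measurement window")
    if result.spiking_mask[i]:
        n_spikes = np.count_nonzero(result.traces[sel, i] == result.spike_value)
        return n_spikes / ((window[1] - window[0]) * 1e-3)
    return float(result.traces[sel, i].mean())
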