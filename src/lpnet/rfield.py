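"""Receptive-field mapping by moving-bar probes.

A cell's receptive field is measured exactly the way it is in the
electrophysiology rig: a small bright bar sweeps rightward at a set of
elevations and downward at a set of azimuths at 1000 deg/s, and the cell's
momentary response (deviation from rest) is attributed to the bar position
a fixed number of frames earlier (the attribution lag compensates the
detector-filter and membrane delays and is calibrated once per grid from a
single sweep across a disconnected cell with a known narrow sensitivity
profile).

Each track is swept back and forth and the two passage responses are
differenced: the luminance transients a bar passage evokes in the
orthogonal detector channels are direction-independent and cancel in the
difference, leaving the genuine direction-selective component.

Sign convention (used everywhere, including plots): h > 0 means the cell
responds more to azimuth-increasing (rightward) than to leftward bar
motion, h = (r_right - r_left)/2; v > 0 means it favours upward motion,
v = (r_up - r_down)/2.  A hyperpolarization to downward motion therefore
registers as upward sensitivity, which is how the network's inhibitory
loops show up in the maps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec
from .detectors import RetinalGrid
from .dynamics import ExperimentControls, Simulation
from .stimuli import BarProbeSpec, render_bar_probe

__all__ = [
    "VectorFieldOnSphere",
    "measure_receptive_field",
    "calibrate_attribution_lag",
    "field_stats",
]


@dataclass
class VectorFieldOnSphere:
    """A 2-vector (h: horizontal, v: vertical component, mV) per node."""
    azimuths: np.ndarray       # deg, ascending
    elevations: np.ndarray     # deg, ascending
    h: np.ndarray              # (n_el, n_az)
    v: np.ndarray              # (n_el, n_az)

    def mesh(self):
        return np.meshgrid(self.azimuths, self.elevations)


def _response_trace(result, comp_id: str, smooth_ms: float = 20.0) -> np.ndarray:
    """Deviation-from-rest trace; spiking compartments are converted to a
    boxcar-smoothed instantaneous rate (Hz) so bar passages register as a
    graded signal."""
    i = result.compartment_ids.index(comp_id)
    tr = result.traces[:, i]
    if result.spiking_mask[i]:
        spikes = (tr == result.spike_value).astype(float) / (result.dt * 1e-3)
        w = max(1, int(round(smooth_ms / result.dt)))
        return np.convolve(spikes, np.ones(w) / w, mode="same")
    return tr


def calibrate_attribution_lag(grid: RetinalGrid | None = None,
                              circuit: CircuitSpec | None = None) -> int:
    """Frames between a bar crossing a location and the response peak.

    Sweeps the horizontal probe bar through the dendritic field of a
    synaptically isolated left VS5 (narrow, 12-deg sensitivity stripe at
    -74 deg azimuth) and returns the offset of the dendritic response peak
    from the bar's center crossing.  Deterministic; calibrated once and
    reused for every map on the same grid.
    """
    from .circuit import build_default_circuit
    circuit = (circuit or build_default_circuit()).disconnected()
    grid = grid or RetinalGrid()
    sim = Simulation(circuit, grid)
    spec = BarProbeSpec(sweep_axis="horizontal", track_positions=(0.0,))
    _, movie = next(render_bar_probe(spec, grid, dt=circuit.dt))
    sim.detectors.reset(np.full(grid.shape, spec.background))
    res = sim.run_movie(movie, reset=False)
    trace = _response_trace(res, "L:VS5:den")
    centers = movie.log["bar_center"]
    k_cross = int(np.argmin(np.abs(centers - (-74.0))))
    k_peak = int(np.argmax(np.abs(trace)))
    return max(0, k_peak - k_cross)


def measure_receptive_field(circuit: CircuitSpec, cell_key: str,
                            compartment: str = "ax",
                            controls: ExperimentControls | None = None,
                            az_step: float = 4.0, el_step: float = 4.0,
                            el_limit: float = 80.0,
                            components: tuple = ("h", "v"),
                            grid: RetinalGrid | None = None,
                            lag: int | None = None) -> VectorFieldOnSphere:
    """Map a cell's receptive field with the moving-bar protocol.

    ``cell_key`` like ``'L:VS10'``; ``compartment`` 'den' or 'ax'.
    ``controls`` selects network variants (disconnect_all, clamps).
    ``components`` may be restricted to ('v',) or ('h',) to halve the cost.
    ``el_limit`` keeps probe tracks and attribution nodes away from the
    grid's elevation border, where the bar is truncated, the vertical
    detectors are one-sided, and the sweep-onset transient lands.
    """
    grid = grid or RetinalGrid()
    controls = controls or ExperimentControls()
    if lag is None:
        lag = calibrate_attribution_lag(grid)
    comp_id = f"{cell_key}:{compartment}"
    sim = Simulation(circuit, grid, controls)

    az_nodes = np.arange(-180.0, 180.0, az_step)
    el_lim = min(el_limit, grid.elevations.max())
    el_nodes = np.arange(-el_lim, el_lim + 0.5, el_step)
    h = np.zeros((len(el_nodes), len(az_nodes)))
    v = np.zeros_like(h)

    def sweep(spec: BarProbeSpec):
        for track, movie in render_bar_probe(spec, grid, dt=circuit.dt):
            pad = np.full((lag + 2,) + grid.shape, spec.background)
            movie.frames = np.concatenate([movie.frames, pad])
            sim.reset()
            sim.detectors.reset(np.full(grid.shape, spec.background))
            res = sim.run_movie(movie, reset=False)
            n_lead = int(movie.log["lead_frames"][0])
            yield track, movie.log["bar_center"], n_lead, _response_trace(res, comp_id)

    def attribute(axis: str, tracks, nodes, out, sign, lead_deg=0.0):
        """Half-difference of the forward and reverse passage responses."""
        for reverse, s in ((False, sign), (True, -sign)):
            spec = BarProbeSpec(sweep_axis=axis, track_positions=tuple(tracks),
                                reverse=reverse, lead_deg=lead_deg)
            for track, centers, n_lead, trace in sweep(spec):
                i = int(np.argmin(np.abs(tracks - track)))
                for j, pos in enumerate(nodes):
                    k = n_lead + int(np.argmin(np.abs(centers[n_lead:] - pos))) + lag
                    if axis == "vertical":
                        out[j, i] += 0.5 * s * trace[k]
                    else:
                        out[i, j] += 0.5 * s * trace[k]

    if "v" in components:
        # forward sweep runs downward: depolarization there counts as v < 0
        attribute("vertical", az_nodes, el_nodes, v, -1.0)
    if "h" in components:
        # forward sweep runs rightward: depolarization counts as h > 0
        # (tracks index rows here: h[el_track, az_node]); the lead-in lap
        # lets the bar-onset transient decay before attribution starts
        attribute("horizontal", el_nodes, az_nodes, h, 1.0, lead_deg=200.0)
    return VectorFieldOnSphere(azimuths=az_nodes, elevations=el_nodes, h=h, v=v)


def field_stats(field: VectorFieldOnSphere) -> dict:
    """Deterministic summaries of a measured receptive field.

    Peaks are (azimuth, elevation, value) of the positive maximum and
    negative minimum per component; ``None`` when the component is all
    zero.  The stripe width is the azimuthal extent at half maximum of the
    |v| profile in the equatorial row.
    """
    out = {}
    az, el = field.azimuths, field.elevations
    for name, comp in (("h", field.h), ("v", field.v)):
        if not np.any(comp):
            out[f"{name}_max"] = out[f"{name}_min"] = None
            continue
        jmax, imax = np.unravel_index(np.argmax(comp), comp.shape)
        jmin, imin = np.unravel_index(np.argmin(comp), comp.shape)
        out[f"{name}_max"] = (float(az[imax]), float(el[jmax]), float(comp[jmax, imax]))
        out[f"{name}_min"] = (float(az[imin]), float(el[jmin]), float(comp[jmin, imin]))
    j0 = int(np.argmin(np.abs(el)))
    profile = np.abs(field.v[j0])
    if profile.max() > 0:
        step = float(az[1] - az[0]) if len(az) > 1 else 0.0
        out["v_stripe_width"] = float(np.count_nonzero(
            profile >= profile.max() / 2.0) * step)
    else:
        out["v_stripe_width"] = None
    out["h_norm"] = float(np.linalg.norm(field.h))
    out["v_norm"] = float(np.linalg.norm(field.v))
    return out
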