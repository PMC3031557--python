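"""Desk-scale runners for the model's standard experiments: single-cell
and chain current-injection probes, receptive-field mapping under in-silico
ablations, rotational/translational action-field sweeps, ideal-sensor
analytics, and full-field motion comparisons.

Each runner composes the library modules (circuit, stimuli, detectors,
dynamics, receptive/action fields) into one named experiment, writes its
results as delimited text tables, and optionally renders summary plots.
The same building blocks back the verification entry point.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .afield import (
    AxisGrid,
    horizontal_slice,
    measure_action_fields,
    peak_axis,
    ring_axes,
    sphere_axes,
)
from .circuit import CircuitSpec, build_default_circuit
from .dynamics import ExperimentControls, Network, Simulation, measure_response
from .rfield import field_stats, measure_receptive_field
from .stimuli import render_uniform_motion

logger = logging.getLogger("lpnet")

__all__ = [
    "run_experiment",
    "verify",
    "isolated_cell_response",
    "spike_rate_vs_current",
    "vs_chain_injection",
    "rotational_peak_azimuths",
    "vs10_upward_peak_azimuth",
    "uniform_downward_responses",
    "EXPERIMENTS",
]


def circuit_fingerprint(circuit: CircuitSpec) -> str:
    """Stable hash of the circuit definition, recorded in run logs."""
    payload = json.dumps(circuit.params, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# elementary measurements (also used by the acceptance script)
# ---------------------------------------------------------------------------

def isolated_cell_response(circuit: CircuitSpec | None = None,
                           current_nA: float = 1.0,
                           duration_ms: float = 1000.0) -> tuple[float, float]:
    """Steady-state (dendritic, axonal) voltage of a synaptically isolated
    cell during constant dendritic current injection."""
    circuit = (circuit or build_default_circuit()).disconnected()
    net = Network(circuit)
    inj = np.zeros(net.n)
    i_den = circuit.compartment_index("L:HSE:den")
    i_ax = circuit.compartment_index("L:HSE:ax")
    inj[i_den] = current_nA
    for _ in range(int(round(duration_ms / circuit.dt))):
        v = net.step(inj=inj)
    return float(v[i_den]), float(v[i_ax])


def spike_rate_vs_current(currents_nA, circuit: CircuitSpec | None = None,
                          duration_ms: float = 2000.0) -> pd.DataFrame:
    """Firing rate of an isolated spiking cell vs axonal injected current."""
    circuit = (circuit or build_default_circuit()).disconnected()
    i_ax = circuit.compartment_index("L:H1:ax")
    rows = []
    for cur in currents_nA:
        net = Network(circuit)
        inj = np.zeros(net.n)
        inj[i_ax] = cur
        n = int(round(duration_ms / circuit.dt))
        spikes = 0
        for _ in range(n):
            v = net.step(inj=inj)
            spikes += v[i_ax] == circuit.spike_value
        rows.append({"current_nA": cur, "rate_Hz": spikes / (duration_ms * 1e-3)})
    return pd.DataFrame(rows)


def vs_chain_injection(circuit: CircuitSpec | None = None,
                       target: str = "VS1", current_nA: float = 10.0,
                       duration_ms: float = 2000.0) -> pd.DataFrame:
    """Steady-state axonal voltages of VS1..VS10 during current injection
    into one VS cell's dendrite (full connectivity)."""
    circuit = circuit or build_default_circuit()
    controls = ExperimentControls(
        injections={f"L:{target}:den": current_nA})
    sim = Simulation(circuit, controls=controls)
    res = sim.run_movie(n_steps=int(round(duration_ms / circuit.dt)))
    return pd.DataFrame({
        "cell": [f"VS{i}" for i in range(1, 11)],
        "v_axon_mV": [res.trace(f"L:VS{i}:ax")[-1] for i in range(1, 11)],
    })


def rotational_peak_azimuths(circuit: CircuitSpec | None = None,
                             axes: AxisGrid | None = None,
                             disconnect: bool = False) -> dict[str, float]:
    """Azimuth of the rotational action-field maximum for each left VS cell."""
    circuit = circuit or build_default_circuit()
    if axes is None:
        axes = ring_axes(15.0)
    controls = ExperimentControls(disconnect_all=True) if disconnect else None
    comps = [f"L:VS{i}:ax" for i in range(1, 11)]
    fields = measure_action_fields(circuit, comps, "rotation", axes,
                                   controls=controls)
    return {f"VS{i}": peak_axis(fields[f"L:VS{i}:ax"])[0] for i in range(1, 11)}


def vs10_upward_peak_azimuth(circuit: CircuitSpec | None = None,
                             az_step: float = 4.0, el_step: float = 8.0) -> float:
    """Azimuth of the maximal positive vertical (upward) component of the
    left VS10 axonal receptive field, full connectivity."""
    circuit = circuit or build_default_circuit()
    fld = measure_receptive_field(circuit, "L:VS10", "ax",
                                  az_step=az_step, el_step=el_step,
                                  components=("v",))
    j, i = np.unravel_index(np.argmax(fld.v), fld.v.shape)
    return float(fld.azimuths[i])


def uniform_downward_responses(circuit: CircuitSpec | None = None,
                               speed: float = 45.0,
                               duration_ms: float = 500.0) -> pd.DataFrame:
    """Steady responses of VS1..VS10 to full-field downward motion, with the
    network connected and disconnected.

    Uses a horizontally uniform grating so the drive is exactly identical
    for every VS cell (their sensitivity profiles differ only by an
    azimuth shift).
    """
    from .stimuli import sine_grating
    circuit = circuit or build_default_circuit()
    movie = render_uniform_motion("down", speed, duration_ms,
                                  sine_grating(20.0, "horizontal"),
                                  dt=circuit.dt)
    out = {"cell": [f"VS{i}" for i in range(1, 11)]}
    for label, ctrl in (("connected", None),
                        ("disconnected", ExperimentControls(disconnect_all=True))):
        sim = Simulation(circuit, movie.grid, ctrl)
        res = sim.run_movie(movie)
        out[label] = [measure_response(res, f"L:VS{i}:ax",
                                       (duration_ms * 0.3, duration_ms))
                      for i in range(1, 11)]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# figure-style experiment runners
# ---------------------------------------------------------------------------

def _save(df: pd.DataFrame, outdir: Path, name: str):
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.csv"
    df.to_csv(path, index=False)
    logger.info("wrote %s", path)
    return path


def _plot_ring(df, outdir: Path, name: str):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for cell, grp in df.groupby("cell"):
        vals = grp["value"] / grp["value"].abs().max()
        ax.plot(np.radians(grp["axis_azimuth"]), vals, label=cell)
    ax.set_title(name)
    ax.legend(fontsize=6, loc="upper right")
    fig.savefig(outdir / f"{name}.png", dpi=120)
    plt.close(fig)


def run_fig2(outdir: Path, circuit=None):
    vd, va = isolated_cell_response(circuit)
    df1 = pd.DataFrame({"quantity": ["v_dendrite_mV", "v_axon_mV",
                                     "input_resistance_MOhm"],
                        "value": [vd, va, vd / 1.0]})
    _save(df1, outdir, "fig2_isolated_cell")
    df2 = spike_rate_vs_current(np.arange(0.0, 20.1, 1.0), circuit)
    _save(df2, outdir, "fig2_rate_vs_current")
    return {"v_dendrite": vd, "v_axon": va,
            "rate_max": float(df2["rate_Hz"].max())}


def run_fig3(outdir: Path, circuit=None):
    frames = []
    for target in ("VS1", "VS10"):
        for cur in (10.0, -10.0):
            df = vs_chain_injection(circuit, target, cur)
            df["injected_cell"] = target
            df["current_nA"] = cur
            frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    _save(df, outdir, "fig3_vs_chain")
    return {"n_conditions": 4}


def run_fig5(outdir: Path, circuit=None, az_step=8.0, el_step=8.0):
    circuit = circuit or build_default_circuit()
    variants = {
        "vs5_dendrite": ("L:VS5", "den", None),
        "vs5_axon": ("L:VS5", "ax", None),
        "vs10_full": ("L:VS10", "ax", None),
        "vs10_disconnected": ("L:VS10", "ax",
                              ExperimentControls(disconnect_all=True)),
        "vs10_clamp_dCH": ("L:VS10", "ax",
                           ExperimentControls(clamps={"L:dCH"})),
        "vs10_clamp_VS1": ("L:VS10", "ax",
                           ExperimentControls(clamps={"L:VS1"})),
    }
    summaries = {}
    for name, (cell, comp, ctrl) in variants.items():
        fld = measure_receptive_field(circuit, cell, comp, controls=ctrl,
                                      az_step=az_step, el_step=el_step)
        az, el = fld.mesh()
        df = pd.DataFrame({"azimuth": az.ravel(), "elevation": el.ravel(),
                           "h": fld.h.ravel(), "v": fld.v.ravel()})
        _save(df, outdir, f"fig5_{name}")
        _plot_quiver(fld, outdir, f"fig5_{name}")
        summaries[name] = field_stats(fld)
    return summaries


def _plot_quiver(fld, outdir: Path, name: str):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    az, el = fld.mesh()
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.quiver(az, el, fld.h, fld.v, angles="xy")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("elevation (deg)")
    ax.set_title(name)
    fig.savefig(outdir / f"{name}.png", dpi=120)
    plt.close(fig)


def run_fig7(outdir: Path, circuit=None, step=15.0):
    circuit = circuit or build_default_circuit()
    axes = ring_axes(step)
    comps = [f"L:VS{i}:ax" for i in range(1, 11)]
    rows = []
    for label, ctrl in (("connected", None),
                        ("disconnected", ExperimentControls(disconnect_all=True))):
        fields = measure_action_fields(circuit, comps, "rotation", axes,
                                       controls=ctrl)
        for i in range(1, 11):
            az, vals = horizontal_slice(fields[f"L:VS{i}:ax"])
            for a, v in zip(az, vals):
                rows.append({"cell": f"VS{i}", "connectivity": label,
                             "axis_azimuth": a, "value": v})
    df = pd.DataFrame(rows)
    _save(df, outdir, "fig7_rotation_ring")
    _plot_ring(df[df.connectivity == "connected"], outdir, "fig7_connected")
    peaks = (df[df.connectivity == "connected"]
             .loc[lambda d: d.groupby("cell")["value"].idxmax()])
    return {row.cell: row.axis_azimuth for row in peaks.itertuples()}


def run_fig6(outdir: Path, circuit=None, step=30.0):
    circuit = circuit or build_default_circuit()
    axes = sphere_axes(step)
    comps = [f"L:VS{i}:ax" for i in range(1, 11)]
    fields = measure_action_fields(circuit, comps, "rotation", axes)
    rows = []
    for i in range(1, 11):
        f = fields[f"L:VS{i}:ax"].normalized_to_max()
        for (a, e), v in zip(f.axes, f.values):
            rows.append({"cell": f"VS{i}", "axis_azimuth": a,
                         "axis_elevation": e, "value": v})
    _save(pd.DataFrame(rows), outdir, "fig6_rotational_action_fields")
    return {f"VS{i}": peak_axis(fields[f"L:VS{i}:ax"]) for i in range(1, 11)}


def run_fig8(outdir: Path):
    from . import flow
    rows = []
    roll = flow.MotionAxis("rotation", (1, 0, 0))
    thrust = flow.MotionAxis("translation", (1, 0, 0))
    for az in np.arange(-180.0, 181.0, 15.0):
        rot_probe = flow.MotionAxis.from_angles("rotation", az, 0.0)
        tr_probe = flow.MotionAxis.from_angles("translation", az, 0.0)
        rows.append({
            "axis_azimuth": az,
            "roll_sensor_rotational": flow.ideal_sensor_action_field(
                "rotation", roll, rot_probe),
            "roll_sensor_translational": flow.ideal_sensor_action_field(
                "rotation", roll, tr_probe),
            "thrust_sensor_rotational": flow.ideal_sensor_action_field(
                "translation", thrust, rot_probe),
            "thrust_sensor_translational": flow.ideal_sensor_action_field(
                "translation", thrust, tr_probe),
        })
    df = pd.DataFrame(rows)
    _save(df, outdir, "fig8_ideal_sensors")
    return {"rotational_peak": float(df["roll_sensor_rotational"].max()),
            "cross_kind_max": float(df["roll_sensor_translational"].abs().max())}


def run_fig9(outdir: Path, circuit=None, step=30.0):
    from .afield import compare_connected_disconnected
    circuit = circuit or build_default_circuit()
    axes = sphere_axes(step)
    cmp_ = compare_connected_disconnected(circuit, "L:VS10:ax", axes, axes)
    rows = []
    for kind, label, f in (
            ("rotation", "connected", cmp_.rotational_connected),
            ("rotation", "disconnected", cmp_.rotational_disconnected),
            ("translation", "connected", cmp_.translational_connected),
            ("translation", "disconnected", cmp_.translational_disconnected)):
        for (a, e), v in zip(f.axes, f.values):
            rows.append({"kind": kind, "connectivity": label,
                         "axis_azimuth": a, "axis_elevation": e, "value": v})
    _save(pd.DataFrame(rows), outdir, "fig9_vs10_action_fields")
    return {"suppression_ratio": cmp_.suppression_ratio}


def run_fig10(outdir: Path, circuit=None):
    df = uniform_downward_responses(circuit)
    _save(df, outdir, "fig10_downward_responses")
    deficit = df["disconnected"] - df["connected"]
    return {"max_deficit_cell": df["cell"][int(deficit.idxmax())]}


EXPERIMENTS = {
    "fig2": run_fig2,
    "fig3": run_fig3,
    "fig5": run_fig5,
    "fig6": run_fig6,
    "fig7": run_fig7,
    "fig8": run_fig8,
    "fig9": run_fig9,
    "fig10": run_fig10,
}


def run_experiment(name: str, outdir: str | Path = "results", **kwargs):
    """Run one named figure-style experiment; returns its summary dict."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    circuit = kwargs.pop("circuit", None) or build_default_circuit()
    logger.info("experiment %s, circuit %s", name, circuit_fingerprint(circuit))
    outdir = Path(outdir)
    if name == "fig8":
        return EXPERIMENTS[name](outdir)
    return EXPERIMENTS[name](outdir, circuit=circuit, **kwargs)


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def verify(outdir: str | Path | None = None) -> tuple[bool, list[dict]]:
    """Evaluate the package's headline checks; returns (all_ok, report).

    Covers the deterministic single-cell calibrations, the VS-chain current
    spread, the flow-field orthogonality, and the ideal-sensor selectivity.
    The expensive receptive/action-field measurements are exercised by the
    test suite and the acceptance script.
    """
    from . import flow
    report = []

    def check(name, value, ok, expected):
        report.append({"check": name, "value": value, "expected": expected,
                       "ok": bool(ok)})

    vd, va = isolated_cell_response()
    check("input_resistance_MOhm", vd, abs(vd - 6.7) < 0.1, "6.7 +- 0.1")
    check("axonal_depolarization_mV", va, abs(va - 3.0) < 0.5, "3.0 +- 0.5")

    rate = spike_rate_vs_current([20.0])["rate_Hz"].iloc[0]
    check("saturation_rate_Hz", rate, rate == 250.0, "250")

    df = vs_chain_injection(target="VS1", current_nA=10.0)
    mags = df["v_axon_mV"].to_numpy()
    check("chain_monotone_decay", float(np.max(np.diff(np.abs(mags[:6])))),
          np.all(np.diff(np.abs(mags[:6])) < 0), "decreasing VS1..VS6")
    check("distal_reversal_mV", float(mags[-1]), mags[-1] < 0, "< 0")

    yaw = flow.rotational_flow(flow.MotionAxis("rotation", (0, 0, 1)))
    thr = flow.translational_flow(flow.MotionAxis("translation", (1, 0, 0)))
    ip = flow.inner_product(yaw, thr, spacing_deg=1.0)
    check("rot_trans_orthogonality", ip, abs(ip) < 1e-6, "|.| < 1e-6")

    roll = flow.MotionAxis("rotation", (1, 0, 0))
    lift = flow.MotionAxis.from_angles("translation", 0.0, 90.0)
    cross = flow.ideal_sensor_action_field("rotation", roll, lift,
                                           method="quadrature")
    norm2 = flow.sensor_norm_squared("rotation")
    check("ideal_sensor_cross_kind", cross / norm2,
          abs(cross) / norm2 < 1e-6, "|.| < 1e-6 of peak")

    ok = all(r["ok"] for r in report)
    if outdir is not None:
        _save(pd.DataFrame(report), Path(outdir), "verify_report")
    return ok, report
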