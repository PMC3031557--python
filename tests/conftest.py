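"""Shared fixtures.

The expensive network measurements (action-field axis sweeps, moving-bar
receptive-field maps) are computed once per session and shared between the
behavioural tests that assert different properties of the same fields.
"""
from __future__ import annotations

import numpy as np
import pytest

from lpnet import (
    ExperimentControls,
    build_default_circuit,
    measure_action_fields,
    measure_receptive_field,
)
from lpnet.afield import ring_axes, sphere_axes
from lpnet.detectors import RetinalGrid
from lpnet.rfield import calibrate_attribution_lag


@pytest.fixture(scope="session")
def circuit():
    return build_default_circuit()


@pytest.fixture(scope="session")
def grid():
    return RetinalGrid()


@pytest.fixture(scope="session")
def attribution_lag(grid):
    return calibrate_attribution_lag(grid)


@pytest.fixture(scope="session")
def vs_ring_fields(circuit):
    """Rotational action fields of all left VS cells on the 15-deg
    horizontal-plane axis ring, connected and disconnected."""
    axes = ring_axes(15.0)
    comps = [f"L:VS{i}:ax" for i in range(1, 11)]
    connected = measure_action_fields(circuit, comps, "rotation", axes)
    disconnected = measure_action_fields(
        circuit, comps, "rotation", axes,
        controls=ExperimentControls(disconnect_all=True))
    return {"connected": connected, "disconnected": disconnected,
            "axes": axes, "comps": comps}


@pytest.fixture(scope="session")
def vs10_rf_variants(circuit, attribution_lag):
    """Left VS10 axonal receptive field under the four network variants of
    the in-silico ablation protocol (8-deg probe spacing)."""
    kw = dict(az_step=8.0, el_step=8.0, lag=attribution_lag)
    return {
        "full": measure_receptive_field(circuit, "L:VS10", "ax", **kw),
        "disconnected": measure_receptive_field(
            circuit, "L:VS10", "ax",
            controls=ExperimentControls(disconnect_all=True), **kw),
        "clamp_vs1": measure_receptive_field(
            circuit, "L:VS10", "ax",
            controls=ExperimentControls(clamps={"L:VS1"}), **kw),
        "clamp_dch": measure_receptive_field(
            circuit, "L:VS10", "ax",
            controls=ExperimentControls(clamps={"L:dCH"}), **kw),
    }


@pytest.fixture(scope="session")
def vs10_translation_fields(circuit):
    """Left VS10 translational action fields (30-deg sphere grid),
    connected vs disconnected."""
    axes = sphere_axes(30.0)
    comp = "L:VS10:ax"
    connected = measure_action_fields(circuit, [comp], "translation", axes)[comp]
    disconnected = measure_action_fields(
        circuit, [comp], "translation", axes,
        controls=ExperimentControls(disconnect_all=True))[comp]
    return {"connected": connected, "disconnected": disconnected, "axes": axes}


def region_max_abs(field, az_lo, az_hi, el_lo, el_hi, component):
    """Max |component| of a vector field within an az/el window."""
    a = (field.azimuths >= az_lo) & (field.azimuths <= az_hi)
    e = (field.elevations >= el_lo) & (field.elevations <= el_hi)
    return float(np.abs(getattr(field, component)[np.ix_(e, a)]).max())
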