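"""Declarative circuit model of the lobula-plate tangential-cell network.

The network comprises 22 identified tangential cells per hemisphere (44 in
total), each reduced to two electrically coupled compartments -- a dendritic
one that collects local motion-detector input through a Gaussian sensitivity
field, and an axonal one that carries the cell's output and, in the spiking
classes (V1, V2, Vi, Vi2, H1, H2, Hu), generates all-or-none action
potentials.  Cells are wired to each other by gap junctions (ohmic, symmetric)
and by rectifying chemical synapses whose conductance is proportional to the
presynaptic depolarization.

All model constants live in a single YAML configuration file
(``lpnet/data/default_circuit.yaml``); this module only expands it into
explicit per-compartment data structures and assembles the static conductance
matrix used by the dynamics engine.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "CompartmentSpec",
    "SensitivityField",
    "CellSpec",
    "ConnectionSpec",
    "CircuitSpec",
    "build_default_circuit",
    "load_circuit",
    "sensitivity_at",
    "assemble_static_matrix",
    "CELL_NAMES",
    "VS_NAMES",
]

#: the 22 cell classes of one hemisphere
VS_NAMES = tuple(f"VS{i}" for i in range(1, 11))
CELL_NAMES = VS_NAMES + (
    "V1", "V2", "Vi", "Vi2",
    "HSN", "HSE", "HSS", "dCH", "vCH",
    "H1", "H2", "Hu",
)

HEMISPHERES = ("left", "right")
_HEMI_TAG = {"left": "L", "right": "R"}

#: motion-direction tokens: down, up, front-to-back, back-to-front
DIRECTION_TOKENS = ("dn", "up", "ftb", "btf")
_OPPOSITE = {"dn": "up", "up": "dn", "ftb": "btf", "btf": "ftb"}


def comp_id(hemisphere: str, cell: str, role: str) -> str:
    """Canonical compartment identifier, e.g. ``'L:VS5:den'``."""
    return f"{_HEMI_TAG[hemisphere]}:{cell}:{role}"


@dataclass(frozen=True)
class CompartmentSpec:
    id: str
    role: str                      # 'den' or 'ax'
    leak_conductance: float        # uS
    capacitance: float             # nF
    spiking: bool = False
    spike_threshold: float | None = None   # mV above rest

    def __post_init__(self):
        if self.leak_conductance <= 0 or self.capacitance <= 0:
            raise ValueError("leak conductance and capacitance must be positive")
        if self.spiking and (self.spike_threshold is None or self.spike_threshold <= 0):
            raise ValueError("spiking compartments need a positive spike threshold")


@dataclass(frozen=True)
class SensitivityField:
    """Anisotropic 2-D Gaussian dendritic sensitivity over visual space."""
    x0: float          # deg azimuth of the field center
    y0: float          # deg elevation of the field center
    sigma_x: float     # deg
    sigma_y: float     # deg
    preferred_direction: str   # token from DIRECTION_TOKENS
    null_direction: str

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if self.null_direction != _OPPOSITE[self.preferred_direction]:
            raise ValueError("preferred and null direction must be opposite")


def sensitivity_at(field: SensitivityField, azimuth, elevation):
    """Sensitivity weight at (azimuth, elevation) in degrees; peak value 1."""
    az = np.asarray(azimuth, dtype=float)
    el = np.asarray(elevation, dtype=float)
    return np.exp(
        -((az - field.x0) ** 2) / (2.0 * field.sigma_x ** 2)
        - ((el - field.y0) ** 2) / (2.0 * field.sigma_y ** 2)
    )


@dataclass(frozen=True)
class CellSpec:
    name: str
    hemisphere: str
    dendrite: CompartmentSpec
    axon: CompartmentSpec
    dendro_axonal_conductance: float   # uS
    sensitivity: SensitivityField | None = None

    @property
    def key(self) -> str:
        return f"{_HEMI_TAG[self.hemisphere]}:{self.name}"


@dataclass(frozen=True)
class ConnectionSpec:
    pre: str    # compartment id
    post: str   # compartment id
    kind: str   # 'electrical' | 'chemical_excitatory' | 'chemical_inhibitory'
    strength: float  # uS (electrical) or uS per mV (chemical gain)

    @property
    def is_electrical(self) -> bool:
        return self.kind == "electrical"


@dataclass
class CircuitSpec:
    """A full, simulable circuit plus its global parameters."""
    cells: list[CellSpec]
    connections: list[ConnectionSpec]
    dt: float = 2.0                      # ms
    e_exc: float = 60.0                  # mV, excitatory reversal
    e_inh: float = -30.0                 # mV, inhibitory reversal
    spike_value: float = 100.0           # mV
    visual_gain_exc: float = 2.0         # uS at full drive
    visual_gain_inh: float = 3.0
    params: dict = field(default_factory=dict)   # raw config for provenance

    def __post_init__(self):
        self._by_key = {c.key: c for c in self.cells}
        ids = []
        for c in self.cells:
            ids.extend([c.dendrite.id, c.axon.id])
        self._comp_index = {cid: i for i, cid in enumerate(ids)}
        if len(self._comp_index) != len(ids):
            raise ValueError("duplicate compartment ids")
        for con in self.connections:
            if con.pre not in self._comp_index or con.post not in self._comp_index:
                raise ValueError(f"connection endpoint missing: {con}")

    # -- lookups ---------------------------------------------------------
    @property
    def n_compartments(self) -> int:
        return 2 * len(self.cells)

    @property
    def compartment_ids(self) -> list[str]:
        return list(self._comp_index)

    def compartment_index(self, cid: str) -> int:
        return self._comp_index[cid]

    def cell(self, name: str, hemisphere: str = "left") -> CellSpec:
        return self._by_key[f"{_HEMI_TAG[hemisphere]}:{name}"]

    def compartment(self, cid: str) -> CompartmentSpec:
        hemi_tag, name, role = cid.split(":")
        cell = self._by_key[f"{hemi_tag}:{name}"]
        return cell.dendrite if role == "den" else cell.axon

    def iter_compartments(self) -> Iterable[CompartmentSpec]:
        for c in self.cells:
            yield c.dendrite
            yield c.axon

    def electrical_connections(self) -> list[ConnectionSpec]:
        return [c for c in self.connections if c.is_electrical]

    def chemical_connections(self) -> list[ConnectionSpec]:
        return [c for c in self.connections if not c.is_electrical]

    def disconnected(self) -> "CircuitSpec":
        """Copy of the circuit with every inter-cell connection removed.

        The dendro-axonal link within each cell is kept; this mimics the
        simulator's global disconnect switch.
        """
        out = replace(self, cells=list(self.cells), connections=[])
        return out


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

def _default_config() -> dict:
    with resources.files("lpnet.data").joinpath("default_circuit.yaml").open() as fh:
        return yaml.safe_load(fh)


def _mirror_sensitivity(sens: SensitivityField) -> SensitivityField:
    # right hemisphere: azimuth center sign-flipped; the ftb/btf tokens keep
    # their behavioural meaning and are resolved per hemisphere at pooling
    return replace(sens, x0=-sens.x0)


def _build_cell(name: str, hemisphere: str, cfg: Mapping) -> CellSpec:
    den_cfg = cfg["compartments"]["dendrite"]
    ax_cfg = cfg["compartments"]["axon"]
    spiking = name in cfg["spiking_cells"]
    dend = CompartmentSpec(
        id=comp_id(hemisphere, name, "den"), role="den",
        leak_conductance=den_cfg["leak_uS"], capacitance=den_cfg["capacitance_nF"],
    )
    axon = CompartmentSpec(
        id=comp_id(hemisphere, name, "ax"), role="ax",
        leak_conductance=ax_cfg["leak_uS"], capacitance=ax_cfg["capacitance_nF"],
        spiking=spiking,
        spike_threshold=cfg["spike_thresholds_mV"][name] if spiking else None,
    )
    sens = None
    if name in cfg["sensitivity_fields"]:
        s = cfg["sensitivity_fields"][name]
        sens = SensitivityField(
            x0=float(s["x0"]), y0=float(s["y0"]),
            sigma_x=float(s["sigma_x"]), sigma_y=float(s["sigma_y"]),
            preferred_direction=s["pd"], null_direction=s["nd"],
        )
        if hemisphere == "right":
            sens = _mirror_sensitivity(sens)
    return CellSpec(
        name=name, hemisphere=hemisphere, dendrite=dend, axon=axon,
        dendro_axonal_conductance=cfg["dendro_axonal_uS"], sensitivity=sens,
    )


def _resolve_strength(kind: str, key: str, cfg: Mapping) -> float:
    if kind == "electrical":
        return float(cfg["electrical_groups"][key])
    return float(cfg["chemical_gains"][key])


def _expand_endpoint(spec: str, hemisphere: str) -> str:
    cell, role = spec.split(".")
    return comp_id(hemisphere, cell, role)


def load_circuit(path: str | None = None) -> CircuitSpec:
    """Build a circuit from a YAML config file (the shipped default if None)."""
    if path is None:
        cfg = _default_config()
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)

    cells = [
        _build_cell(name, hemi, cfg)
        for hemi in HEMISPHERES
        for name in CELL_NAMES
    ]

    connections: list[ConnectionSpec] = []
    for hemi in HEMISPHERES:
        for row in cfg["connections_ipsilateral"]:
            connections.append(ConnectionSpec(
                pre=_expand_endpoint(row["pre"], hemi),
                post=_expand_endpoint(row["post"], hemi),
                kind=row["kind"],
                strength=_resolve_strength(row["kind"], row["strength"], cfg),
            ))
    for pre_hemi, post_hemi in (("left", "right"), ("right", "left")):
        for row in cfg["connections_contralateral"]:
            connections.append(ConnectionSpec(
                pre=_expand_endpoint(row["pre"], pre_hemi),
                post=_expand_endpoint(row["post"], post_hemi),
                kind=row["kind"],
                strength=_resolve_strength(row["kind"], row["strength"], cfg),
            ))

    return CircuitSpec(
        cells=cells,
        connections=connections,
        dt=float(cfg["dt_ms"]),
        e_exc=float(cfg["reversal_mV"]["excitatory"]),
        e_inh=float(cfg["reversal_mV"]["inhibitory"]),
        spike_value=float(cfg["spike_value_mV"]),
        visual_gain_exc=float(cfg["visual_gains_uS"]["excitatory"]),
        visual_gain_inh=float(cfg["visual_gains_uS"]["inhibitory"]),
        params=cfg,
    )


def build_default_circuit() -> CircuitSpec:
    """The two-hemisphere, 44-cell default network."""
    return load_circuit(None)


# ---------------------------------------------------------------------------
# static conductance matrix
# ---------------------------------------------------------------------------

def assemble_static_matrix(circuit: CircuitSpec, connected: bool = True) -> np.ndarray:
    """Static part of the per-step linear system, in uS.

    Off-diagonal (i, j) entries hold -g for every gap junction between
    compartments i and j (including the intra-cell dendro-axonal link);
    the diagonal holds leak + C/dt + sum of adjacent gap-junction
    conductances.  The matrix is symmetric and strictly diagonally dominant
    (leak and capacitive terms are strictly positive), hence non-singular.

    With ``connected=False`` only the intra-cell links are kept.
    """
    n = circuit.n_compartments
    m = np.zeros((n, n))
    comps = list(circuit.iter_compartments())
    for i, comp in enumerate(comps):
        m[i, i] = comp.leak_conductance + comp.capacitance / circuit.dt

    def couple(i: int, j: int, g: float):
        if m[i, j] != 0.0:
            raise ValueError(
                f"duplicate electrical edge between {comps[i].id} and {comps[j].id}")
        m[i, j] -= g
        m[j, i] -= g
        m[i, i] += g
        m[j, j] += g

    for cell in circuit.cells:
        couple(circuit.compartment_index(cell.dendrite.id),
               circuit.compartment_index(cell.axon.id),
               cell.dendro_axonal_conductance)
    if connected:
        for con in circuit.electrical_connections():
            couple(circuit.compartment_index(con.pre),
                   circuit.compartment_index(con.post),
                   con.strength)
    return m
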