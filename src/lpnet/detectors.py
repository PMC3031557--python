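"""Retinotopic array of correlation-type (Reichardt) motion detectors.

At every node of an equirectangular retinal grid sit four detector subunit
pairs, one per cardinal direction (rightward, leftward, downward, upward).
A detector correlates the low-pass filtered luminance of one pixel with the
high-pass filtered luminance of its neighbour 2 deg away along the channel
axis, subtracts the mirror term, and half-wave rectifies the result, so each
channel carries a non-negative motion-energy signal for its named direction.

Channel outputs are pooled into per-cell excitatory/inhibitory conductances
through each cell's Gaussian sensitivity field: the preferred-direction
channel drives the excitatory conductance, the null-direction channel the
inhibitory one.  Sums are normalized by the sensitivity mass and detector
outputs are scaled so a reference drifting grating (20 deg wavelength, 1 Hz,
contrast 1) produces a mean channel output of 1.0; the printed synaptic
gains (2 uS excitatory, 3 uS inhibitory) are then the conductances reached
at full-field reference drive, independent of grid resolution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec, sensitivity_at

__all__ = [
    "RetinalGrid",
    "DetectorField",
    "ReichardtArray",
    "Pooler",
    "correlator_mean_response",
    "REFERENCE_GRATING",
]

TAU_LP = 20.0   # ms, delay (low-pass) branch
TAU_HP = 50.0   # ms, direct (high-pass) branch

#: reference drifting grating fixing the absolute detector output scale:
#: wavelength (deg), temporal frequency (Hz), luminance amplitude
REFERENCE_GRATING = (20.0, 1.0, 0.5)

#: mean channel output at the reference grating.  Calibrated once so that
#: strong full-field motion (checkerboard ego-motion at the correlator
#: optimum, which pools to roughly ten times the reference-grating mean)
#: drives a dendritic conductance comparable to the compartment's resting
#: conductance: responses then sit in the upper graded range with the mild
#: saturation characteristic of tangential cells, instead of pinning every
#: dendrite at the excitatory reversal potential.
REFERENCE_OUTPUT = 0.02


@dataclass(frozen=True)
class RetinalGrid:
    """Equirectangular retinal sampling grid with 2-deg spacing by default."""
    spacing: float = 2.0   # deg, interommatidial angle

    @property
    def azimuths(self) -> np.ndarray:
        # wraps at +/-180: [-180, 180) covered without duplication
        return np.arange(-180.0, 180.0, self.spacing)

    @property
    def elevations(self) -> np.ndarray:
        # poles excluded; +/-88 deg at the default spacing
        lim = 90.0 - self.spacing
        return np.arange(-lim, lim + 0.5 * self.spacing, self.spacing)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.elevations), len(self.azimuths))

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(azimuth, elevation) 2-D arrays matching the frame layout."""
        return np.meshgrid(self.azimuths, self.elevations)


@dataclass
class DetectorField:
    """Rectified per-node motion-energy of the four direction channels."""
    rightward: np.ndarray
    leftward: np.ndarray
    downward: np.ndarray
    upward: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def scaled(self, a: float) -> "DetectorField":
        return DetectorField(*(a * self.channel(c) for c in
                               ("rightward", "leftward", "downward", "upward")))


def _lp_coef(dt: float, tau: float) -> float:
    # exact exponential update for a 1st-order low-pass
    return 1.0 - np.exp(-dt / tau)


def discrete_lp_response(freq_hz: float, dt: float, tau: float) -> complex:
    """Frequency response of the discrete exponential low-pass update."""
    a = _lp_coef(dt, tau)
    z = np.exp(-2j * np.pi * freq_hz * dt * 1e-3)
    return a / (1.0 - (1.0 - a) * z)


def correlator_mean_response(wavelength_deg: float, freq_hz: float,
                             amplitude: float = 0.5, dt: float = 2.0,
                             spacing: float = 2.0) -> float:
    """Closed-form time-averaged output of one unrectified correlator.

    For a sinusoidal grating of the given wavelength drifting at the given
    temporal frequency in the channel's preferred direction, the mean of
    LP(s1)*HP(s2) - LP(s2)*HP(s1) is  A^2 * Im[H_HP conj(H_LP)] * sin(k d),
    with k the spatial frequency and d the detector sampling base.  Uses the
    exact frequency responses of the discrete-time filters.
    """
    h_lp = discrete_lp_response(freq_hz, dt, TAU_LP)
    h_hp = 1.0 - discrete_lp_response(freq_hz, dt, TAU_HP)
    k_d = 2.0 * np.pi * spacing / wavelength_deg
    return float(amplitude ** 2 * np.imag(h_hp * np.conj(h_lp)) * np.sin(k_d))


def detector_output_scale(dt: float = 2.0, spacing: float = 2.0) -> float:
    """Scale factor fixing the reference-grating mean response to
    ``REFERENCE_OUTPUT``."""
    lam, f, amp = REFERENCE_GRATING
    return REFERENCE_OUTPUT / correlator_mean_response(lam, f, amp, dt, spacing)


class ReichardtArray:
    """Stateful 4-channel detector array on a retinal grid."""

    def __init__(self, grid: RetinalGrid | None = None, dt: float = 2.0):
        self.grid = grid or RetinalGrid()
        self.dt = dt
        self._a20 = _lp_coef(dt, TAU_LP)
        self._a50 = _lp_coef(dt, TAU_HP)
        self.scale = detector_output_scale(dt, self.grid.spacing)
        self.reset()

    def reset(self, frame: np.ndarray | None = None):
        """Reset filter states (to a frame's luminance, or to zero)."""
        shape = self.grid.shape
        if frame is None:
            self._lp = np.zeros(shape)
            self._lp50 = np.zeros(shape)
        else:
            self._lp = np.array(frame, dtype=float)
            self._lp50 = np.array(frame, dtype=float)

    def step(self, frame: np.ndarray) -> DetectorField:
        """Advance filters by one timestep and return the rectified field."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape != self.grid.shape:
            raise ValueError(f"frame shape {frame.shape} != grid {self.grid.shape}")
        if not np.all(np.isfinite(frame)):
            raise ValueError("non-finite luminance values in frame")

        self._lp += self._a20 * (frame - self._lp)
        self._lp50 += self._a50 * (frame - self._lp50)
        lp = self._lp
        hp = frame - self._lp50

        # horizontal: neighbour in the +azimuth direction, wrapping at +/-180
        lp_e = np.roll(lp, -1, axis=1)
        hp_e = np.roll(hp, -1, axis=1)
        horiz = lp * hp_e - lp_e * hp

        # vertical: neighbour one grid step lower in elevation (rows are
        # ascending elevation); bottom row has no lower neighbour
        vert = np.zeros_like(horiz)
        vert[1:, :] = lp[1:, :] * hp[:-1, :] - lp[:-1, :] * hp[1:, :]

        s = self.scale
        return DetectorField(
            rightward=s * np.maximum(horiz, 0.0),
            leftward=s * np.maximum(-horiz, 0.0),
            downward=s * np.maximum(vert, 0.0),
            upward=s * np.maximum(-vert, 0.0),
        )


def _resolve_channel(token: str, hemisphere: str) -> str:
    """Map a behavioural direction token to a detector channel.

    Vertical tokens are hemisphere-independent.  Front-to-back on the left
    eye is motion toward more negative azimuths (leftward); on the right eye
    it is the mirror image.
    """
    if token == "dn":
        return "downward"
    if token == "up":
        return "upward"
    if token == "ftb":
        return "leftward" if hemisphere == "left" else "rightward"
    if token == "btf":
        return "rightward" if hemisphere == "left" else "leftward"
    raise ValueError(f"unknown direction token {token!r}")


class Pooler:
    """Pools detector output into per-cell (g_exc, g_inh) conductances."""

    def __init__(self, circuit: CircuitSpec, grid: RetinalGrid | None = None):
        self.circuit = circuit
        self.grid = grid or RetinalGrid()
        az, el = self.grid.mesh()
        self.cell_keys: list[str] = []
        weights, pd_ch, nd_ch = [], [], []
        for cell in circuit.cells:
            if cell.sensitivity is None:
                continue
            w = sensitivity_at(cell.sensitivity, az, el)
            weights.append((w / w.sum()).ravel())
            pd_ch.append(_resolve_channel(cell.sensitivity.preferred_direction,
                                          cell.hemisphere))
            nd_ch.append(_resolve_channel(cell.sensitivity.null_direction,
                                          cell.hemisphere))
            self.cell_keys.append(cell.key)
        self._w = np.array(weights) if weights else np.zeros((0, az.size))
        self._gain_exc = circuit.visual_gain_exc
        self._gain_inh = circuit.visual_gain_inh
        # group cells by channel so pooling is a handful of matmuls per frame
        self._groups: list[tuple[str, str, np.ndarray]] = []
        for which, chans in (("exc", pd_ch), ("inh", nd_ch)):
            for ch in ("rightward", "leftward", "downward", "upward"):
                idx = np.array([i for i, c in enumerate(chans) if c == ch], dtype=int)
                if idx.size:
                    self._groups.append((which, ch, idx))

    def pool_vectors(self, field: DetectorField) -> tuple[np.ndarray, np.ndarray]:
        """(g_exc, g_inh) vectors in uS, aligned with ``self.cell_keys``."""
        n = len(self.cell_keys)
        g_exc = np.zeros(n)
        g_inh = np.zeros(n)
        for which, ch, idx in self._groups:
            vals = self._w[idx] @ field.channel(ch).ravel()
            if which == "exc":
                g_exc[idx] = vals
            else:
                g_inh[idx] = vals
        return self._gain_exc * g_exc, self._gain_inh * g_inh

    def __call__(self, field: DetectorField) -> tuple[dict, dict]:
        """Return ({cell key: g_exc}, {cell key: g_inh}) in uS.

        Cells without a sensitivity field are absent from the maps (their
        conductances are zero).
        """
        g_exc, g_inh = self.pool_vectors(field)
        return (dict(zip(self.cell_keys, g_exc.tolist())),
                dict(zip(self.cell_keys, g_inh.tolist())))
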