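"""Visual stimulus generation on the equirectangular retinal grid.

Three stimulus families are produced, all as luminance movies in [0, 1]
sampled at the simulation timestep:

* moving-bar probes for receptive-field mapping (a 4x8 deg bright bar swept
  rightward at fixed elevations, an 8x4 deg bar swept downward at fixed
  azimuths, at 1000 deg/s),
* ego-motion movies rendered by ray-casting a textured virtual box around a
  rotating or translating observer,
* rigidly drifting full-field patterns (gratings, checkerboards).

Coordinate conventions: the body frame is x = forward, y = rightward,
z = up; azimuth is positive to the right of the animal, elevation positive
above the horizon.  A viewing direction at (azimuth phi, elevation theta)
is the unit vector (cos th cos ph, cos th sin ph, sin th).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detectors import RetinalGrid

__all__ = [
    "Movie",
    "BarProbeSpec",
    "EgoMotionSpec",
    "VirtualBox",
    "render_bar_probe",
    "render_ego_motion",
    "render_uniform_motion",
    "axis_vector",
    "checkerboard",
    "sine_grating",
    "save_movie",
    "load_movie",
]

BAR_SPEED = 1000.0   # deg/s


@dataclass
class Movie:
    """A luminance image sequence on a retinal grid.

    ``frames`` has shape (T, n_elevations, n_azimuths); rows are ascending
    elevation, columns ascending azimuth.  ``log`` carries per-frame stimulus
    annotations (e.g. the bar center during a probe sweep).
    """
    frames: np.ndarray
    dt: float                     # ms between frames
    grid: RetinalGrid = field(default_factory=RetinalGrid)
    log: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt


def save_movie(movie: Movie, path: str | Path):
    """Write a movie to a single .npz container with a JSON header."""
    header = json.dumps({"dt": movie.dt, "spacing": movie.grid.spacing,
                         "log": {k: np.asarray(v).tolist()
                                 for k, v in movie.log.items()}})
    np.savez(path, frames=movie.frames, header=np.array(header))


def load_movie(path: str | Path) -> Movie:
    with np.load(path) as data:
        header = json.loads(str(data["header"]))
        return Movie(frames=data["frames"], dt=header["dt"],
                     grid=RetinalGrid(spacing=header["spacing"]),
                     log={k: np.asarray(v) for k, v in header["log"].items()})


def export_png_frames(movie: Movie, directory: str | Path):
    """Dump each frame as an 8-bit grayscale PNG (one file per frame)."""
    import imageio.v3 as iio   # optional dependency, only needed here
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(movie.frames):
        img = (np.clip(frame[::-1], 0.0, 1.0) * 255).astype(np.uint8)
        iio.imwrite(directory / f"frame_{i:05d}.png", img)


# ---------------------------------------------------------------------------
# moving-bar probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarProbeSpec:
    """Receptive-field probe: a small bright bar on a mid-gray background."""
    sweep_axis: str                       # 'horizontal' | 'vertical'
    track_positions: tuple = ()           # elevations (horizontal) / azimuths
    speed: float = BAR_SPEED              # deg/s
    reverse: bool = False                 # sweep leftward/upward instead
    lead_deg: float = 0.0                 # horizontal pre-lap before the
                                          # attributed traversal (onset decay)
    bar_luminance: float = 1.0
    background: float = 0.5

    @property
    def bar_width(self) -> float:
        # vertical probe bar is 4 deg wide x 8 deg high; horizontal 8 x 4
        return 4.0 if self.sweep_axis == "horizontal" else 8.0

    @property
    def bar_height(self) -> float:
        return 8.0 if self.sweep_axis == "horizontal" else 4.0


def _paint_bar(frame, grid: RetinalGrid, az_c, el_c, width, height,
               lum, wrap_az=True):
    az = grid.azimuths
    el = grid.elevations
    daz = az - az_c
    if wrap_az:
        daz = (daz + 180.0) % 360.0 - 180.0
    cols = np.abs(daz) <= width / 2.0
    rows = np.abs(el - el_c) <= height / 2.0
    frame[np.ix_(rows, cols)] = lum


def render_bar_probe(spec: BarProbeSpec, grid: RetinalGrid | None = None,
                     dt: float = 2.0):
    """Yield (track_position, Movie) pairs, one continuous sweep each.

    Horizontal sweeps traverse the full azimuth range rightward, vertical
    sweeps the full elevation range downward (``reverse`` flips the
    direction, for back-and-forth probing).  The movie log maps each frame
    to the bar center position along the sweep.
    """
    grid = grid or RetinalGrid()
    if spec.bar_width > 360.0 or spec.bar_height > np.ptp(grid.elevations):
        raise ValueError("bar larger than the retinal grid")
    step = spec.speed * dt * 1e-3           # deg advanced per frame
    n_lead = int(round(spec.lead_deg / step))
    for track in spec.track_positions:
        if spec.sweep_axis == "horizontal":
            if spec.reverse:
                centers = np.arange(180.0 + spec.lead_deg, -180.0, -step)
            else:
                centers = np.arange(-180.0 - spec.lead_deg, 180.0, step)
            centers = (centers + 180.0) % 360.0 - 180.0
            if not (grid.elevations.min() <= track <= grid.elevations.max()):
                raise ValueError(f"track elevation {track} outside grid")
        else:
            lo, hi = grid.elevations.min(), grid.elevations.max()
            centers = np.arange(hi, lo - 0.5 * step, -step)
            if spec.reverse:
                centers = centers[::-1]
            if not (-180.0 <= track < 180.0):
                raise ValueError(f"track azimuth {track} outside grid")
        frames = np.full((len(centers),) + grid.shape, spec.background)
        for k, c in enumerate(centers):
            if spec.sweep_axis == "horizontal":
                _paint_bar(frames[k], grid, c, track,
                           spec.bar_width, spec.bar_height, spec.bar_luminance)
            else:
                _paint_bar(frames[k], grid, track, c,
                           spec.bar_width, spec.bar_height, spec.bar_luminance,
                           wrap_az=False)
        yield track, Movie(frames=frames, dt=dt, grid=grid,
                           log={"bar_center": centers,
                                "lead_frames": np.array([n_lead])})


# ---------------------------------------------------------------------------
# ego-motion rendering in a virtual box
# ---------------------------------------------------------------------------

def axis_vector(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit 3-vector for an axis given in (azimuth, elevation) degrees."""
    ph = np.radians(azimuth_deg)
    th = np.radians(elevation_deg)
    return np.array([np.cos(th) * np.cos(ph),
                     np.cos(th) * np.sin(ph),
                     np.sin(th)])


@dataclass(frozen=True)
class VirtualBox:
    """Cube-shaped room with checkerboard walls, observer at the center.

    ``check_deg`` is the angular size of one check as seen from the center
    looking at the middle of a face.
    """
    half_extent: float = 1.0
    check_deg: float = 10.0

    @property
    def check_size(self) -> float:
        return 2.0 * self.half_extent * np.tan(np.radians(self.check_deg / 2.0))


@dataclass(frozen=True)
class EgoMotionSpec:
    """A pure rotation about, or pure translation along, a body axis.

    Rotation sense: positive rotation about an axis moves the frontal image
    in the direction axis x view (the convention under which a pitch axis at
    +90 deg azimuth drives the frontal visual field downward).  Translation
    moves the observer along +axis.
    """
    kind: str                      # 'rotation' | 'translation'
    axis: np.ndarray               # unit 3-vector
    speed: float                   # deg/s (rotation) or box-units/s
    duration: float = 500.0        # ms

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-8):
            raise ValueError("axis must be a unit vector")
        if self.kind not in ("rotation", "translation"):
            raise ValueError(f"unknown ego-motion kind {self.kind!r}")


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return (np.eye(3) + np.sin(angle_rad) * kx
            + (1.0 - np.cos(angle_rad)) * (kx @ kx))


def _ray_grid(grid: RetinalGrid) -> np.ndarray:
    az, el = grid.mesh()
    ph = np.radians(az)
    th = np.radians(el)
    return np.stack([np.cos(th) * np.cos(ph),
                     np.cos(th) * np.sin(ph),
                     np.sin(th)])           # (3, n_el, n_az)


def _sample_box(rays: np.ndarray, eye: np.ndarray, box: VirtualBox) -> np.ndarray:
    """Luminance seen along each ray from an eye point inside the box."""
    h = box.half_extent
    d = rays.reshape(3, -1)
    p = eye.reshape(3, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_axis = (np.sign(d) * h - p) / d       # exit distance per axis
    t_axis[~np.isfinite(t_axis)] = np.inf
    face = np.argmin(t_axis, axis=0)
    t = np.take_along_axis(t_axis, face[None], axis=0)[0]
    q = p + t * d
    # texture coordinates: the two coordinates orthogonal to the hit face
    u = np.empty_like(t)
    v = np.empty_like(t)
    for ax, (ua, va) in enumerate(((1, 2), (0, 2), (0, 1))):
        m = face == ax
        u[m] = q[ua, m]
        v[m] = q[va, m]
    c = box.check_size
    parity = (np.floor(u / c) + np.floor(v / c)).astype(np.int64) & 1
    return parity.astype(float).reshape(rays.shape[1:])


def render_ego_motion(spec: EgoMotionSpec, box: VirtualBox | None = None,
                      grid: RetinalGrid | None = None, dt: float = 2.0) -> Movie:
    """Ray-cast the checkerboard box as seen by the moving observer."""
    box = box or VirtualBox()
    grid = grid or RetinalGrid()
    rays0 = _ray_grid(grid)
    n = max(1, int(round(spec.duration / dt)))
    frames = np.empty((n,) + grid.shape)
    eye0 = np.zeros(3)
    for k in range(n):
        t_s = k * dt * 1e-3
        if spec.kind == "rotation":
            # world ray = Rot(axis, -theta) . body ray, which makes the image
            # of a fixed feature flow with velocity  axis x view
            ang = np.radians(spec.speed * t_s)
            rot = _rotation_matrix(spec.axis, -ang)
            rays = np.tensordot(rot, rays0, axes=1)
            eye = eye0
        else:
            rays = rays0
            eye = eye0 + spec.speed * t_s * spec.axis
            if np.any(np.abs(eye) >= box.half_extent):
                raise ValueError("observer left the virtual box")
        frames[k] = _sample_box(rays, eye, box)
    return Movie(frames=frames, dt=dt, grid=grid,
                 log={"kind": [spec.kind], "speed": [spec.speed]})


# ---------------------------------------------------------------------------
# rigidly drifting full-field patterns
# ---------------------------------------------------------------------------

def checkerboard(period_deg: float = 20.0):
    """Checkerboard pattern function of (azimuth, elevation) with the given
    full period (two checks) in degrees."""
    def pattern(az, el):
        c = period_deg / 2.0
        return ((np.floor(az / c) + np.floor(el / c)).astype(np.int64) & 1
                ).astype(float)
    return pattern


def sine_grating(wavelength_deg: float, orientation: str = "vertical",
                 amplitude: float = 0.5, mean: float = 0.5):
    """Sinusoidal grating; 'vertical' bars vary along azimuth (drift left or
    right), 'horizontal' bars vary along elevation (drift up or down)."""
    def pattern(az, el):
        x = az if orientation == "vertical" else el
        return mean + amplitude * np.sin(2.0 * np.pi * x / wavelength_deg)
    return pattern


_SHIFT = {"right": (1.0, 0.0), "left": (-1.0, 0.0),
          "up": (0.0, 1.0), "down": (0.0, -1.0)}


def render_uniform_motion(direction: str, speed: float, duration: float,
                          pattern=None, grid: RetinalGrid | None = None,
                          dt: float = 2.0) -> Movie:
    """Rigid drift of a full-field pattern at constant speed (deg/s).

    The pattern is evaluated in pattern coordinates shifted opposite to the
    motion, so features move in the named direction; azimuth wraps.
    """
    grid = grid or RetinalGrid()
    pattern = pattern or checkerboard()
    sx, sy = _SHIFT[direction]
    az, el = grid.mesh()
    n = max(1, int(round(duration / dt)))
    frames = np.empty((n,) + grid.shape)
    for k in range(n):
        shift = speed * k * dt * 1e-3
        a = (az - sx * shift + 180.0) % 360.0 - 180.0
        e = el - sy * shift
        frames[k] = pattern(a, e)
    return Movie(frames=frames, dt=dt, grid=grid,
                 log={"direction": [direction], "speed": [speed]})
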