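"""Closed-form optic-flow fields on the unit sphere and their inner products.

The eye is a unit sphere; a viewing direction at azimuth phi, elevation
theta is x = (cos th cos ph, cos th sin ph, sin th) with x = forward,
y = rightward, z = up.  The local tangent basis at x is
e_phi = (-sin ph, cos ph, 0) (longitude) and
e_theta = (-sin th cos ph, -sin th sin ph, cos th) (latitude).

A rotation about the unit axis R (magnitude omega) induces the flow
v(x) = omega R x x; a translation along the unit axis T (speed v, constant
nearness mu) induces v(x) = mu v ((T.x) x - T), with the focus of expansion
at +T.  In tangent components:

    rotation:     f_phi   = omega (cos th sin thR - sin th cos thR cos(ph - phR))
                  f_theta = omega cos thR sin(ph - phR)
    translation:  f_phi   = mu v cos thT sin(ph - phT)
                  f_theta = mu v (sin th cos thT cos(ph - phT) - cos th sin thT)

The inner product of two fields is the area-weighted integral of the
pointwise dot product, quadrature weight cos(theta).  On the full sphere
the six flow fields of three orthogonal rotation axes and three orthogonal
translation axes are mutually orthogonal with squared norm 8*pi/3 (times
mu^2 for translations), so the optic-flow space is six-dimensional and an
ideal matched filter for one self-motion component is blind to all others.
These statements persist when the receptive field is windowed to the
symmetric sub-domain |phi| <= pi - eps_phi, |theta| <= pi/2 - eps_theta
around the sensor axis, only the norm shrinking to  A(eps) - Jx(eps)  (the
domain area minus its second moment along the sensor axis); same-kind
tuning remains exactly the cosine of the inter-axis angle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionAxis",
    "SphericalDomain",
    "AnalyticFlowField",
    "rotational_flow",
    "translational_flow",
    "inner_product",
    "sensor_norm_squared",
    "ideal_sensor_action_field",
    "numeric_action_field_of_field",
]


@dataclass(frozen=True)
class MotionAxis:
    kind: str                  # 'rotation' | 'translation'
    direction: tuple           # unit 3-vector
    magnitude: float = 1.0     # omega (rad/s) or v (units/s)

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("axis direction must be a unit vector")
        if self.kind not in ("rotation", "translation"):
            raise ValueError(f"unknown motion kind {self.kind!r}")

    @classmethod
    def from_angles(cls, kind: str, azimuth_deg: float, elevation_deg: float,
                    magnitude: float = 1.0) -> "MotionAxis":
        ph = np.radians(azimuth_deg)
        th = np.radians(elevation_deg)
        d = (np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), np.sin(th))
        return cls(kind=kind, direction=d, magnitude=magnitude)

    @property
    def vec(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def angles(self) -> tuple[float, float]:
        """(azimuth, elevation) of the axis in radians."""
        x, y, z = self.vec
        return float(np.arctan2(y, x)), float(np.arcsin(np.clip(z, -1, 1)))


@dataclass(frozen=True)
class SphericalDomain:
    """Symmetric sub-domain |phi| <= pi - eps_phi, |theta| <= pi/2 - eps_theta."""
    eps_phi: float = 0.0    # rad
    eps_theta: float = 0.0  # rad

    def __post_init__(self):
        if self.eps_phi < 0 or self.eps_theta < 0:
            raise ValueError("eps_phi and eps_theta must be non-negative")
        if self.eps_phi >= np.pi or self.eps_theta >= np.pi / 2:
            raise ValueError("degenerate domain (zero area)")

    @property
    def phi_max(self) -> float:
        return np.pi - self.eps_phi

    @property
    def theta_max(self) -> float:
        return np.pi / 2 - self.eps_theta

    @property
    def area(self) -> float:
        return 4.0 * self.phi_max * np.cos(self.eps_theta)

    def second_moment_axis(self) -> float:
        """Integral of (x . x_axis)^2 = cos^2 th cos^2 ph over the domain."""
        b, a = self.phi_max, self.theta_max
        int_phi = b + 0.5 * np.sin(2.0 * b)
        int_theta = 2.0 * (np.sin(a) - np.sin(a) ** 3 / 3.0)
        return int_theta * int_phi


FULL_SPHERE = SphericalDomain()


class AnalyticFlowField:
    """Tangential flow field of one pure rotation or translation."""

    def __init__(self, axis: MotionAxis, mu: float = 1.0):
        self.axis = axis
        self.mu = mu if axis.kind == "translation" else 1.0

    def components(self, azimuth_deg, elevation_deg):
        """(f_phi, f_theta) tangent components at the given angles (deg)."""
        ph = np.radians(np.asarray(azimuth_deg, dtype=float))
        th = np.radians(np.asarray(elevation_deg, dtype=float))
        ph_a, th_a = self.axis.angles
        mag = self.axis.magnitude
        if self.axis.kind == "rotation":
            f_phi = mag * (np.cos(th) * np.sin(th_a)
                           - np.sin(th) * np.cos(th_a) * np.cos(ph - ph_a))
            f_theta = mag * np.cos(th_a) * np.sin(ph - ph_a)
        else:
            s = self.mu * mag
            f_phi = s * np.cos(th_a) * np.sin(ph - ph_a)
            f_theta = s * (np.sin(th) * np.cos(th_a) * np.cos(ph - ph_a)
                           - np.cos(th) * np.sin(th_a))
        return f_phi, f_theta

    def vectors3d(self, azimuth_deg, elevation_deg):
        """The same flow as 3-D vectors (for cross-checking and plotting)."""
        ph = np.radians(np.asarray(azimuth_deg, dtype=float))
        th = np.radians(np.asarray(elevation_deg, dtype=float))
        x = np.stack([np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph),
                      np.sin(th)], axis=-1)
        a = self.axis.vec
        if self.axis.kind == "rotation":
            return self.axis.magnitude * np.cross(np.broadcast_to(a, x.shape), x)
        proj = (x @ a)[..., None] * x
        return self.mu * self.axis.magnitude * (proj - a)


def rotational_flow(axis: MotionAxis) -> AnalyticFlowField:
    """Flow field of a pure rotation; independent of nearness."""
    if axis.kind != "rotation":
        raise ValueError("axis kind must be 'rotation'")
    return AnalyticFlowField(axis)


def translational_flow(axis: MotionAxis, mu: float = 1.0) -> AnalyticFlowField:
    """Flow field of a pure translation at constant nearness mu > 0."""
    if axis.kind != "translation":
        raise ValueError("axis kind must be 'translation'")
    if mu <= 0:
        raise ValueError("nearness mu must be positive")
    return AnalyticFlowField(axis, mu=mu)


def _quad_grid(domain: SphericalDomain, spacing_deg: float):
    """Midpoint quadrature nodes and weights on the domain (degrees)."""
    h = np.radians(spacing_deg)
    n_ph = max(1, int(round(2.0 * domain.phi_max / h)))
    n_th = max(1, int(round(2.0 * domain.theta_max / h)))
    ph = -domain.phi_max + (np.arange(n_ph) + 0.5) * (2.0 * domain.phi_max / n_ph)
    th = -domain.theta_max + (np.arange(n_th) + 0.5) * (2.0 * domain.theta_max / n_th)
    PH, TH = np.meshgrid(ph, th)
    w = np.cos(TH) * (2.0 * domain.phi_max / n_ph) * (2.0 * domain.theta_max / n_th)
    return np.degrees(PH), np.degrees(TH), w


def inner_product(f: AnalyticFlowField, g: AnalyticFlowField,
                  domain: SphericalDomain = FULL_SPHERE,
                  spacing_deg: float = 1.0) -> float:
    """Area-weighted integral of the pointwise dot product of two fields."""
    az, el, w = _quad_grid(domain, spacing_deg)
    f_ph, f_th = f.components(az, el)
    g_ph, g_th = g.components(az, el)
    return float(np.sum(w * (f_ph * g_ph + f_th * g_th)))


def sensor_norm_squared(sensor_kind: str, domain: SphericalDomain = FULL_SPHERE,
                        mu: float = 1.0) -> float:
    """Closed-form squared norm of an ideal sensor's receptive field.

    For both a rotation sensor (field R x x) and a translation sensor
    (field mu((T.x)x - T)) restricted to the symmetric domain around its
    own axis, the squared norm is  Area - Jx, the domain area minus its
    second moment along the axis (times mu^2 for translation); 8*pi/3 on
    the full sphere.
    """
    base = domain.area - domain.second_moment_axis()
    return base * (mu ** 2 if sensor_kind == "translation" else 1.0)


def ideal_sensor_action_field(sensor_kind: str, sensor_axis: MotionAxis,
                              probe: MotionAxis,
                              domain: SphericalDomain = FULL_SPHERE,
                              mu: float = 1.0,
                              method: str = "closed_form",
                              spacing_deg: float = 1.0) -> float:
    """Response of an ideal matched-filter sensor to a probe self-motion.

    The sensor's receptive field equals the flow field of its own kind
    about/along ``sensor_axis``, windowed to ``domain`` (a symmetric cap
    around the sensor axis).  Closed form: zero across kinds; for matching
    kinds  norm^2 * cos(angle between axes) * probe magnitude.  The
    quadrature route evaluates the same integral numerically and is only
    available for a sensor on the +x axis (the domain is tied to the
    sensor's own frame).
    """
    if method == "closed_form":
        if sensor_kind != probe.kind:
            return 0.0
        cos_gamma = float(np.dot(sensor_axis.vec, probe.vec))
        norm2 = sensor_norm_squared(sensor_kind, domain, mu)
        return norm2 * cos_gamma * probe.magnitude * sensor_axis.magnitude
    if method == "quadrature":
        if not np.allclose(sensor_axis.vec, [1.0, 0.0, 0.0], atol=1e-12):
            raise ValueError("quadrature route requires the sensor on the +x axis")
        if sensor_kind == "rotation":
            sensor = rotational_flow(MotionAxis("rotation", (1, 0, 0),
                                                sensor_axis.magnitude))
        else:
            sensor = translational_flow(MotionAxis("translation", (1, 0, 0),
                                                   sensor_axis.magnitude), mu=mu)
        if probe.kind == "rotation":
            probe_field = rotational_flow(probe)
        else:
            probe_field = translational_flow(probe, mu=mu)
        return inner_product(sensor, probe_field, domain, spacing_deg)
    raise ValueError(f"unknown method {method!r}")


def numeric_action_field_of_field(h: np.ndarray, v: np.ndarray,
                                  azimuths_deg: np.ndarray,
                                  elevations_deg: np.ndarray,
                                  probe: MotionAxis, mu: float = 1.0) -> float:
    """Area-weighted mean dot product of a sampled receptive field with the
    analytic flow field of a probe self-motion.

    ``h`` and ``v`` are the horizontal (along +azimuth) and vertical (along
    +elevation) receptive-field components on the regular grid
    (elevation rows x azimuth columns); this bridges simulated receptive
    fields to the analytic action-field predictions.
    """
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    az, el = np.meshgrid(azimuths_deg, elevations_deg)
    if h.shape != az.shape or v.shape != az.shape:
        raise ValueError("receptive-field components do not match the grid")
    if probe.kind == "rotation":
        fld = rotational_flow(probe)
    else:
        fld = translational_flow(probe, mu=mu)
    f_ph, f_th = fld.components(az, el)
    w = np.cos(np.radians(el))
    return float(np.sum(w * (h * f_ph + v * f_th)) / np.sum(w))
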