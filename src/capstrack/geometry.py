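"""Local cylinder model of the colon and the camera projection geometry.

A capsule camera head looks down the bowel, which is approximated locally
as a cylinder of radius ``R``.  A wall point at axial distance ``D`` ahead
of the camera subtends the inclination angle ``theta = atan(R / D)`` with
the optical axis.  After the capsule advances a distance ``d`` the same
point subtends ``atan(R / (D - d))``.  Eliminating the unobservable depth
``D`` from the two relations gives the axial displacement in closed form::

    d = R * (cot(theta_t) - cot(theta_t1))

which is the quantity every speed estimate in this package is built from.

On the sensor a wall point appears at polar position ``(r, phi)`` around
the optical centre.  Frames are unwrapped to Cartesian coordinates
``x = L * phi / (2 pi)``, ``y = r`` so that capsule roll becomes a pure
horizontal translation.  The pixel radius maps to the inclination angle
through the small-angle linear model ``theta = eta_eff * y / H`` where
``eta_eff`` is the half field of view (a 172 degree head sees 86 degrees
off-axis at the frame edge) and ``H`` the usable pixel radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraGeometry",
    "CylinderModel",
    "PolarPoint",
    "UnwrappedPoint",
    "InclinationPair",
    "unwrap_point",
    "rewrap_point",
    "inclination_angle",
    "axial_displacement",
    "pair_tilt_magnitude",
    "unwrap_frame",
    "usable_angle_mask",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CameraGeometry:
    """Projection geometry of one camera head.

    Parameters
    ----------
    field_of_view_deg:
        Full cone angle of the head in degrees.  The half angle is the
        inclination of a ray hitting the edge of the usable image area.
    optical_center:
        ``(row, col)`` pixel coordinates of the cylinder axis in the raw
        frame.  Defaults to the geometric centre of a 256 x 256 frame.
    usable_radius_px:
        Largest radius from the optical centre that still images tissue.
    unwrapped_width_L:
        Width of the unwrapped (Cartesian) frame; one full turn of
        azimuth maps onto ``L`` pixels.
    unwrapped_height_H:
        Height of the unwrapped frame; equals the radial pixel count so
        ``y = r`` holds exactly.
    theta_min_deg, theta_max_deg:
        Inclination window outside which points are excluded from
        displacement estimation (cot(theta) blows up at 0 and 90 deg).
    """

    field_of_view_deg: float = 172.0
    optical_center: tuple[float, float] = (128.0, 128.0)
    usable_radius_px: float = 128.0
    unwrapped_width_L: int = 512
    unwrapped_height_H: int = 128
    theta_min_deg: float = 2.0
    theta_max_deg: float = 84.0

    def __post_init__(self) -> None:
        if not (0.0 < self.field_of_view_deg <= 180.0):
            raise ValueError("field_of_view_deg must be in (0, 180]")
        if self.usable_radius_px <= 0:
            raise ValueError("usable_radius_px must be positive")
        if self.unwrapped_width_L <= 0 or self.unwrapped_height_H <= 0:
            raise ValueError("unwrapped frame dimensions must be positive")
        if not (0.0 <= self.theta_min_deg < self.theta_max_deg < 90.0):
            raise ValueError("need 0 <= theta_min < theta_max < 90 degrees")

    @property
    def eta_eff(self) -> float:
        """Half field of view in radians; the angle at ``y = H``."""
        return np.deg2rad(self.field_of_view_deg / 2.0)

    @property
    def theta_min(self) -> float:
        return np.deg2rad(self.theta_min_deg)

    @property
    def theta_max(self) -> float:
        return np.deg2rad(self.theta_max_deg)


@dataclass(frozen=True)
class CylinderModel:
    """Local cylindrical approximation of the bowel, radius in cm."""

    radius_R: float

    def __post_init__(self) -> None:
        if self.radius_R <= 0:
            raise ValueError("radius_R must be positive")


@dataclass(frozen=True)
class PolarPoint:
    """Sensor-plane position: radius in pixels, azimuth in [0, 2pi)."""

    r: float
    phi: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")
        object.__setattr__(self, "phi", float(np.mod(self.phi, TWO_PI)))


@dataclass(frozen=True)
class UnwrappedPoint:
    """Cartesian position in the unwrapped frame, x in [0, L), y = r."""

    x: float
    y: float


@dataclass(frozen=True)
class InclinationPair:
    """Inclination angles of one tracked point at times t and t+1."""

    theta_t: float
    theta_t1: float
    delta_theta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_theta", self.theta_t1 - self.theta_t)


def unwrap_point(p: PolarPoint, g: CameraGeometry) -> UnwrappedPoint:
    """Map a sensor-plane polar point to unwrapped Cartesian coordinates.

    ``x = L * phi / (2 pi)``, ``y = r``.  Raises ``ValueError`` when the
    point lies outside the usable tissue annulus; estimators catch this
    and drop the point rather than fail.
    """
    if p.r > g.usable_radius_px:
        raise ValueError("point outside usable radius; exclude from estimation")
    return UnwrappedPoint(x=g.unwrapped_width_L * p.phi / TWO_PI, y=p.r)


def rewrap_point(u: UnwrappedPoint, g: CameraGeometry) -> PolarPoint:
    """Inverse of :func:`unwrap_point` (up to azimuth wrapping)."""
    return PolarPoint(r=u.y, phi=TWO_PI * u.x / g.unwrapped_width_L)


def inclination_angle(y, g: CameraGeometry):
    """Inclination angle of a ray through unwrapped row ``y``.

    Linear small-angle pixel-to-angle map ``theta = eta_eff * y / H``;
    accepts a scalar, an :class:`UnwrappedPoint`, or an array of ``y``
    values, and returns radians in ``[0, eta_eff]``.
    """
    if isinstance(y, UnwrappedPoint):
        y = y.y
    y = np.asarray(y, dtype=float)
    H = g.unwrapped_height_H
    if np.any(y < 0) or np.any(y > H):
        raise ValueError("y outside [0, H]")
    theta = g.eta_eff * y / H
    return float(theta) if theta.ndim == 0 else theta


def axial_displacement(pair, cyl: CylinderModel):
    """Axial distance travelled between frames, from one tracked point.

    ``d = R * (cot(theta_t) - cot(theta_t1))`` -- positive when the
    capsule approaches the point (theta grows), negative when receding.
    Accepts an :class:`InclinationPair` or two broadcastable angle
    arrays via ``axial_displacement((theta_t, theta_t1), cyl)``.
    """
    if isinstance(pair, InclinationPair):
        t0, t1 = pair.theta_t, pair.theta_t1
    else:
        t0, t1 = pair
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(t0 <= 0) or np.any(t0 >= np.pi / 2) or np.any(t1 <= 0) or np.any(t1 >= np.pi / 2):
        raise ValueError("angles must lie strictly inside (0, pi/2)")
    d = cyl.radius_R * (1.0 / np.tan(t0) - 1.0 / np.tan(t1))
    return float(d) if d.ndim == 0 else d


def pair_tilt_magnitude(dp, dq):
    """Tilt magnitude of a feature-point pair.

    ``Omega = |dp - dq| / max(dp, dq)`` where ``dp`` and ``dq`` are the
    between-frame inclination changes of two distinct points.  Lies in
    [0, 1] for non-negative inputs and is symmetric in its arguments.
    Raises when the normaliser ``max(dp, dq)`` vanishes (the caller
    excludes such pairs).
    """
    dp = np.asarray(dp, dtype=float)
    dq = np.asarray(dq, dtype=float)
    m = np.maximum(dp, dq)
    if np.any(m == 0):
        raise ValueError("max(dp, dq) = 0: pair carries no tilt information")
    out = np.abs(dp - dq) / m
    return float(out) if out.ndim == 0 else out


def usable_angle_mask(theta_t: np.ndarray, theta_t1: np.ndarray, g: CameraGeometry) -> np.ndarray:
    """Boolean mask of point pairs whose angles are safe for cot()."""
    lo, hi = g.theta_min, g.theta_max
    return (theta_t > lo) & (theta_t < hi) & (theta_t1 > lo) & (theta_t1 < hi)


def unwrap_frame(frame: np.ndarray, g: CameraGeometry, order: int = 1) -> np.ndarray:
    """Resample a raw polar frame onto the unwrapped Cartesian grid.

    Output shape is ``(H, L)``: row ``y`` is sensor radius, column ``x``
    is azimuth ``2 pi x / L``.  Bilinear interpolation by default; the
    azimuth axis wraps.
    """
    from scipy.ndimage import map_coordinates

    H, L = g.unwrapped_height_H, g.unwrapped_width_L
    y = np.arange(H, dtype=float)[:, None]
    x = np.arange(L, dtype=float)[None, :]
    r = y * (g.usable_radius_px / H)
    phi = TWO_PI * x / L
    rows = g.optical_center[0] + r * np.sin(phi)
    cols = g.optical_center[1] + r * np.cos(phi)
    return map_coordinates(
        np.asarray(frame, dtype=float), [rows, cols], order=order, mode="nearest"
    )
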