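"""Most-likely per-frame motion parameters from a filtered match set.

Every matched feature point yields one noisy estimate of the capsule's
displacement, roll and tilt; the per-frame value adopted is the *mode*
of the ensemble distribution (the most likely value), not the mean --
a deliberate robustness choice, since a handful of mismatched points
can skew an average arbitrarily while barely moving the density peak.
The mode is realized as the argmax of a Gaussian kernel density
estimate evaluated on a regular grid spanning the sample range.

Estimated quantities per frame transition t -> t+1:

* speed ``v``: mode of ``f * d_P`` over points P, with ``d_P`` the
  cylinder-model axial displacement of point P;
* roll ``gamma``: mode of the horizontal unwrapped displacement
  ``dx_P`` (wrapped to half a turn) scaled to radians;
* tilt ``(Omega, omega)``: the pairwise statistic
  ``|d_theta_P - d_theta_Q| / max(d_theta_P, d_theta_Q)`` over point
  pairs, gated to the top ``xi`` fraction of its distribution, with the
  direction taken as the circular mode of the azimuths of the
  dominant pair members;
* pitch/yaw: ``alpha = Omega cos(omega)``, ``beta = Omega sin(omega)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .features import MatchSet
from .geometry import (
    CameraGeometry,
    CylinderModel,
    TWO_PI,
    inclination_angle,
    usable_angle_mask,
)

__all__ = [
    "ModeEstimatorConfig",
    "TiltConfig",
    "MotionEstimate",
    "InvalidEstimate",
    "mode_of",
    "circular_mode",
    "unit_displacement_samples",
    "estimate_speed",
    "estimate_roll",
    "estimate_tilt",
    "pitch_yaw",
    "estimate_motion",
]


class InvalidEstimate(ValueError):
    """Raised when too few samples support an estimate; callers fall back."""


@dataclass(frozen=True)
class ModeEstimatorConfig:
    method: str = "kde"  # "kde" | "histogram"
    bandwidth: str | float = "silverman"
    grid_size: int = 512
    min_samples: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("kde", "histogram"):
            raise ValueError(f"unknown mode method {self.method!r}")
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass(frozen=True)
class TiltConfig:
    """Pair-statistic settings: gate fraction xi, pair cap, output scale.

    The quantile-gated ratio distribution is sharply peaked at its
    upper support edge, where Silverman's bandwidth rule (tuned for
    near-Gaussian densities) over-smooths badly; the magnitude mode
    therefore shrinks the bandwidth by ``magnitude_bandwidth_scale``.
    The kept-pair azimuth density is a broad symmetric bump centred on
    the tilt direction, so the direction mode uses a wide von Mises
    kernel (``omega_kappa``) that locates the bump centre robustly.
    """

    xi: float = 0.25
    max_pairs: int = 20_000
    scale: float = 1.0  # radians per unit of the dimensionless pair ratio
    omega_grid: int = 360
    omega_kappa: float = 1.0
    magnitude_bandwidth_scale: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if self.max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")


@dataclass(frozen=True)
class MotionEstimate:
    """Most-likely motion of one frame transition."""

    v: float
    gamma: float
    Omega: float
    omega: float
    alpha: float
    beta: float
    frame_index: int = 0
    valid: bool = True
    n_support: int = 0


def mode_of(samples, cfg: ModeEstimatorConfig | None = None) -> float:
    """Most likely value of a sample ensemble.

    KDE (Gaussian, Silverman bandwidth by default) evaluated on a
    regular grid spanning the sample range; ties break toward the
    smallest grid value.  Degenerate ensembles (all values equal)
    return that value directly.  Raises :class:`InvalidEstimate` below
    ``min_samples``.
    """
    cfg = cfg or ModeEstimatorConfig()
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < cfg.min_samples or len(x) == 0:
        raise InvalidEstimate(f"{len(x)} samples < min_samples={cfg.min_samples}")
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-15 * max(1.0, abs(hi)):
        return float(x[0])
    grid = np.linspace(lo, hi, cfg.grid_size)
    if cfg.method == "histogram":
        counts, edges = np.histogram(x, bins=cfg.grid_size)
        return float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
    kde = gaussian_kde(x, bw_method=cfg.bandwidth)
    return float(grid[int(np.argmax(kde(grid)))])


def circular_mode(angles, grid_size: int = 360, concentration: float | None = None) -> float:
    """Most likely angle of a circular sample, in [0, 2pi).

    Von Mises kernel density on a regular grid; the concentration
    defaults to a Silverman-style rule mapped onto the circle.
    """
    a = np.mod(np.asarray(angles, dtype=float).ravel(), TWO_PI)
    if len(a) == 0:
        raise InvalidEstimate("no angles")
    if len(a) == 1:
        return float(a[0])
    if concentration is None:
        # circular spread -> bandwidth -> kappa ~ 1/h^2
        C, S = np.cos(a).mean(), np.sin(a).mean()
        Rbar = min(np.hypot(C, S), 1.0 - 1e-12)
        sigma = np.sqrt(max(-2.0 * np.log(Rbar), 1e-6))
        h = 1.06 * sigma * len(a) ** (-0.2)
        concentration = 1.0 / max(h * h, 1e-6)
    grid = np.linspace(0.0, TWO_PI, grid_size, endpoint=False)
    dens = np.exp(concentration * (np.cos(grid[:, None] - a[None, :]) - 1.0)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def _angles(ms: MatchSet, g: CameraGeometry):
    theta_t = inclination_angle(np.clip(ms.points_t[:, 1], 0, g.unwrapped_height_H), g)
    theta_t1 = inclination_angle(np.clip(ms.points_t1[:, 1], 0, g.unwrapped_height_H), g)
    return np.atleast_1d(theta_t), np.atleast_1d(theta_t1)


def unit_displacement_samples(ms: MatchSet, g: CameraGeometry) -> np.ndarray:
    """Per-match axial displacement per unit cylinder radius, ``d / R``.

    Equals ``cot(theta_t) - cot(theta_t1)``; points whose angles fall
    outside the usable window are dropped.  The caller multiplies by a
    radius draw to obtain displacements in cm -- factoring the radius
    out lets one match set serve every prior draw.
    """
    if ms.FP == 0:
        return np.empty((0,))
    theta_t, theta_t1 = _angles(ms, g)
    ok = usable_angle_mask(theta_t, theta_t1, g)
    return 1.0 / np.tan(theta_t[ok]) - 1.0 / np.tan(theta_t1[ok])


def estimate_speed(
    ms: MatchSet,
    g: CameraGeometry,
    cyl: CylinderModel,
    f: float,
    cfg: ModeEstimatorConfig | None = None,
) -> float:
    """Most likely axial speed in cm/s; sign is direction along the axis."""
    if f <= 0:
        raise ValueError("sample frequency must be positive")
    unit = unit_displacement_samples(ms, g)
    if len(unit) == 0:
        raise InvalidEstimate("no usable matches for speed")
    return f * cyl.radius_R * mode_of(unit, cfg)


def wrapped_dx(ms: MatchSet, L: float) -> np.ndarray:
    """Horizontal displacements wrapped to (-L/2, L/2] (seam-safe)."""
    dx = ms.points_t1[:, 0] - ms.points_t[:, 0]
    return -((-dx + L / 2.0) % L - L / 2.0)


def estimate_roll(
    ms: MatchSet, g: CameraGeometry, cfg: ModeEstimatorConfig | None = None
) -> float:
    """Most likely roll angle in radians from horizontal displacements."""
    if ms.FP == 0:
        raise InvalidEstimate("no matches for roll")
    L = g.unwrapped_width_L
    return TWO_PI * mode_of(wrapped_dx(ms, L), cfg) / L


def estimate_tilt(
    ms: MatchSet,
    g: CameraGeometry,
    tcfg: TiltConfig | None = None,
    cfg: ModeEstimatorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Most likely tilt magnitude and direction.

    All distinct point pairs (subsampled to ``max_pairs`` when the
    match count is large) contribute the dimensionless ratio
    ``|d_theta_P - d_theta_Q| / max(d_theta_P, d_theta_Q)``; only pairs
    at or above the ``(1 - xi)`` empirical quantile are kept.  The
    magnitude is the argmax of the pair-ratio density restricted to
    the kept region (times ``scale``); the direction is the circular
    mode of the azimuths at t+1 of the dominant (larger d_theta)
    member of each kept pair.
    """
    tcfg = tcfg or TiltConfig()
    cfg = cfg or ModeEstimatorConfig()
    if ms.FP < 2:
        raise InvalidEstimate("tilt needs at least two matches")
    theta_t, theta_t1 = _angles(ms, g)
    dtheta = theta_t1 - theta_t
    # orient by the dominant motion direction so a receding camera
    # (all inclination changes negative) is handled symmetrically to an
    # advancing one; the ratio statistic needs a positive normaliser
    if np.median(dtheta) < 0:
        dtheta = -dtheta
    if np.all(dtheta == 0.0):
        # stationary view: no inclination change anywhere, hence no tilt
        return 0.0, 0.0
    n = len(dtheta)
    ii, jj = np.triu_indices(n, k=1)
    if len(ii) > tcfg.max_pairs:
        rng = rng or np.random.default_rng(0)
        sel = rng.choice(len(ii), size=tcfg.max_pairs, replace=False)
        ii, jj = ii[sel], jj[sel]
    dp, dq = dtheta[ii], dtheta[jj]
    m = np.maximum(dp, dq)
    ok = m > 0
    if not np.any(ok):
        raise InvalidEstimate("no pair carries tilt information")
    dp, dq, m = dp[ok], dq[ok], m[ok]
    ii, jj = ii[ok], jj[ok]
    ratio = np.abs(dp - dq) / m
    cut = np.quantile(ratio, 1.0 - tcfg.xi)
    keep = ratio >= cut
    kept = ratio[keep]
    if len(kept) == 1 or kept.max() - kept.min() < 1e-15:
        Omega = float(kept[0])
    else:
        # argmax of the *full* pair-ratio density restricted to the
        # gated region: estimating a density from the truncated sample
        # instead would raise a spurious peak at the cut boundary
        bw = cfg.bandwidth
        if bw == "silverman":
            bw = tcfg.magnitude_bandwidth_scale * len(ratio) ** (-0.2) * 1.06
        kde = gaussian_kde(ratio, bw_method=bw)
        grid = np.linspace(cut, float(ratio.max()), cfg.grid_size)
        if cfg.method == "histogram":
            counts, edges = np.histogram(ratio, bins=cfg.grid_size)
            centers = 0.5 * (edges[:-1] + edges[1:])
            sel = centers >= cut
            Omega = float(centers[sel][np.argmax(counts[sel])])
        else:
            Omega = float(grid[int(np.argmax(kde(grid)))])
    # azimuth of the pair member with the larger inclination change
    dominant = np.where(dp[keep] >= dq[keep], ii[keep], jj[keep])
    phi = TWO_PI * ms.points_t1[dominant, 0] / g.unwrapped_width_L
    omega = circular_mode(phi, grid_size=tcfg.omega_grid, concentration=tcfg.omega_kappa)
    return tcfg.scale * Omega, omega


def pitch_yaw(Omega: float, omega: float) -> tuple[float, float]:
    """Split tilt magnitude/direction into pitch and yaw angles."""
    if Omega < 0:
        raise ValueError("Omega must be non-negative")
    return Omega * np.cos(omega), Omega * np.sin(omega)


def estimate_motion(
    ms: MatchSet,
    g: CameraGeometry,
    cyl: CylinderModel,
    f: float,
    cfg: ModeEstimatorConfig | None = None,
    tcfg: TiltConfig | None = None,
    rng: np.random.Generator | None = None,
    frame_index: int = 0,
) -> MotionEstimate:
    """All motion parameters of one transition; invalid on thin support."""
    cfg = cfg or ModeEstimatorConfig()
    try:
        v = estimate_speed(ms, g, cyl, f, cfg)
        gamma = estimate_roll(ms, g, cfg)
        Omega, omega = estimate_tilt(ms, g, tcfg, cfg, rng=rng)
    except InvalidEstimate:
        return MotionEstimate(
            0.0, 0.0, 0.0, 0.0, 0.0, 0.0, frame_index=frame_index, valid=False, n_support=ms.FP
        )
    alpha, beta = pitch_yaw(Omega, omega)
    return MotionEstimate(
        v, gamma, Omega, omega, alpha, beta,
        frame_index=frame_index, valid=True, n_support=ms.FP,
    )
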