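"""Dead-reckoning integration of per-frame motion into a 3-D path.

The capsule state is a position in the observer frame plus an
orientation: a rotation matrix ``R`` and a unit heading vector ``s``.
Each frame's pitch/yaw/roll increments are composed as elementary
rotations and applied by conjugation with the current orientation,
``R_{t+1} = R_t Rx Ry Rz R_t^{-1}``, so that the increment acts in the
capsule's own axes; the heading advances as ``s_{t+1} = R_{t+1} s_t``
and the position by ``(v/f) s_t`` (pre-update heading).  Products of
rotations drift off SO(3) in floating point, so the matrix is snapped
back to the nearest rotation (polar decomposition) after every update.

When a frame is unusable -- too few feature points or unacceptable
cleanliness -- the update is replayed from history: each parameter
``h in {v, f, alpha, beta, gamma}`` is taken as its last estimate plus
zero-mean Gaussian noise whose variance is the population variance of
the parameter's history, and the track advances from those noised
values.  Fallback frames do not enter the history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrientationState",
    "TrackState",
    "ParameterHistory",
    "elementary_rotations",
    "update_orientation",
    "advance_track",
    "fallback_update",
    "nearest_rotation",
    "initial_state",
]

logger = logging.getLogger(__name__)

_FALLBACK_PARAMS = ("v", "f", "alpha", "beta", "gamma")


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3) (polar decomposition)."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


@dataclass(frozen=True)
class OrientationState:
    """Rotation matrix plus unit heading vector in the observer frame."""

    R: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "s", s)
        if R.shape != (3, 3) or s.shape != (3,):
            raise ValueError("R must be 3x3 and s a 3-vector")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(s)):
            raise ValueError("non-finite orientation")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6 or abs(np.linalg.det(R) - 1) > 1e-6:
            raise ValueError("R is not a rotation matrix")
        if abs(np.linalg.norm(s) - 1.0) > 1e-6:
            raise ValueError("s must be a unit vector")


@dataclass(frozen=True)
class TrackState:
    position: np.ndarray
    orientation: OrientationState
    t: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", p)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError("position must be a finite 3-vector")


def initial_state(direction=(1.0, 0.0, 0.0)) -> TrackState:
    """Track start at the origin heading along ``direction``.

    The initial rotation maps the capsule roll axis (x) onto the chosen
    heading so that a pure roll leaves the heading invariant.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    d = d / n
    # build an orthonormal frame with first column = d
    a = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    R0 = np.column_stack([d, u, w])
    if np.linalg.det(R0) < 0:
        R0[:, 2] *= -1.0
    return TrackState(np.zeros(3), OrientationState(R0, d), t=0)


def elementary_rotations(alpha: float, beta: float, gamma: float):
    """Elementary rotations: Rx by roll gamma, Ry by yaw beta, Rz by pitch alpha."""
    for v in (alpha, beta, gamma):
        if not np.isfinite(v):
            raise ValueError("angles must be finite")
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    Rx = np.array([[1, 0, 0], [0, cg, -sg], [0, sg, cg]], dtype=float)
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]], dtype=float)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]], dtype=float)
    return Rx, Ry, Rz


def update_orientation(
    st: OrientationState, alpha: float, beta: float, gamma: float
) -> OrientationState:
    """One orientation step by conjugated elementary rotations.

    The body-frame increment ``Rx Ry Rz`` is conjugated with the
    current orientation into the observer frame,
    ``Q = R_t Rx Ry Rz R_t^{-1}``, and ``Q`` advances both the
    accumulated rotation (``R_{t+1} = Q R_t``, i.e. ``R_t Rx Ry Rz``)
    and the heading (``s_{t+1} = Q s_t``).  Zero angles therefore leave
    the state unchanged, and a pure roll -- a rotation about the
    capsule's own axis -- leaves the heading invariant.
    """
    Rx, Ry, Rz = elementary_rotations(alpha, beta, gamma)
    Q = nearest_rotation(st.R @ Rx @ Ry @ Rz @ st.R.T)
    R_new = nearest_rotation(Q @ st.R)
    s_new = Q @ st.s
    s_new = s_new / np.linalg.norm(s_new)
    return OrientationState(R_new, s_new)


def advance_track(
    st: TrackState, v: float, f: float, orient: OrientationState
) -> TrackState:
    """Advance position by ``(v/f)`` along the pre-update heading.

    ``orient`` is the already-updated orientation carried into the next
    state; the position increment uses the heading *before* the update.
    """
    if f <= 0:
        raise ValueError("sample frequency must be positive")
    pos = st.position + (v / f) * st.orientation.s
    return TrackState(pos, orient, t=st.t + 1)


@dataclass
class ParameterHistory:
    """Per-parameter history of accepted (non-fallback) estimates."""

    values: dict = field(
        default_factory=lambda: {h: [] for h in _FALLBACK_PARAMS}
    )

    def append(self, v: float, f: float, alpha: float, beta: float, gamma: float) -> None:
        for h, x in zip(_FALLBACK_PARAMS, (v, f, alpha, beta, gamma)):
            self.values[h].append(float(x))

    def __len__(self) -> int:
        return len(self.values["v"])

    def last(self, h: str) -> float:
        return self.values[h][-1]

    def mean(self, h: str) -> float:
        return float(np.mean(self.values[h]))

    def variance(self, h: str) -> float:
        """Population (1/t) variance of the stored sequence."""
        x = np.asarray(self.values[h], dtype=float)
        return float(np.mean((x - x.mean()) ** 2))


def fallback_update(
    st: TrackState,
    hist: ParameterHistory,
    rng: np.random.Generator,
) -> tuple[TrackState, dict]:
    """Advance the track from history-noised parameters.

    Each of v, f, alpha, beta, gamma is its most recent accepted value
    plus independent N(0, sigma_h^2) noise with sigma_h^2 the population
    variance of that parameter's history; the motion update is rebuilt
    from the noised values.  An empty history holds the capsule
    stationary for this frame.  Returns the new state and the drawn
    parameter values.
    """
    if len(hist) == 0:
        logger.debug("fallback with empty history: capsule held stationary")
        return TrackState(st.position, st.orientation, t=st.t + 1), {}
    drawn = {}
    for h in _FALLBACK_PARAMS:
        sigma = np.sqrt(hist.variance(h))
        drawn[h] = hist.last(h) + (sigma * rng.standard_normal() if sigma > 0 else 0.0)
    if drawn["f"] <= 0:
        drawn["f"] = max(hist.last("f"), 1e-6)
    orient = update_orientation(st.orientation, drawn["alpha"], drawn["beta"], drawn["gamma"])
    return advance_track(st, drawn["v"], drawn["f"], orient), drawn
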