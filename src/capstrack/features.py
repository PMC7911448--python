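"""Feature-point detection, matching and outlier rejection.

Consecutive unwrapped frames are reduced to a set of point
correspondences: repeatable keypoints with descriptors are detected in
each frame, matched by mutual nearest neighbour with a Lowe-style ratio
test, and filtered for mismatches with RANSAC under a 2-D similarity
transform (capsule roll appears as horizontal translation in unwrapped
coordinates, axial motion as a mild vertical shift, so a low-order
global model separates consistent matches from clutter).

The detector is a pluggable contract, not a fixed algorithm: any
detector producing repeatable keypoints with fixed-length descriptors
serves.  SIFT is the default; ORB is available as a faster binary
alternative.  Because unwrapping cuts the cylinder open at azimuth
zero, each frame is tiled cyclically by a configurable margin before
detection so keypoints straddling the seam are not lost, and duplicate
detections from the tiles are removed before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import ORB, SIFT, match_descriptors
from skimage.measure import ransac as _sk_ransac
from skimage.transform import SimilarityTransform

from .geometry import UnwrappedPoint

__all__ = [
    "Keypoint",
    "Match",
    "MatchSet",
    "DetectorConfig",
    "RansacConfig",
    "detect_keypoints",
    "detect_and_match",
    "match_keypoints",
    "ransac_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Keypoint:
    position: UnwrappedPoint
    scale: float
    descriptor: np.ndarray


@dataclass(frozen=True)
class Match:
    point_t: UnwrappedPoint
    point_t1: UnwrappedPoint
    distance: float


@dataclass
class MatchSet:
    """Correspondences between frames t and t+1 in unwrapped coordinates.

    Point coordinates are stored as ``(n, 2)`` arrays with columns
    ``(x, y)``; ``FP`` is the match count used by the cleanliness gate.
    """

    points_t: np.ndarray
    points_t1: np.ndarray
    distances: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points_t = np.atleast_2d(np.asarray(self.points_t, dtype=float))
        self.points_t1 = np.atleast_2d(np.asarray(self.points_t1, dtype=float))
        self.distances = np.asarray(self.distances, dtype=float)
        if self.points_t.size == 0:
            self.points_t = self.points_t.reshape(0, 2)
            self.points_t1 = self.points_t1.reshape(0, 2)
        if self.points_t.shape != self.points_t1.shape:
            raise ValueError("points_t and points_t1 must have equal shapes")
        if len(self.distances) != len(self.points_t):
            raise ValueError("one distance per match required")

    @property
    def FP(self) -> int:
        return len(self.points_t)

    @property
    def matches(self) -> list[Match]:
        return [
            Match(
                UnwrappedPoint(*self.points_t[i]),
                UnwrappedPoint(*self.points_t1[i]),
                float(self.distances[i]),
            )
            for i in range(self.FP)
        ]

    @classmethod
    def empty(cls, frame_index: int = 0) -> "MatchSet":
        return cls(
            np.empty((0, 2)), np.empty((0, 2)), np.empty((0,)), frame_index=frame_index
        )

    def subset(self, mask: np.ndarray) -> "MatchSet":
        return MatchSet(
            self.points_t[mask],
            self.points_t1[mask],
            self.distances[mask],
            frame_index=self.frame_index,
        )


@dataclass(frozen=True)
class DetectorConfig:
    """Detector and matcher settings.

    ``detector`` selects the keypoint algorithm ('sift' or 'orb';
    'surf' is accepted for compatibility and falls back to SIFT with a
    warning since no patent-free implementation ships here).
    ``seam_tile_frac`` is the fraction of the unwrapped width tiled on
    each side before detection to cover the azimuth seam.
    """

    detector: str = "sift"
    ratio_threshold: float = 0.75
    seam_tile_frac: float = 0.10
    n_keypoints: int = 500  # ORB only
    sift_upsampling: int = 2

    def __post_init__(self) -> None:
        if self.detector not in ("sift", "orb", "surf"):
            raise ValueError(f"unknown detector {self.detector!r}")
        if not 0.0 <= self.seam_tile_frac < 0.5:
            raise ValueError("seam_tile_frac must be in [0, 0.5)")


@dataclass(frozen=True)
class RansacConfig:
    model: str = "similarity"
    tau_px: float = 2.0
    iterations: int = 500

    def __post_init__(self) -> None:
        if self.model != "similarity":
            raise ValueError("only the 2-D similarity model is implemented")
        if self.tau_px <= 0 or self.iterations < 1:
            raise ValueError("tau_px must be > 0 and iterations >= 1")


def _make_detector(cfg: DetectorConfig):
    name = cfg.detector
    if name == "surf":
        logger.warning("SURF unavailable; falling back to SIFT")
        name = "sift"
    if name == "sift":
        return SIFT(upsampling=cfg.sift_upsampling)
    return ORB(n_keypoints=cfg.n_keypoints)


def detect_keypoints(frame: np.ndarray, cfg: DetectorConfig):
    """Detect keypoints and descriptors on one unwrapped gray frame.

    Returns ``(positions, scales, descriptors)`` with positions as an
    ``(n, 2)`` array of ``(x, y)``.  The frame is tiled cyclically by
    ``seam_tile_frac`` on both sides so seam-straddling features are
    found; duplicate detections are collapsed onto canonical azimuth.
    """
    frame = np.asarray(frame, dtype=float)
    H, L = frame.shape
    pad = int(round(cfg.seam_tile_frac * L))
    if pad > 0:
        ext = np.concatenate([frame[:, L - pad :], frame, frame[:, :pad]], axis=1)
    else:
        ext = frame
    det = _make_detector(cfg)
    try:
        det.detect_and_extract(ext)
    except (RuntimeError, IndexError, ValueError):
        # textureless frame: no features is a valid outcome
        return np.empty((0, 2)), np.empty((0,)), np.empty((0, 1))
    rows = det.keypoints[:, 0].astype(float)
    cols = det.keypoints[:, 1].astype(float) - pad
    x = np.mod(cols, L)
    y = rows
    scales = getattr(det, "scales", np.ones(len(x))).astype(float)
    desc = det.descriptors
    # de-duplicate tile copies of the same physical feature
    key = np.round(x).astype(int) * 10 * H + np.round(y).astype(int)
    _, keep = np.unique(key, return_index=True)
    keep = np.sort(keep)
    return np.column_stack([x[keep], y[keep]]), scales[keep], desc[keep]


def match_keypoints(kp_t, kp_t1, cfg: DetectorConfig, frame_index: int = 0) -> MatchSet:
    """Mutual-nearest-neighbour + ratio-test matching of two keypoint sets."""
    pos_t, _, desc_t = kp_t
    pos_t1, _, desc_t1 = kp_t1
    if len(pos_t) == 0 or len(pos_t1) == 0:
        return MatchSet.empty(frame_index)
    # mutual nearest neighbours with the ratio test applied in both
    # directions, so matching is invariant to swapping the two frames
    fwd = match_descriptors(desc_t, desc_t1, cross_check=True, max_ratio=cfg.ratio_threshold)
    bwd = match_descriptors(desc_t1, desc_t, cross_check=True, max_ratio=cfg.ratio_threshold)
    keep = set(map(tuple, bwd[:, ::-1]))
    idx = np.asarray([p for p in map(tuple, fwd) if p in keep], dtype=int)
    if len(idx) == 0:
        return MatchSet.empty(frame_index)
    p0 = pos_t[idx[:, 0]]
    p1 = pos_t1[idx[:, 1]]
    if desc_t.dtype == bool:
        dist = np.count_nonzero(desc_t[idx[:, 0]] != desc_t1[idx[:, 1]], axis=1).astype(float)
    else:
        dist = np.linalg.norm(desc_t[idx[:, 0]] - desc_t1[idx[:, 1]], axis=1)
    return MatchSet(p0, p1, dist, frame_index=frame_index)


def detect_and_match(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    cfg: DetectorConfig | None = None,
    frame_index: int = 0,
) -> MatchSet:
    """Detect and match feature points between two unwrapped gray frames.

    Deterministic for fixed inputs and settings; a textureless frame
    yields an empty :class:`MatchSet` rather than an error.
    """
    cfg = cfg or DetectorConfig()
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames must share dimensions")
    if frame_t.ndim != 2:
        raise ValueError("frames must be single-channel (grayscale)")
    return match_keypoints(
        detect_keypoints(frame_t, cfg),
        detect_keypoints(frame_t1, cfg),
        cfg,
        frame_index=frame_index,
    )


def _seam_continuous_dst(ms: MatchSet, width_L: float | None) -> np.ndarray:
    """Destination points with x adjusted so displacement is seam-continuous."""
    dst = ms.points_t1.copy()
    if width_L is not None:
        dx = dst[:, 0] - ms.points_t[:, 0]
        dx = (dx + width_L / 2.0) % width_L - width_L / 2.0
        dst[:, 0] = ms.points_t[:, 0] + dx
    return dst


def ransac_filter(
    ms: MatchSet,
    cfg: RansacConfig | None = None,
    rng: np.random.Generator | int | None = 0,
    width_L: float | None = None,
) -> MatchSet:
    """Keep the largest consensus set under a 2-D similarity transform.

    ``width_L`` (the unwrapped frame width) enables cyclic handling of
    horizontal displacements so rolls across the azimuth seam are not
    treated as outliers.  Deterministic given ``rng``.  Below the model
    minimum of 3 matches the input is returned unchanged.
    """
    cfg = cfg or RansacConfig()
    if ms.FP < 3:
        logger.warning("RANSAC skipped: %d matches below model minimum", ms.FP)
        return ms
    src = ms.points_t
    dst = _seam_continuous_dst(ms, width_L)
    _, inliers = _sk_ransac(
        (src, dst),
        SimilarityTransform,
        min_samples=3,
        residual_threshold=cfg.tau_px,
        max_trials=cfg.iterations,
        rng=rng,
    )
    if inliers is None or not np.any(inliers):
        logger.warning("RANSAC found no consensus; returning input unchanged")
        return ms
    return ms.subset(inliers)
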