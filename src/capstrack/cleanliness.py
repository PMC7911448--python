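"""Frame cleanliness scoring: pixel SVM, exposure masking, 4-level gate.

A colon frame may be partly or wholly covered by fecal matter, in which
case tracked features belong to debris rather than the bowel wall and
the motion update must not trust them.  Pixels are classified clean or
dirty by a linear support vector machine on simple photometric features
(intensity and local contrast: tissue texture is contrast-rich, debris
films are flat), over- and under-exposed pixels are excluded, and the
clean fraction of the remaining pixels maps to a four-level score::

    3 Good / 2 Fair / 1 Poor / 0 Unacceptable

Levels 1-3 are adequate for motion estimation; level 0 (or too few
matched feature points) triggers the tracker's history-noise fallback.
The level cutoffs and the feature definition are deliberately plain and
configurable: the tracker only consumes the level, chiefly whether it
is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter
from sklearn.svm import LinearSVC

__all__ = [
    "CleanlinessModel",
    "CleanlinessResult",
    "CleanlinessThresholds",
    "pixel_features",
    "exposure_mask",
    "train_pixel_svm",
    "frame_cleanliness",
    "default_model",
]

FEATURE_ID = "intensity+contrast9"
_CONTRAST_WINDOW = 9


@dataclass(frozen=True)
class CleanlinessThresholds:
    """Exposure bounds (fractions of the intensity range) and level cutoffs."""

    exposure_low: float = 0.02
    exposure_high: float = 0.98
    c_good: float = 0.90
    c_fair: float = 0.75
    c_poor: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.c_poor < self.c_fair < self.c_good <= 1.0:
            raise ValueError("need 0 < c_poor < c_fair < c_good <= 1")
        if not self.exposure_low < self.exposure_high:
            raise ValueError("need exposure_low < exposure_high")


@dataclass(frozen=True)
class CleanlinessResult:
    level_L: int
    clean_fraction: float
    excluded_fraction: float


@dataclass(frozen=True)
class CleanlinessModel:
    """Linear clean/dirty pixel classifier: sign(w . x + b) > 0 is clean."""

    weights: np.ndarray
    bias: float
    feature_id: str = FEATURE_ID

    def predict_clean(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ np.asarray(self.weights, dtype=float) + self.bias > 0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_id": self.feature_id,
                    "weights": list(map(float, np.ravel(self.weights))),
                    "bias": float(self.bias),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "CleanlinessModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["weights"], float), float(d["bias"]), d["feature_id"])


def pixel_features(frame: np.ndarray) -> np.ndarray:
    """Per-pixel (intensity, local contrast) features, shape (H*W, 2).

    Local contrast is the standard deviation of the intensity in a
    square window around each pixel.
    """
    f = np.asarray(frame, dtype=float)
    if f.ndim != 2:
        raise ValueError("expected a single-channel frame")
    mean = uniform_filter(f, size=_CONTRAST_WINDOW, mode="nearest")
    sq = uniform_filter(f * f, size=_CONTRAST_WINDOW, mode="nearest")
    contrast = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    return np.column_stack([f.ravel(), contrast.ravel()])


def exposure_mask(frame: np.ndarray, th: CleanlinessThresholds | None = None) -> np.ndarray:
    """True where a pixel is neither under- nor over-exposed.

    Bounds are fractions of the intensity range; frames are assumed in
    [0, 1] (uint8 input is rescaled).
    """
    th = th or CleanlinessThresholds()
    f = np.asarray(frame, dtype=float)
    if f.dtype != float or f.max() > 1.5:
        f = f / 255.0
    return (f > th.exposure_low) & (f < th.exposure_high)


def train_pixel_svm(X: np.ndarray, clean: np.ndarray, seed: int = 0) -> CleanlinessModel:
    """Fit the linear clean/dirty pixel classifier.

    ``clean`` is a boolean label vector; both classes must be present.
    """
    X = np.asarray(X, dtype=float)
    clean = np.asarray(clean, dtype=bool)
    if clean.all() or (~clean).all():
        raise ValueError("training data must contain both classes")
    svm = LinearSVC(C=1.0, dual=True, random_state=seed, max_iter=20_000)
    svm.fit(X, clean.astype(int))
    return CleanlinessModel(svm.coef_.ravel().copy(), float(svm.intercept_[0]))


def frame_cleanliness(
    frame: np.ndarray,
    model: CleanlinessModel,
    th: CleanlinessThresholds | None = None,
) -> CleanlinessResult:
    """Four-level cleanliness of a frame.

    The clean fraction is computed over exposure-valid pixels only;
    level 3 requires clean_fraction >= c_good, 2 >= c_fair, 1 >= c_poor,
    else 0 (also when every pixel is exposure-excluded).
    """
    th = th or CleanlinessThresholds()
    f = np.asarray(frame, dtype=float)
    if f.max() > 1.5:
        f = f / 255.0
    mask = exposure_mask(f, th).ravel()
    excluded = 1.0 - float(mask.mean()) if mask.size else 1.0
    if not mask.any():
        return CleanlinessResult(0, 0.0, 1.0)
    X = pixel_features(f)[mask]
    clean_fraction = float(model.predict_clean(X).mean())
    if clean_fraction >= th.c_good:
        level = 3
    elif clean_fraction >= th.c_fair:
        level = 2
    elif clean_fraction >= th.c_poor:
        level = 1
    else:
        level = 0
    return CleanlinessResult(level, clean_fraction, excluded)


def default_model(seed: int = 7) -> CleanlinessModel:
    """Classifier shipped for synthetic videos.

    Trained on programmatically generated pixel features that mirror
    the renderer's photometry: tissue is textured (local contrast a few
    percent of the intensity range and up), debris is a flat film
    (near-zero contrast).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = 4000
    clean = np.column_stack(
        [
            rng.normal(0.50, 0.18, n).clip(0.05, 0.95),
            np.abs(rng.normal(0.10, 0.05, n)) + 0.03,
        ]
    )
    dirty = np.column_stack(
        [
            rng.normal(0.55, 0.12, n).clip(0.05, 0.95),
            np.abs(rng.normal(0.008, 0.006, n)),
        ]
    )
    X = np.vstack([clean, dirty])
    y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    return train_pixel_svm(X, y, seed=seed)
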