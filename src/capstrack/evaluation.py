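"""Evaluation of path ensembles: path difference, sections, speed CDFs.

Without a position ground truth inside the body, reconstruction quality
is judged by internal consistency and anatomical plausibility:

* *path difference*: at every frame, the Euclidean distances between a
  path inside an anatomical section box and every other path of the
  ensemble, summarised per section -- a spread measure that grows as
  estimation error propagates along the colon;
* *section classification*: each reconstructed position is assigned to
  the nearest section box and compared against reference labels in a
  column-normalised confusion matrix (diagonal = per-section accuracy);
* *dual-head speed CDFs*: the two camera heads of a capsule see the
  same motion mirrored, so their pooled absolute-speed distributions
  must agree; agreement is scored as the fraction of an evaluation
  grid where bootstrap 95% bands of the two empirical CDFs overlap.

Section boxes are axis-aligned and deliberately ad hoc; for synthetic
data an auto-placer derives them from the ground-truth polyline by
arc-length fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .pipeline import PathEnsemble
from .simulator import SECTION_FRACTIONS

__all__ = [
    "SectionBox",
    "PathDifferenceSummary",
    "SectionConfusion",
    "SpeedCdfComparison",
    "auto_place_boxes",
    "label_positions",
    "path_difference",
    "summarize_videos",
    "section_confusion",
    "speed_cdf_compare",
    "SECTION_ORDER",
    "CONFUSION_SECTIONS",
]

SECTION_ORDER = ("I", "II", "III", "IV", "V", "VI")
CONFUSION_SECTIONS = ("II", "III", "IV", "V", "VI")


@dataclass(frozen=True)
class SectionBox:
    """Axis-aligned box loosely associated with one anatomical section."""

    label: str
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if lo.shape != (3,) or hi.shape != (3,) or not np.all(lo < hi):
            raise ValueError("box needs lo < hi per axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance to the box (zero inside)."""
        p = np.atleast_2d(points)
        d = np.maximum(self.lo - p, 0.0) + np.maximum(p - self.hi, 0.0)
        return np.linalg.norm(d, axis=1)


def auto_place_boxes(
    polyline: np.ndarray,
    fractions: dict | None = None,
    pad: float = 1.0,
) -> list[SectionBox]:
    """Boxes along a reference polyline, split by arc-length fractions.

    Each section's box is the axis-aligned bounding box of its stretch
    of the polyline, padded by ``pad`` cm on every side.
    """
    fractions = fractions or SECTION_FRACTIONS
    pts = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ValueError("degenerate polyline")
    names = list(fractions)
    bounds = np.concatenate([[0.0], np.cumsum([fractions[k] for k in names]) * total])
    boxes = []
    for k, name in enumerate(names):
        sel = (arc >= bounds[k]) & (arc <= bounds[k + 1])
        if not sel.any():
            continue
        chunk = pts[sel]
        boxes.append(SectionBox(name, chunk.min(axis=0) - pad, chunk.max(axis=0) + pad))
    return boxes


def label_positions(positions: np.ndarray, boxes: list[SectionBox]) -> np.ndarray:
    """Section label of each position: the nearest box (containing wins).

    Ties break toward the earlier section in box order.
    """
    p = np.atleast_2d(positions)
    dists = np.stack([b.distance(p) for b in boxes], axis=1)
    idx = np.argmin(dists, axis=1)
    return np.asarray([boxes[i].label for i in idx])


@dataclass
class PathDifferenceSummary:
    """Per-section path-difference statistics of one video's ensemble."""

    mean: dict
    var: dict
    count: dict
    samples: dict = field(default_factory=dict)

    def sections(self) -> list[str]:
        return [s for s in SECTION_ORDER if s in self.mean]


def path_difference(
    ens: PathEnsemble,
    boxes: list[SectionBox],
    collect_samples: bool = False,
) -> PathDifferenceSummary:
    """Between-path distances aggregated per anatomical section.

    For every frame ``t`` and every ordered pair of reconstructions
    ``(q, w)``, ``q != w``, whose member ``q`` lies inside section S at
    that frame, the Euclidean distance ``|x_{t,q} - x_{t,w}|``
    contributes one sample to S.  Sections no path ever visits are
    omitted (with a warning via the count dict being absent).
    """
    if ens.N < 2:
        raise ValueError("path difference needs at least two paths")
    pos = ens.positions  # (N, T, 3)
    N, T, _ = pos.shape
    sums: dict[str, float] = {}
    sqs: dict[str, float] = {}
    cnt: dict[str, int] = {}
    samples: dict[str, list] = {}
    for t in range(T):
        pts = pos[:, t, :]
        labels = label_positions(pts, boxes)
        D = cdist(pts, pts)
        for s in np.unique(labels):
            idx_q = np.flatnonzero(labels == s)
            # all ordered pairs (q, w), q in S, w != q; the self column
            # contributes exactly zero so dropping it is a count fix only
            rows = D[idx_q]
            sums[s] = sums.get(s, 0.0) + float(rows.sum())
            sqs[s] = sqs.get(s, 0.0) + float((rows**2).sum())
            cnt[s] = cnt.get(s, 0) + len(idx_q) * (N - 1)
            if collect_samples:
                for q in idx_q:
                    samples.setdefault(s, []).extend(np.delete(D[q], q).tolist())
    mean = {s: sums[s] / cnt[s] for s in cnt if cnt[s] > 0}
    var = {s: sqs[s] / cnt[s] - mean[s] ** 2 for s in cnt if cnt[s] > 0}
    out_samples = {s: np.asarray(v) for s, v in samples.items()} if collect_samples else {}
    return PathDifferenceSummary(mean, var, cnt, out_samples)


def summarize_videos(summaries: list[PathDifferenceSummary]) -> tuple[dict, dict]:
    """Across-video mean and variance per section.

    ``mu_S`` is the mean over videos of the per-video mean path
    difference; ``sigma2_S`` the mean over videos of the per-video
    variance.
    """
    mu: dict[str, float] = {}
    s2: dict[str, float] = {}
    for s in SECTION_ORDER:
        per_video = [sm.mean[s] for sm in summaries if s in sm.mean]
        per_var = [sm.var[s] for sm in summaries if s in sm.var]
        if per_video:
            mu[s] = float(np.mean(per_video))
            s2[s] = float(np.mean(per_var))
    return mu, s2


@dataclass
class SectionConfusion:
    """Column-normalised confusion matrix over sections II-VI."""

    matrix: np.ndarray  # (pred, true), columns sum to 1
    sections: tuple = CONFUSION_SECTIONS

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def average_accuracy(self) -> float:
        d = self.diagonal
        return float(np.mean(d[~np.isnan(d)]))


def section_confusion(predicted, truth) -> SectionConfusion:
    """Confusion of predicted vs reference section labels (II-VI).

    Columns are conditioned on the true label, so each column sums to
    one and the diagonal reads as per-section accuracy.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    valid = set(CONFUSION_SECTIONS)
    for arr in (predicted, truth):
        bad = set(np.unique(arr)) - valid
        if bad:
            raise ValueError(f"labels outside II-VI: {sorted(bad)}")
    k = len(CONFUSION_SECTIONS)
    index = {s: i for i, s in enumerate(CONFUSION_SECTIONS)}
    M = np.zeros((k, k))
    for p, t in zip(predicted, truth):
        M[index[p], index[t]] += 1.0
    col = M.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(col > 0, M / col, np.nan)
    return SectionConfusion(M)


@dataclass
class SpeedCdfComparison:
    grid: np.ndarray
    cdf_head1: np.ndarray
    cdf_head2: np.ndarray
    band_head1: np.ndarray  # (2, G) lower/upper
    band_head2: np.ndarray
    overlap_fraction: float


def _ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    v = np.sort(values)
    return np.searchsorted(v, grid, side="right") / len(v)


def speed_cdf_compare(
    ens_head1: PathEnsemble,
    ens_head2: PathEnsemble,
    grid_size: int = 100,
    n_boot: int = 200,
    rng: np.random.Generator | int | None = 0,
) -> SpeedCdfComparison:
    """Agreement of the two heads' absolute-speed distributions.

    Pools |v| per head and reports the fraction of an evaluation grid
    where pointwise 95% bootstrap bands of the two empirical CDFs
    overlap (1.0 = full agreement).  The bootstrap resamples both
    frames and paths: the speed distribution lives over frames, and
    each frame's speeds across paths share one observation, so both
    levels contribute genuine sampling uncertainty.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    s1 = ens_head1.pooled_speeds()
    s2 = ens_head2.pooled_speeds()
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both ensembles must contain speed records")
    hi = max(s1.max(), s2.max())
    grid = np.linspace(0.0, hi if hi > 0 else 1.0, grid_size)
    out_bands = []
    for ens in (ens_head1, ens_head2):
        sp = np.stack([np.abs(p.records["v"].to_numpy()) for p in ens.paths])
        N, T = sp.shape
        boots = np.empty((n_boot, grid_size))
        for b in range(n_boot):
            pooled = sp[np.ix_(rng.integers(0, N, N), rng.integers(0, T, T))].ravel()
            boots[b] = _ecdf_on_grid(pooled, grid)
        out_bands.append(np.percentile(boots, [2.5, 97.5], axis=0))
    band1, band2 = out_bands
    overlap = np.mean((band1[0] <= band2[1]) & (band2[0] <= band1[1]))
    return SpeedCdfComparison(
        grid, _ecdf_on_grid(s1, grid), _ecdf_on_grid(s2, grid), band1, band2, float(overlap)
    )
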