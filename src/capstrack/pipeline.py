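"""Per-video reconstruction: frames -> observations -> path ensembles.

Reconstruction separates cleanly into a deterministic, per-video
observation pass and a cheap, stochastic per-path pass:

1. *Observation*: every consecutive frame pair is unwrapped, feature
   points are detected, matched and RANSAC-filtered, the frame's
   cleanliness level is scored, and the motion estimators are run.
   The axial displacement is stored per unit radius (``d / R``,
   i.e. the mode of ``cot(theta_t) - cot(theta_t1)``), because the true
   radius is never observed.
2. *Path sampling*: each reconstruction draws a fresh radius and
   sample frequency from the chosen prior combination at every frame,
   scales the unit displacement into cm, and integrates the oriented
   track.  Frames failing the quality gate (cleanliness level 0 or
   fewer than ``min_feature_points`` matches) advance by the
   history-noise fallback instead.

Since the observation pass is shared, an ensemble of N reconstructions
costs one feature pass plus N fast integrations, and ensembles are
embarrassingly parallel: each path's generator is seeded from
``(master_seed, path_index)`` so results do not depend on execution
order and disjoint sub-ensembles merge exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cleanliness import (
    CleanlinessModel,
    CleanlinessThresholds,
    default_model,
    frame_cleanliness,
)
from .features import DetectorConfig, MatchSet, RansacConfig, detect_keypoints, match_keypoints, ransac_filter
from .geometry import CameraGeometry, unwrap_frame
from .motion import (
    InvalidEstimate,
    ModeEstimatorConfig,
    TiltConfig,
    estimate_roll,
    estimate_tilt,
    mode_of,
    pitch_yaw,
    unit_displacement_samples,
)
from .priors import PriorCombo
from .tracking import (
    ParameterHistory,
    advance_track,
    fallback_update,
    initial_state,
    update_orientation,
)

__all__ = [
    "PipelineConfig",
    "TransitionObservation",
    "Path",
    "PathEnsemble",
    "observe_frames",
    "observe_matchsets",
    "reconstruct_path",
    "run_ensemble",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    geometry: CameraGeometry = field(default_factory=CameraGeometry)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    mode: ModeEstimatorConfig = field(default_factory=ModeEstimatorConfig)
    tilt: TiltConfig = field(default_factory=TiltConfig)
    thresholds: CleanlinessThresholds = field(default_factory=CleanlinessThresholds)
    min_feature_points: int = 20
    initial_direction: tuple = (1.0, 0.0, 0.0)


@dataclass(frozen=True)
class TransitionObservation:
    """Radius-free measurements of one frame transition."""

    frame_index: int
    FP: int
    level: int
    unit_disp: float  # mode of d/R samples (dimensionless)
    gamma: float
    Omega: float
    omega: float
    valid: bool


def _observe_transition(
    ms: MatchSet,
    level: int,
    cfg: PipelineConfig,
    rng: np.random.Generator,
) -> TransitionObservation:
    g = cfg.geometry
    try:
        unit = unit_displacement_samples(ms, g)
        if len(unit) == 0:
            raise InvalidEstimate("no usable matches")
        u = mode_of(unit, cfg.mode)
        gamma = estimate_roll(ms, g, cfg.mode)
        Omega, omega = estimate_tilt(ms, g, cfg.tilt, cfg.mode, rng=rng)
    except InvalidEstimate:
        return TransitionObservation(ms.frame_index, ms.FP, level, 0.0, 0.0, 0.0, 0.0, False)
    return TransitionObservation(ms.frame_index, ms.FP, level, u, gamma, Omega, omega, True)


def observe_frames(
    frames: Sequence[np.ndarray],
    cfg: PipelineConfig | None = None,
    model: CleanlinessModel | None = None,
    seed: int = 0,
) -> list[TransitionObservation]:
    """Run detection, matching, RANSAC and estimation over a video.

    ``frames`` are raw (polar) grayscale images; keypoints are detected
    once per unwrapped frame and matched consecutively.  Deterministic
    given ``seed`` (which drives RANSAC and tilt-pair subsampling).
    """
    cfg = cfg or PipelineConfig()
    model = model or default_model()
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1EA]))
    g = cfg.geometry
    obs: list[TransitionObservation] = []
    kp_prev = None
    for t, frame in enumerate(frames):
        try:
            level = frame_cleanliness(frame, model, cfg.thresholds).level_L
            unwrapped = unwrap_frame(frame, g)
            kp = detect_keypoints(unwrapped, cfg.detector)
        except (ValueError, RuntimeError) as err:  # unreadable frame
            logger.warning("frame %d unreadable (%s); treated as level 0", t, err)
            level, kp = 0, (np.empty((0, 2)), np.empty((0,)), np.empty((0, 1)))
        if kp_prev is not None:
            ms = match_keypoints(kp_prev, kp, cfg.detector, frame_index=t - 1)
            ms = ransac_filter(ms, cfg.ransac, rng=rng, width_L=g.unwrapped_width_L)
            # the transition is gated by the quality of the incoming frame
            obs.append(_observe_transition(ms, level, cfg, rng))
        kp_prev = kp
    return obs


def observe_matchsets(
    matchsets: Sequence[MatchSet],
    cfg: PipelineConfig | None = None,
    levels: Sequence[int] | None = None,
    seed: int = 0,
    apply_ransac: bool = False,
) -> list[TransitionObservation]:
    """Observation pass over pre-built correspondences (simulator input)."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1EA]))
    out = []
    for i, ms in enumerate(matchsets):
        level = 3 if levels is None else int(levels[i])
        if apply_ransac:
            ms = ransac_filter(ms, cfg.ransac, rng=rng, width_L=cfg.geometry.unwrapped_width_L)
        out.append(_observe_transition(ms, level, cfg, rng))
    return out


@dataclass
class Path:
    """One reconstruction: states, per-frame records, and provenance."""

    states: list
    records: pd.DataFrame
    label: str
    seed: int

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([st.position for st in self.states])


def reconstruct_path(
    observations: Sequence[TransitionObservation],
    combo: PriorCombo,
    cfg: PipelineConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> Path:
    """Integrate one prior-sampled path through the observations."""
    cfg = cfg or PipelineConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    st = initial_state(cfg.initial_direction)
    hist = ParameterHistory()
    states = [st]
    rows = []
    # one vectorised draw per path instead of per frame: same law,
    # far fewer quantile-function evaluations
    n = len(observations)
    radii = np.atleast_1d(combo.radius_prior.sample(rng, size=n)) / 2.0
    freqs = np.atleast_1d(combo.frequency_prior.sample(rng, size=n))
    for k, obs in enumerate(observations):
        R, f = float(radii[k]), float(freqs[k])
        use = obs.valid and obs.level != 0 and obs.FP >= cfg.min_feature_points
        if use:
            v = f * R * obs.unit_disp
            alpha, beta = pitch_yaw(obs.Omega, obs.omega)
            orient = update_orientation(st.orientation, alpha, beta, obs.gamma)
            st = advance_track(st, v, f, orient)
            hist.append(v, f, alpha, beta, obs.gamma)
            rec = dict(v=v, f_drawn=f, gamma=obs.gamma, alpha=alpha, beta=beta)
        else:
            if len(hist) == 0 and not rows:
                logger.warning(
                    "fallback before any accepted estimate: capsule held stationary"
                )
            st, drawn = fallback_update(st, hist, rng)
            v = drawn.get("v", 0.0)
            rec = dict(
                v=v,
                f_drawn=drawn.get("f", f),
                gamma=drawn.get("gamma", 0.0),
                alpha=drawn.get("alpha", 0.0),
                beta=drawn.get("beta", 0.0),
            )
        states.append(st)
        rows.append(
            dict(
                t=obs.frame_index,
                **rec,
                R_drawn=R,
                Omega=obs.Omega,
                omega=obs.omega,
                x=st.position[0],
                y=st.position[1],
                z=st.position[2],
                L_level=obs.level,
                FP=obs.FP,
                fallback_flag=not use,
            )
        )
    records = pd.DataFrame(rows)
    seed_repr = seed if isinstance(seed, int) else -1
    return Path(states, records, combo.label, seed_repr)


@dataclass
class PathEnsemble:
    """N independent prior-sampled reconstructions of one video."""

    paths: list
    label: str
    master_seed: int

    @property
    def N(self) -> int:
        return len(self.paths)

    @property
    def positions(self) -> np.ndarray:
        """Array of shape (N, n_frames, 3)."""
        return np.asarray([p.positions for p in self.paths])

    def pooled_speeds(self) -> np.ndarray:
        """Absolute per-frame speeds pooled over all paths."""
        return np.abs(np.concatenate([p.records["v"].to_numpy() for p in self.paths]))

    def merged_with(self, other: "PathEnsemble") -> "PathEnsemble":
        if other.label != self.label:
            raise ValueError("cannot merge ensembles of different prior combos")
        return PathEnsemble(self.paths + other.paths, self.label, self.master_seed)


def run_ensemble(
    observations: Sequence[TransitionObservation],
    combo: PriorCombo,
    N: int,
    master_seed: int = 0,
    cfg: PipelineConfig | None = None,
    path_offset: int = 0,
) -> PathEnsemble:
    """N independent reconstructions with per-path seeds from the master.

    Path ``i`` uses a generator seeded by ``(master_seed, offset + i)``,
    so the ensemble is bit-reproducible, order-independent, and two
    disjoint half-ensembles (via ``path_offset``) merge into exactly
    the full ensemble.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    cfg = cfg or PipelineConfig()
    paths = []
    for i in range(N):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, path_offset + i]))
        paths.append(reconstruct_path(observations, combo, cfg, seed=rng))
    return PathEnsemble(paths, combo.label, master_seed)
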