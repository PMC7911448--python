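"""YAML configuration covering every tunable of the pipeline.

One structured file configures geometry, detector, RANSAC, mode
estimation, tilt, cleanliness thresholds and priors; any omitted key
falls back to the package default.  Example::

    geometry:
      field_of_view_deg: 172
      unwrapped_width: 512
      unwrapped_height: 128
    detector:
      detector: sift
      ratio_threshold: 0.75
    ransac:
      tau_px: 2.0
      iterations: 500
    mode_estimator:
      method: kde
      grid_size: 512
    tilt:
      xi: 0.25
    priors: tt        # or a full {radius: {...}, frequency: {...}} block
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .cleanliness import CleanlinessThresholds
from .features import DetectorConfig, RansacConfig
from .geometry import CameraGeometry
from .motion import ModeEstimatorConfig, TiltConfig
from .pipeline import PipelineConfig
from .priors import PriorCombo, PriorSpec, prior_combo

__all__ = ["load_config", "load_priors", "pipeline_from_dict"]

_GEOMETRY_KEYS = {
    "field_of_view_deg": "field_of_view_deg",
    "usable_radius_px": "usable_radius_px",
    "unwrapped_width": "unwrapped_width_L",
    "unwrapped_height": "unwrapped_height_H",
    "theta_min_deg": "theta_min_deg",
    "theta_max_deg": "theta_max_deg",
    "optical_center": "optical_center",
}


def _build(cls, block: dict, rename: dict | None = None):
    block = block or {}
    if rename:
        block = {rename.get(k, k): v for k, v in block.items()}
    return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in block.items()})


def _prior_spec(block: dict) -> PriorSpec:
    return PriorSpec(
        kind=block["kind"],
        a=float(block["a"]),
        b=float(block["b"]),
        mu=block.get("mu"),
        sigma=block.get("sigma"),
    )


def load_priors(spec) -> PriorCombo:
    """Priors from a preset name ('tt', ...) or a full radius/frequency block."""
    if isinstance(spec, str):
        return prior_combo(spec)
    return PriorCombo(
        radius_prior=_prior_spec(spec["radius"]),
        frequency_prior=_prior_spec(spec["frequency"]),
    )


def pipeline_from_dict(cfg: dict) -> tuple[PipelineConfig, PriorCombo]:
    cfg = cfg or {}
    pc = PipelineConfig(
        geometry=_build(CameraGeometry, cfg.get("geometry"), _GEOMETRY_KEYS),
        detector=_build(DetectorConfig, cfg.get("detector")),
        ransac=_build(RansacConfig, cfg.get("ransac")),
        mode=_build(ModeEstimatorConfig, cfg.get("mode_estimator")),
        tilt=_build(TiltConfig, cfg.get("tilt")),
        thresholds=_build(CleanlinessThresholds, cfg.get("cleanliness")),
        min_feature_points=int(cfg.get("min_feature_points", 20)),
        initial_direction=tuple(cfg.get("initial_direction", (1.0, 0.0, 0.0))),
    )
    return pc, load_priors(cfg.get("priors", "tt"))


def load_config(path: str | Path) -> tuple[PipelineConfig, PriorCombo]:
    """Read a YAML file into a pipeline configuration and prior combo."""
    with open(path) as fh:
        return pipeline_from_dict(yaml.safe_load(fh) or {})
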