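"""YAML pipeline configuration.

One file configures every stage; sections map 1:1 onto the module-level
parameter dataclasses.  Unknown keys are rejected rather than ignored, so a
typo cannot silently fall back to a default.

Schema (all sections optional; defaults apply):

.. code-block:: yaml

    seed: 0
    verbosity: 1
    camera:
      ir:   {width: 384, height: 288, fx: 370, fy: 370, cx: 191.5, cy: 143.5}
      rgbd: {width: 1280, height: 720, fx: 640, fy: 640, cx: 639.5, cy: 359.5}
    registration: {scale_x: 0.4, scale_y: 0.4, shift_x: -64.0, shift_y: 0.0,
                   crop_width: 384, crop_height: 288}
    skin:       # SkinThresholds fields
    stat_filter: {k_neighbors: 20, std_multiplier: 2.0}
    ransac: {iterations: 500, distance_threshold_mm: null, auto_scale_c: 2.0,
             min_inliers: 3, seed: 0}
    staple: {prior: null, p0: 0.99999, q0: 0.99999, tol: 1.0e-7, max_iter: 200}
    scene:      # SceneConfig fields (synthetic generator)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .depth import RansacConfig, StatFilterConfig
from .errors import ConfigError
from .frames import (DEFAULT_IR_CAMERA, CameraModel, RegistrationParams)
from .skin import SkinThresholds
from .synthetic import FootShape, SceneConfig


@dataclass(frozen=True)
class StapleSettings:
    prior: float | None = None
    p0: float = 0.99999
    q0: float = 0.99999
    tol: float = 1e-7
    max_iter: int = 200


@dataclass
class PipelineConfig:
    """Validated configuration for the whole pipeline."""

    seed: int = 0
    verbosity: int = 1
    ir_camera: CameraModel = DEFAULT_IR_CAMERA
    rgbd_camera: CameraModel | None = None
    registration: RegistrationParams | None = None
    skin: SkinThresholds = field(default_factory=SkinThresholds)
    stat_filter: StatFilterConfig = field(default_factory=StatFilterConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    staple: StapleSettings = field(default_factory=StapleSettings)
    scene: SceneConfig = field(default_factory=SceneConfig)

    def digest(self) -> str:
        """Stable short hash of the full configuration, for run logs."""
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _build(cls, section: dict, name: str):
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    coerced = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def load_pipeline_config(path: str | Path | None = None) -> PipelineConfig:
    """Load (or default-construct) a :class:`PipelineConfig` from YAML."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    known = {"seed", "verbosity", "camera", "registration", "skin",
             "stat_filter", "ransac", "staple", "scene"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.verbosity = int(raw.get("verbosity", cfg.verbosity))

    cam = raw.get("camera", {})
    if cam:
        unknown = set(cam) - {"ir", "rgbd"}
        if unknown:
            raise ConfigError(f"unknown camera keys: {sorted(unknown)}")
        if "ir" in cam:
            cfg.ir_camera = _build(CameraModel, cam["ir"], "camera.ir")
        if "rgbd" in cam:
            cfg.rgbd_camera = _build(CameraModel, cam["rgbd"], "camera.rgbd")
    if "registration" in raw:
        cfg.registration = _build(RegistrationParams, raw["registration"],
                                  "registration")
    if "skin" in raw:
        cfg.skin = _build(SkinThresholds, raw["skin"], "skin")
    if "stat_filter" in raw:
        cfg.stat_filter = _build(StatFilterConfig, raw["stat_filter"],
                                 "stat_filter")
    if "ransac" in raw:
        cfg.ransac = _build(RansacConfig, raw["ransac"], "ransac")
    if "staple" in raw:
        cfg.staple = _build(StapleSettings, raw["staple"], "staple")
    if "scene" in raw:
        scene = dict(raw["scene"])
        if "foot" in scene:
            scene["foot"] = _build(FootShape, scene["foot"], "scene.foot")
        cfg.scene = _build(SceneConfig, scene, "scene")
    return cfg
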