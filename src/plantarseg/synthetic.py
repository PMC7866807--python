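"""Seeded synthetic RGB-D-IR scenes and simulated raters.

Clinical plantar-thermography data is rarely shareable, so every stage of
the pipeline is exercised on synthetic scenes that emulate the acquisition
geometry: a seated subject with both foot soles facing the camera at an
~80 cm stand-off, skin-toned in RGB, warmer than the background in IR, and
near-planar in depth.  The background sits farther away (default 1.3 m)
and carries *distractors* — blobs that are skin-coloured and/or warm, the
failure mode of purely colour- or heat-based segmentation — placed at
background depth so that only depth-plane refinement can reject them.

The foot silhouette is stylised (an elliptical sole plus five toe discs),
which is enough to exercise boundary behaviour at the toes and arch; it is
not an anatomical model.  IR is rendered in raw sensor counts, not
temperature — nothing downstream needs absolute calibration.

Every generator is driven by a single integer seed through independent
child streams, so scenes, raters and RANSAC are separately reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage import draw, morphology

from .errors import ConfigError, ParameterError
from .frames import BinaryMask, MultimodalFrame

#: IR raster size used by default throughout.
_WIDTH, _HEIGHT = 384, 288


@dataclass(frozen=True)
class FootShape:
    """Stylised foot: elliptical sole with five toe discs at the far end."""

    length_px: float = 110.0       # sole ellipse major diameter
    width_px: float = 42.0         # sole ellipse minor diameter
    toe_radius_px: float = 5.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Depth defaults emulate the acquisition stand-off: foot surface at
    800 mm with 4 mm within-surface spread, background at 1300 mm
    (so distractors sit 500 mm behind the foot plane), plus sensor noise.
    """

    seed: int = 0
    width: int = _WIDTH
    height: int = _HEIGHT
    foot: FootShape = field(default_factory=FootShape)
    position_jitter_px: float = 10.0
    rotation_jitter_deg: float = 8.0
    scale_range: tuple[float, float] = (0.9, 1.1)

    foot_depth_mm: float = 800.0
    foot_depth_std_mm: float = 4.0
    background_depth_mm: float = 1300.0
    depth_noise_mm: float = 1.5

    skin_tone: tuple[int, int, int] = (224, 180, 150)
    skin_tone_jitter: float = 8.0      # per-scene uniform shift per channel
    rgb_noise_std: float = 5.0
    background_color: tuple[int, int, int] = (110, 120, 140)

    ir_foot_counts: float = 7600.0
    ir_background_counts: float = 7000.0
    ir_gradient_amplitude: float = 150.0
    ir_noise_std: float = 30.0

    n_skin_distractors: int = 2        # skin-coloured blobs at background depth
    n_warm_distractors: int = 1        # warm-only blobs (invisible to skin seg)
    distractor_radius_range: tuple[float, float] = (10.0, 18.0)

    def __post_init__(self) -> None:
        if self.foot_depth_mm >= self.background_depth_mm:
            raise ConfigError("feet must be nearer the camera than the background")
        if min(self.foot_depth_std_mm, self.depth_noise_mm, self.rgb_noise_std,
               self.ir_noise_std) < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.n_skin_distractors < 0 or self.n_warm_distractors < 0:
            raise ConfigError("distractor counts must be >= 0")
        max_scale = self.scale_range[1]
        extent = (self.foot.length_px + 4 * self.foot.toe_radius_px) * max_scale \
            + 2 * self.position_jitter_px
        if extent > min(self.width, self.height) or 2.6 * self.foot.width_px * max_scale > self.width:
            raise ConfigError("foot geometry does not fit inside the frame")

    def with_seed(self, seed: int) -> "SceneConfig":
        return dataclasses.replace(self, seed=seed)


@dataclass(frozen=True)
class RaterModel:
    """Simulated human rater: per-pixel sensitivity p and specificity q,
    optionally preceded by a morphological boundary perturbation."""

    sensitivity: float = 0.95
    specificity: float = 0.98
    boundary_jitter: int = 0           # max dilation/erosion radius in px
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity <= 1 and 0 < self.specificity <= 1):
            raise ParameterError("sensitivity and specificity must lie in (0, 1]")
        if self.boundary_jitter < 0:
            raise ParameterError("boundary_jitter must be >= 0")


def _render_foot(cfg: SceneConfig, rng: np.random.Generator,
                 center_col: float) -> np.ndarray:
    """Rasterise one stylised foot (sole ellipse + 5 toe discs)."""
    scale = rng.uniform(*cfg.scale_range)
    angle = np.deg2rad(rng.uniform(-cfg.rotation_jitter_deg,
                                   cfg.rotation_jitter_deg))
    cy = cfg.height / 2 + rng.uniform(-cfg.position_jitter_px,
                                      cfg.position_jitter_px)
    cx = center_col + rng.uniform(-cfg.position_jitter_px,
                                  cfg.position_jitter_px)
    a = cfg.foot.length_px * scale / 2          # semi-major (rows)
    b = cfg.foot.width_px * scale / 2           # semi-minor (cols)
    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    rr, cc = draw.ellipse(cy, cx, a, b, shape=mask.shape, rotation=angle)
    mask[rr, cc] = True
    # toes along an arc at the top of the sole, in the rotated frame
    toe_r = cfg.foot.toe_radius_px * scale
    for i, frac in enumerate(np.linspace(-0.85, 0.85, 5)):
        ty = -(a + toe_r * 0.8) * (1 - 0.18 * frac * frac)
        tx = frac * b
        row = cy + ty * np.cos(angle) - tx * np.sin(angle)
        col = cx + ty * np.sin(angle) + tx * np.cos(angle)
        radius = toe_r * (1.2 - 0.12 * i)
        rr, cc = draw.disk((row, col), radius, shape=mask.shape)
        mask[rr, cc] = True
    return mask


@dataclass(frozen=True)
class SceneLayers:
    """Per-layer boolean rasters of a rendered scene, for inspection."""

    feet: np.ndarray
    skin_distractors: np.ndarray
    warm_distractors: np.ndarray


def generate_scene(
    config: SceneConfig, return_layers: bool = False
) -> tuple[MultimodalFrame, BinaryMask] | tuple[MultimodalFrame, BinaryMask, SceneLayers]:
    """Render one synthetic frame and its exact ground-truth mask.

    Deterministic under a fixed seed.  Skin-coloured distractors are placed
    at background depth, disjoint from the feet, so the ground truth is
    exactly the rendered foot silhouette and depth refinement can remove
    every distractor pixel.  With ``return_layers=True`` the individual
    boolean layers (feet, skin distractors, warm distractors) are returned
    as well.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    feet = np.zeros((h, w), dtype=bool)
    for center_col in (w * 0.38, w * 0.62):
        feet |= _render_foot(config, rng, center_col)

    # distractors may not touch (or nearly touch) the feet
    forbidden = morphology.dilation(feet, morphology.disk(4))
    skin_distr = np.zeros((h, w), dtype=bool)
    warm_distr = np.zeros((h, w), dtype=bool)
    for kind_mask, count in ((skin_distr, config.n_skin_distractors),
                             (warm_distr, config.n_warm_distractors)):
        placed = 0
        for _ in range(200):                    # rejection sampling
            if placed >= count:
                break
            radius = rng.uniform(*config.distractor_radius_range)
            row = rng.uniform(radius, h - radius)
            col = rng.uniform(radius, w - radius)
            rr, cc = draw.disk((row, col), radius, shape=(h, w))
            if forbidden[rr, cc].any():
                continue
            kind_mask[rr, cc] = True
            forbidden[rr, cc] = True
            placed += 1
        if placed < count:
            raise ConfigError("could not place all distractors off the feet")

    # ---- depth ----
    depth = np.full((h, w), config.background_depth_mm, dtype=np.float64)
    depth[feet] = config.foot_depth_mm + rng.normal(
        0.0, config.foot_depth_std_mm, int(feet.sum()))
    depth += rng.normal(0.0, config.depth_noise_mm, (h, w))
    depth = np.clip(np.rint(depth), 1, 65535).astype(np.uint16)

    # ---- RGB ----
    tone = np.array(config.skin_tone, dtype=np.float64) + rng.uniform(
        -config.skin_tone_jitter, config.skin_tone_jitter, 3)
    rgb = np.empty((h, w, 3), dtype=np.float64)
    rgb[:] = np.array(config.background_color, dtype=np.float64)
    rgb[feet] = tone
    rgb[skin_distr] = tone
    rgb += rng.normal(0.0, config.rgb_noise_std, (h, w, 3))
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    # ---- IR: warm feet with a smooth gradient over a cooler background ----
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    gradient = config.ir_gradient_amplitude * (
        np.sin(2 * np.pi * yy / h) * 0.5 + np.cos(2 * np.pi * xx / w) * 0.5)
    ir = np.full((h, w), config.ir_background_counts, dtype=np.float64)
    ir[feet] = config.ir_foot_counts
    ir[warm_distr] = config.ir_foot_counts
    ir += gradient + rng.normal(0.0, config.ir_noise_std, (h, w))
    ir = np.clip(np.rint(ir), 0, 65535).astype(np.uint16)

    frame = MultimodalFrame(rgb=rgb, depth=depth, ir=ir,
                            frame_id=f"scene{config.seed:05d}", timepoint="T0")
    gt = BinaryMask(data=feet.astype(np.uint8))
    if return_layers:
        return frame, gt, SceneLayers(feet=feet, skin_distractors=skin_distr,
                                      warm_distractors=warm_distr)
    return frame, gt


def simulate_rater(gt: BinaryMask, model: RaterModel) -> BinaryMask:
    """Simulate one imperfect human delineation of *gt*.

    An optional boundary perturbation first dilates or erodes the mask by a
    random radius up to ``boundary_jitter``; then each foreground pixel is
    kept with probability p (sensitivity) and each background pixel is
    flipped on with probability 1 - q (specificity), independently.
    """
    rng = np.random.default_rng(model.seed)
    base = gt.as_bool()
    if model.boundary_jitter > 0:
        radius = int(rng.integers(-model.boundary_jitter,
                                  model.boundary_jitter + 1))
        if radius > 0:
            base = morphology.dilation(base, morphology.disk(radius))
        elif radius < 0:
            base = morphology.erosion(base, morphology.disk(-radius))
    u = rng.random(base.shape)
    out = np.where(base, u < model.sensitivity, u >= model.specificity)
    return BinaryMask(data=out.astype(np.uint8), side=gt.side)


def simulate_rater_stack(
    gt: BinaryMask,
    n_raters: int,
    sensitivity: float = 0.95,
    specificity: float = 0.98,
    boundary_jitter: int = 0,
    seed: int = 0,
) -> list[BinaryMask]:
    """Simulate several independent raters with shared (p, q) from one seed."""
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, n_raters)
    return [
        simulate_rater(gt, RaterModel(sensitivity=sensitivity,
                                      specificity=specificity,
                                      boundary_jitter=boundary_jitter,
                                      seed=int(s)))
        for s in seeds
    ]
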