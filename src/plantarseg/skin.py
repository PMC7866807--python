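"""Pixel-wise skin detection by joint RGB / HSV / YCbCr thresholding.

The "Skin" segmentation approach classifies each pixel independently: the
RGB image is converted to HSV and to full-range BT.601 YCbCr, one bound rule
is evaluated per colour space, and the per-space decisions are combined
(conjunction by default).  There is deliberately no spatial reasoning here —
the depth-plane refinement stage is what removes skin-coloured background
structure.

The default numeric bounds are the widely used combined skin-pixel rule
(Kolkur et al. style):

* RGB:    R > 95, G > 40, B > 20, R > G, R > B, |R - G| > 15
* HSV:    0 <= H <= 50 degrees, 0.23 <= S <= 0.68
* YCbCr:  Y > 80, 85 <= Cb <= 135, 135 <= Cr <= 180

All bounds are plain config values, never hard-coded in the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage import color as skcolor
from skimage import morphology

from .errors import ConfigError, ParameterError
from .frames import BinaryMask

_COMBINE_MODES = ("AND", "OR", "majority")


@dataclass(frozen=True)
class SkinThresholds:
    """Bounds for the three per-colour-space skin rules plus the combine mode.

    H is in degrees [0, 360); S in [0, 1]; Y, Cb, Cr on the full 0-255 range.
    """

    r_min: float = 95.0
    g_min: float = 40.0
    b_min: float = 20.0
    require_r_gt_g: bool = True
    require_r_gt_b: bool = True
    rg_abs_diff_min: float = 15.0

    h_min: float = 0.0
    h_max: float = 50.0
    s_min: float = 0.23
    s_max: float = 0.68

    y_min: float = 80.0
    cb_min: float = 85.0
    cb_max: float = 135.0
    cr_min: float = 135.0
    cr_max: float = 180.0

    combine: str = "AND"

    def __post_init__(self) -> None:
        if self.combine not in _COMBINE_MODES:
            raise ConfigError(f"combine must be one of {_COMBINE_MODES}")
        if not (0.0 <= self.h_min <= self.h_max < 360.0):
            raise ConfigError("H bounds must satisfy 0 <= h_min <= h_max < 360")
        if not (0.0 <= self.s_min <= self.s_max <= 1.0):
            raise ConfigError("S bounds must lie in [0, 1] with s_min <= s_max")
        for lo, hi, name in ((self.cb_min, self.cb_max, "Cb"),
                             (self.cr_min, self.cr_max, "Cr")):
            if not (0.0 <= lo <= hi <= 255.0):
                raise ConfigError(f"{name} bounds must lie in [0, 255], lo <= hi")
        if not (0.0 <= self.y_min <= 255.0):
            raise ConfigError("Y bound must lie in [0, 255]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SkinThresholds":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown skin threshold keys: {sorted(unknown)}")
        return cls(**d)


def rgb_to_hsv(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit RGB image to (H, S, V) with H in degrees [0, 360)
    and S, V in [0, 1] (standard hexcone model)."""
    _check_rgb(image)
    hsv = skcolor.rgb2hsv(image)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def rgb_to_ycbcr(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 8-bit RGB to full-range BT.601 YCbCr (all channels 0-255).

    Y  = 0.299 R + 0.587 G + 0.114 B
    Cb = 128 - 0.168736 R - 0.331264 G + 0.5 B
    Cr = 128 + 0.5 R - 0.418688 G - 0.081312 B
    """
    _check_rgb(image)
    rgb = image.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return (np.clip(y, 0, 255), np.clip(cb, 0, 255), np.clip(cr, 0, 255))


def ycbcr_to_rgb(y: np.ndarray, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """Inverse full-range BT.601 transform, returned as 8-bit RGB."""
    r = y + 1.402 * (cr - 128.0)
    g = y - 0.344136 * (cb - 128.0) - 0.714136 * (cr - 128.0)
    b = y + 1.772 * (cb - 128.0)
    return np.clip(np.stack([r, g, b], axis=-1).round(), 0, 255).astype(np.uint8)


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ParameterError("expected an HxWx3 RGB image")
    if image.dtype != np.uint8:
        raise ParameterError("expected 8-bit per channel RGB input")


def skin_rules(rgb: np.ndarray, thresholds: SkinThresholds) -> dict[str, np.ndarray]:
    """Evaluate the three per-colour-space boolean rules pixel-wise."""
    _check_rgb(rgb)
    t = thresholds
    f = rgb.astype(np.float64)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]

    rule_rgb = (r > t.r_min) & (g > t.g_min) & (b > t.b_min) \
        & (np.abs(r - g) > t.rg_abs_diff_min)
    if t.require_r_gt_g:
        rule_rgb &= r > g
    if t.require_r_gt_b:
        rule_rgb &= r > b

    h, s, _ = rgb_to_hsv(rgb)
    rule_hsv = (h >= t.h_min) & (h <= t.h_max) & (s >= t.s_min) & (s <= t.s_max)

    y, cb, cr = rgb_to_ycbcr(rgb)
    rule_ycbcr = (y > t.y_min) & (cb >= t.cb_min) & (cb <= t.cb_max) \
        & (cr >= t.cr_min) & (cr <= t.cr_max)

    return {"rgb": rule_rgb, "hsv": rule_hsv, "ycbcr": rule_ycbcr}


def skin_mask(rgb: np.ndarray, thresholds: SkinThresholds | None = None) -> BinaryMask:
    """Classify each pixel as skin/non-skin by the combined threshold rule.

    A pure per-pixel function: permuting pixel positions permutes the output
    identically.  An alpha channel, if present, is ignored for classification.
    """
    if rgb.ndim == 3 and rgb.shape[-1] == 4:
        rgb = rgb[..., :3]
    thresholds = thresholds or SkinThresholds()
    rules = skin_rules(rgb, thresholds)
    votes = (rules["rgb"].astype(np.uint8) + rules["hsv"].astype(np.uint8)
             + rules["ycbcr"].astype(np.uint8))
    if thresholds.combine == "AND":
        fg = votes == 3
    elif thresholds.combine == "OR":
        fg = votes >= 1
    else:  # majority
        fg = votes >= 2
    return BinaryMask(data=fg.astype(np.uint8))


def clean_mask(mask: BinaryMask, min_component_px: int = 0,
               closing_radius: int = 0) -> BinaryMask:
    """Optional morphological tidy-up: closing, then removal of connected
    components smaller than *min_component_px*.  With both parameters 0 the
    mask is returned unchanged (the default raw-threshold workflow)."""
    if min_component_px < 0 or closing_radius < 0:
        raise ParameterError("clean_mask parameters must be non-negative")
    out = mask.as_bool()
    if closing_radius > 0:
        out = morphology.closing(out, morphology.disk(closing_radius))
    if min_component_px > 0:
        # removes components of size <= max_size, i.e. < min_component_px
        out = morphology.remove_small_objects(out, max_size=min_component_px - 1)
    return BinaryMask(data=out.astype(np.uint8), side=mask.side)
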