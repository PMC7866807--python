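"""Multimodal frame data model, PNG I/O, and RGB-D -> IR registration.

A *multimodal frame* carries three co-registered rasters — an 8-bit RGB
image, a 16-bit depth map in millimetres (0 = no measurement) and a 16-bit
infrared (IR) image in radiometric counts — on the IR camera grid, so each
pixel is a five-channel RGB-D-IR sample.  The RGB-D camera has a wider field
of view (FOV) and higher resolution than the thermal camera, so its images
must first be scaled to match the IR FOV, translated and cropped onto the
IR raster; that parametric transform lives here as
:func:`register_rgbd_to_ir`.

Pixel convention: 0-based indices, origin at the top-left, ``x`` = column,
``y`` = row, pixel centres at integer coordinates.  Depth is always in
millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import FormatError, ParameterError

#: Default IR raster size (width, height) of the thermal sensor.
IR_WIDTH = 384
IR_HEIGHT = 288

#: Default RGB-D raster size, fixed by the depth sensor.
RGBD_WIDTH = 1280
RGBD_HEIGHT = 720


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics: raster size, focal lengths and principal point,
    all in pixels."""

    width: int
    height: int
    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("camera raster dimensions must be positive")
        if self.fx <= 0 or self.fy <= 0:
            raise ParameterError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ParameterError("principal point must lie inside the raster")

    @property
    def fov_x(self) -> float:
        """Horizontal field of view in radians."""
        return 2.0 * math.atan(self.width / (2.0 * self.fx))

    @property
    def fov_y(self) -> float:
        """Vertical field of view in radians."""
        return 2.0 * math.atan(self.height / (2.0 * self.fy))


#: Plausible intrinsics for the 384x288 thermal camera; used by the
#: synthetic scene generator and as a default for deprojection.
DEFAULT_IR_CAMERA = CameraModel(
    width=IR_WIDTH, height=IR_HEIGHT, fx=370.0, fy=370.0,
    cx=(IR_WIDTH - 1) / 2.0, cy=(IR_HEIGHT - 1) / 2.0,
)


@dataclass(frozen=True)
class RegistrationParams:
    """FOV-matching scale + translation + crop bringing RGB-D rasters onto
    the IR grid.

    A source pixel ``x_s`` maps to target coordinate
    ``x_t = x_s * scale_x + shift_x`` (likewise for y); the output is the
    ``crop_height x crop_width`` window starting at the target origin.
    """

    scale_x: float
    scale_y: float
    shift_x: float
    shift_y: float
    crop_width: int = IR_WIDTH
    crop_height: int = IR_HEIGHT

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ParameterError("registration scale factors must be positive")
        if self.crop_width <= 0 or self.crop_height <= 0:
            raise ParameterError("crop dimensions must be positive")


def registration_from_cameras(
    source: CameraModel, target: CameraModel
) -> RegistrationParams:
    """Derive FOV-matching registration parameters from two camera models.

    The per-axis scale is ``tan(fov_target/2) / tan(fov_source/2)`` expressed
    on the pixel grid, and the shift aligns the scaled source principal
    point with the target principal point.  This is a convenience for users
    who know their hardware; measured parameters can always be supplied
    directly.
    """
    scale_x = (target.width * math.tan(target.fov_x / 2) / math.tan(source.fov_x / 2)) / source.width
    scale_y = (target.height * math.tan(target.fov_y / 2) / math.tan(source.fov_y / 2)) / source.height
    shift_x = target.cx - source.cx * scale_x
    shift_y = target.cy - source.cy * scale_y
    return RegistrationParams(
        scale_x=scale_x, scale_y=scale_y, shift_x=shift_x, shift_y=shift_y,
        crop_width=target.width, crop_height=target.height,
    )


@dataclass
class MultimodalFrame:
    """Co-registered RGB + depth + IR rasters (the five-channel pixel model).

    ``depth`` is in millimetres with 0 reserved for "no measurement";
    ``ir`` is in raw radiometric counts.  ``timepoint`` distinguishes the
    acquisition at the start of the exam (T0) from the one five minutes
    later (T5).
    """

    rgb: np.ndarray
    depth: np.ndarray
    ir: np.ndarray
    frame_id: str = ""
    timepoint: str = "T0"

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise FormatError("rgb must be an HxWx3 raster")
        if self.depth.ndim != 2 or self.ir.ndim != 2:
            raise FormatError("depth and ir must be single-channel rasters")
        if not (self.rgb.shape[:2] == self.depth.shape == self.ir.shape):
            raise FormatError("rgb, depth and ir must share identical HxW")
        if np.any(self.depth < 0):
            raise FormatError("depth values must be non-negative")
        if self.timepoint not in ("T0", "T5"):
            raise ParameterError("timepoint must be 'T0' or 'T5'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class BinaryMask:
    """Single-channel foreground/background raster with values in {0, 1}."""

    data: np.ndarray
    side: str = "both"

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise FormatError("mask must be a single-channel raster")
        if not np.isin(self.data, (0, 1)).all():
            raise FormatError("mask values must be strictly in {0, 1}")
        if self.side not in ("left", "right", "both"):
            raise ParameterError("side must be 'left', 'right' or 'both'")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------

def _read_png(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    return np.asarray(iio.imread(path))


def load_frame(
    rgb_path: str | Path,
    depth_path: str | Path,
    ir_path: str | Path,
    frame_id: str = "",
    timepoint: str = "T0",
) -> MultimodalFrame:
    """Load a multimodal frame from three PNG files.

    RGB may be 3- or 4-channel 8-bit (an alpha channel is discarded); depth
    and IR must be single-channel 16-bit.  Bit depths are preserved
    losslessly; no registration is applied here.
    """
    rgb = _read_png(rgb_path)
    if rgb.ndim != 3 or rgb.shape[2] not in (3, 4) or rgb.dtype != np.uint8:
        raise FormatError(
            f"{rgb_path}: expected 8-bit RGB or RGBA PNG, got "
            f"shape {rgb.shape} dtype {rgb.dtype}"
        )
    rgb = rgb[:, :, :3]

    depth = _read_png(depth_path)
    if depth.ndim != 2 or depth.dtype != np.uint16:
        raise FormatError(
            f"{depth_path}: expected single-channel 16-bit depth PNG, got "
            f"shape {depth.shape} dtype {depth.dtype}"
        )
    ir = _read_png(ir_path)
    if ir.ndim != 2 or ir.dtype != np.uint16:
        raise FormatError(
            f"{ir_path}: expected single-channel 16-bit IR PNG, got "
            f"shape {ir.shape} dtype {ir.dtype}"
        )
    return MultimodalFrame(rgb=rgb, depth=depth, ir=ir,
                           frame_id=frame_id, timepoint=timepoint)


def save_frame(frame: MultimodalFrame, directory: str | Path) -> None:
    """Write ``rgb.png``, ``depth.png`` and ``ir.png`` into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "rgb.png", frame.rgb.astype(np.uint8))
    iio.imwrite(directory / "depth.png", frame.depth.astype(np.uint16))
    iio.imwrite(directory / "ir.png", frame.ir.astype(np.uint16))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit single-channel PNG with 0/255 coding."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), (mask.data * 255).astype(np.uint8))


def load_mask(path: str | Path, side: str = "both") -> BinaryMask:
    """Read a 0/255-coded mask PNG; any other pixel value is a format error."""
    data = _read_png(path)
    if data.ndim == 3:  # tolerate RGB(A)-saved masks if channels agree
        if not (data[..., :3] == data[..., :1]).all():
            raise FormatError(f"{path}: mask PNG must be single-channel")
        data = data[..., 0]
    if not np.isin(data, (0, 255)).all():
        bad = np.unique(data[~np.isin(data, (0, 255))])[:5]
        raise FormatError(
            f"{path}: mask PNG must contain only 0 and 255, found {bad.tolist()}"
        )
    return BinaryMask(data=(data == 255).astype(np.uint8), side=side)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_rgbd_to_ir(
    rgb: np.ndarray,
    depth: np.ndarray,
    params: RegistrationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample RGB and depth rasters onto the IR grid.

    RGB is interpolated bilinearly; depth uses nearest-neighbour sampling so
    that depth values are never blended across object edges (a blended depth
    at a silhouette would be a measurement of nothing).  Target pixels whose
    pre-image falls outside the source raster become black / depth 0.
    """
    if rgb.shape[:2] != depth.shape:
        raise ParameterError("rgb and depth must share HxW")
    h, w = params.crop_height, params.crop_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    src_x = (xx - params.shift_x) / params.scale_x
    src_y = (yy - params.shift_y) / params.scale_y
    coords = np.stack([src_y, src_x])

    rgb_reg = np.zeros((h, w, 3), dtype=rgb.dtype)
    for ch in range(3):
        rgb_reg[:, :, ch] = ndimage.map_coordinates(
            rgb[:, :, ch].astype(np.float64), coords, order=1,
            mode="constant", cval=0.0,
        ).round().clip(0, 255).astype(rgb.dtype)
    depth_reg = ndimage.map_coordinates(
        depth, coords, order=0, mode="constant", cval=0
    ).astype(depth.dtype)
    return rgb_reg, depth_reg


def register_frame(
    rgb: np.ndarray,
    depth: np.ndarray,
    ir: np.ndarray,
    params: RegistrationParams,
    frame_id: str = "",
    timepoint: str = "T0",
) -> MultimodalFrame:
    """Register RGB-D onto the IR grid and bundle a MultimodalFrame."""
    if ir.shape != (params.crop_height, params.crop_width):
        raise ParameterError(
            f"IR raster {ir.shape} does not match crop "
            f"({params.crop_height}, {params.crop_width})"
        )
    rgb_reg, depth_reg = register_rgbd_to_ir(rgb, depth, params)
    return MultimodalFrame(rgb=rgb_reg, depth=depth_reg, ir=ir,
                           frame_id=frame_id, timepoint=timepoint)
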