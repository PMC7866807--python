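"""Depth-based refinement of a candidate foot mask.

While a subject sits with legs extended and feet off the ground, the foot
soles face the camera as an approximately planar surface at a known
stand-off (~80 cm), whereas skin-coloured or warm background structure
(hands, face, furniture) lies at other depths.  The refinement stage
exploits this: the candidate mask's depth pixels are deprojected to a point
cloud, a statistical outlier filter removes stray edge points, RANSAC
extracts the dominant (foot-sole) plane, and mask pixels farther from that
plane than a distance threshold are discarded.  The threshold can be
derived automatically from the standard deviation of the masked depth
values.

The stage accepts *any* candidate mask — the skin-threshold mask (the SPD
pipeline, implemented end-to-end here) or an externally produced CNN
prediction (the UPD scenario) — which is why :func:`refine_mask` only ever
removes pixels, never adds them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .errors import (DegenerateInputError, NoPlaneError, ParameterError,
                     PlantarsegError)
from .frames import DEFAULT_IR_CAMERA, BinaryMask, CameraModel, MultimodalFrame
from .skin import SkinThresholds, skin_mask


@dataclass
class PointCloud:
    """3-D points in millimetres in the camera frame (x right, y down,
    z forward), with per-point (row, col) back-references into the source
    raster.  ``undeprojectable`` lists mask pixels that had no valid depth
    and therefore produced no point."""

    points: np.ndarray                 # (N, 3) float64, all z > 0
    pixel_index: np.ndarray            # (N, 2) int, unique (row, col)
    undeprojectable: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.intp))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.intp).reshape(-1, 2)
        if len(self.points) != len(self.pixel_index):
            raise ParameterError("points and pixel_index lengths differ")
        if np.any(self.points[:, 2] <= 0):
            raise ParameterError("point cloud contains non-positive z")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Plane:
    """Plane {x : normal . x = d} with unit normal, canonicalised to d >= 0."""

    normal: np.ndarray
    d: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            raise ParameterError("plane normal must be unit length")
        if self.d < 0:
            object.__setattr__(self, "normal", -n)
            object.__setattr__(self, "d", -self.d)
        else:
            object.__setattr__(self, "normal", n)

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned orthogonal distance of each point to the plane, in mm."""
        return np.abs(points @ self.normal - self.d)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Plane":
        """Total-least-squares plane through >= 3 points (smallest principal
        direction of the centred cloud)."""
        pts = np.asarray(points, dtype=np.float64)
        if len(pts) < 3:
            raise DegenerateInputError("need at least 3 points to fit a plane")
        centroid = pts.mean(axis=0)
        _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        normal = vt[-1]
        normal = normal / np.linalg.norm(normal)
        return cls(normal=normal, d=float(normal @ centroid))


@dataclass(frozen=True)
class RansacConfig:
    """RANSAC parameters.  ``distance_threshold_mm=None`` means AUTO: derive
    the threshold as ``auto_scale_c`` times the standard deviation of the
    masked depth values (see :func:`auto_distance_threshold`)."""

    iterations: int = 500
    distance_threshold_mm: float | None = None
    auto_scale_c: float = 2.0
    min_inliers: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if self.distance_threshold_mm is not None and self.distance_threshold_mm <= 0:
            raise ParameterError("distance threshold must be positive")
        if self.auto_scale_c <= 0:
            raise ParameterError("auto_scale_c must be positive")


@dataclass(frozen=True)
class StatFilterConfig:
    """k-nearest-neighbour statistical outlier filter parameters."""

    k_neighbors: int = 20
    std_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ParameterError("k_neighbors must be >= 1")
        if self.std_multiplier <= 0:
            raise ParameterError("std_multiplier must be positive")


def mask_to_pointcloud(
    mask: BinaryMask,
    depth: np.ndarray,
    camera: CameraModel = DEFAULT_IR_CAMERA,
) -> PointCloud:
    """Deproject the valid-depth pixels under *mask* through the pinhole
    model: ``x = (c - cx) z / fx``, ``y = (r - cy) z / fy``, ``z = depth``.

    Mask pixels with depth 0 produce no point but are recorded as
    undeprojectable so that :func:`refine_mask` can apply its policy.
    """
    if mask.shape != depth.shape:
        raise ParameterError("mask and depth must share dimensions")
    rows, cols = np.nonzero(mask.data)
    z = depth[rows, cols].astype(np.float64)
    valid = z > 0
    if not valid.any():
        raise DegenerateInputError(
            "no foreground pixel has a valid depth measurement")
    r, c, zv = rows[valid], cols[valid], z[valid]
    x = (c - camera.cx) * zv / camera.fx
    y = (r - camera.cy) * zv / camera.fy
    return PointCloud(
        points=np.column_stack([x, y, zv]),
        pixel_index=np.column_stack([r, c]),
        undeprojectable=np.column_stack([rows[~valid], cols[~valid]]),
    )


def statistical_outlier_filter(
    pc: PointCloud, config: StatFilterConfig = StatFilterConfig()
) -> PointCloud:
    """Remove points whose mean distance to their k nearest neighbours
    exceeds (global mean + std_multiplier * global std) of those per-point
    mean distances.  Stray points at mask edges — depth pixels straddling
    the silhouette — are the typical casualties."""
    n = len(pc)
    if n <= config.k_neighbors:
        raise DegenerateInputError(
            f"need more than k_neighbors={config.k_neighbors} points, got {n}")
    tree = cKDTree(pc.points)
    # first neighbour is the point itself
    dists, _ = tree.query(pc.points, k=config.k_neighbors + 1)
    mean_dist = dists[:, 1:].mean(axis=1)
    cutoff = mean_dist.mean() + config.std_multiplier * mean_dist.std()
    # slack so equidistant configurations (zero variance up to float error)
    # are never clipped by rounding noise
    keep = mean_dist <= cutoff + 1e-9 * max(1.0, cutoff)
    return PointCloud(points=pc.points[keep],
                      pixel_index=pc.pixel_index[keep],
                      undeprojectable=pc.undeprojectable)


def ransac_plane(
    pc: PointCloud,
    config: RansacConfig,
    distance_threshold_mm: float | None = None,
) -> tuple[Plane, np.ndarray]:
    """Extract the best plane from the cloud by RANSAC.

    Each iteration draws 3 distinct points (near-collinear triples are
    skipped), forms the candidate plane and counts points within the
    distance threshold; the candidate with the most inliers wins (ties go to
    the first encountered).  The returned plane is the total-least-squares
    refit on the winning inlier set; the second return value is the sorted
    index array of the points within the threshold of that *refitted* plane,
    so the set is consistent with the plane callers actually receive.
    Fully deterministic under a fixed seed.
    """
    threshold = (distance_threshold_mm if distance_threshold_mm is not None
                 else config.distance_threshold_mm)
    if threshold is None or threshold <= 0:
        raise ParameterError("a positive distance threshold is required "
                             "(pass one or use auto_distance_threshold)")
    pts = pc.points
    n = len(pts)
    if n < 3:
        raise DegenerateInputError("RANSAC needs at least 3 points")

    rng = np.random.default_rng(config.seed)
    best_count = 0
    best_inliers: np.ndarray | None = None
    for _ in range(config.iterations):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[idx]
        v1, v2 = p1 - p0, p2 - p0
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        # collinearity guard, scale-aware
        if norm <= 1e-9 * (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-300):
            continue
        normal = normal / norm
        dist = np.abs((pts - p0) @ normal)
        count = int((dist <= threshold).sum())
        if count > best_count:
            best_count = count
            best_inliers = np.nonzero(dist <= threshold)[0]
    if best_inliers is None:
        raise NoPlaneError("all sampled triples were degenerate")
    if best_count < config.min_inliers:
        raise NoPlaneError(
            f"best candidate has {best_count} inliers < min_inliers="
            f"{config.min_inliers}")
    plane = Plane.from_points(pts[best_inliers])
    final_inliers = np.nonzero(plane.distance(pts) <= threshold)[0]
    return plane, final_inliers


def auto_distance_threshold(
    depth: np.ndarray, mask: BinaryMask, c: float = 2.0, robust: bool = True
) -> float:
    """Distance threshold derived from the depth data itself: *c* times the
    standard deviation of the depth at the surface of the feet.

    The candidate mask may contain skin-coloured background blobs at a very
    different depth, which would inflate a plain sample standard deviation
    by orders of magnitude and defeat the subsequent plane test.  The
    default therefore rejects values outside the Tukey fences
    (quartile ± 1.5 IQR) and takes the sample standard deviation of the
    remainder, rescaled by the normal-consistency constant 0.9711: this
    measures the spread of the dominant surface — the feet — agrees with
    the plain std on clean Gaussian depth, and stays stable on
    integer-millimetre data where pure quantile estimators quantise.
    ``robust=False`` selects the plain sample std.

    Zero (invalid) depths are discarded before estimation.
    """
    if mask.shape != depth.shape:
        raise ParameterError("mask and depth must share dimensions")
    vals = depth[mask.as_bool()].astype(np.float64)
    vals = vals[vals > 0]
    if len(vals) < 2:
        raise DegenerateInputError(
            "need at least 2 valid-depth masked pixels for the auto threshold")
    if robust:
        q25, q75 = np.percentile(vals, [25, 75])
        iqr = q75 - q25
        if iqr == 0:
            sigma = 0.0  # dominant surface is depth-constant
        else:
            inner = vals[(vals >= q25 - 1.5 * iqr) & (vals <= q75 + 1.5 * iqr)]
            # 0.9711 restores normal consistency after the ±2.7σ fence cut
            sigma = inner.std(ddof=1) / 0.9711
    else:
        sigma = vals.std(ddof=1)
    return float(c * sigma)


def refine_mask(
    mask: BinaryMask,
    plane: Plane,
    pc: PointCloud,
    threshold_mm: float,
    undeprojectable_policy: str = "drop",
) -> BinaryMask:
    """Keep only mask pixels whose 3-D point lies within *threshold_mm* of
    the plane; never adds pixels outside the input mask.

    Pixels with no valid depth cannot be tested against the plane; the
    policy decides their fate: ``drop`` (default), ``keep``, or
    ``fill-by-neighbor-vote`` (re-added when the majority of their refined
    8-neighbourhood is foreground).
    """
    if threshold_mm <= 0:
        raise ParameterError("threshold_mm must be positive")
    if undeprojectable_policy not in ("drop", "keep", "fill-by-neighbor-vote"):
        raise ParameterError(f"unknown policy {undeprojectable_policy!r}")
    out = np.zeros(mask.shape, dtype=np.uint8)
    keep = plane.distance(pc.points) <= threshold_mm
    r, c = pc.pixel_index[keep].T
    out[r, c] = 1
    und = pc.undeprojectable
    if len(und):
        if undeprojectable_policy == "keep":
            out[und[:, 0], und[:, 1]] = 1
        elif undeprojectable_policy == "fill-by-neighbor-vote":
            neigh = ndimage.convolve(out.astype(np.int16),
                                     np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
                                     mode="constant")
            vote = neigh[und[:, 0], und[:, 1]] > 4
            out[und[:, 0][vote], und[:, 1][vote]] = 1
    out &= mask.data  # output is always a subset of the input mask
    return BinaryMask(data=out, side=mask.side)


@dataclass
class SpdResult:
    """All artifacts of one SPD run, retrievable for inspection."""

    mask: BinaryMask                   # final refined mask
    skin: BinaryMask                   # raw skin-threshold mask
    cloud: PointCloud                  # deprojected candidate cloud
    filtered_cloud: PointCloud         # after the statistical filter
    plane: Plane
    inliers: np.ndarray                # indices into filtered_cloud
    threshold_mm: float


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise library errors with the
    pipeline stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, PlantarsegError):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False
    return _Ctx()


def segment_spd(
    frame: MultimodalFrame,
    thresholds: SkinThresholds | None = None,
    stat_cfg: StatFilterConfig = StatFilterConfig(),
    ransac_cfg: RansacConfig = RansacConfig(),
    camera: CameraModel = DEFAULT_IR_CAMERA,
    undeprojectable_policy: str = "drop",
) -> SpdResult:
    """The full Skin-plus-Depth pipeline on a registered frame.

    Composition: skin threshold -> deprojection -> statistical outlier
    filter -> RANSAC best plane (AUTO distance threshold unless the config
    fixes one) -> discard off-plane pixels.  Returns an :class:`SpdResult`
    whose ``mask`` attribute is the final segmentation and whose other
    fields expose every intermediate artifact.
    """
    with _stage("skin"):
        skin = skin_mask(frame.rgb, thresholds)
    with _stage("deproject"):
        cloud = mask_to_pointcloud(skin, frame.depth, camera)
    with _stage("statistical_filter"):
        filtered = statistical_outlier_filter(cloud, stat_cfg)
    with _stage("threshold"):
        if ransac_cfg.distance_threshold_mm is not None:
            threshold = ransac_cfg.distance_threshold_mm
        else:
            threshold = auto_distance_threshold(
                frame.depth, skin, ransac_cfg.auto_scale_c)
            if threshold <= 0:
                raise DegenerateInputError(
                    "masked depth is constant; AUTO threshold is 0 — "
                    "set distance_threshold_mm explicitly")
    with _stage("ransac"):
        plane, inliers = ransac_plane(filtered, ransac_cfg, threshold)
    with _stage("refine"):
        refined = refine_mask(skin, plane, filtered, threshold,
                              undeprojectable_policy)
    return SpdResult(mask=refined, skin=skin, cloud=cloud,
                     filtered_cloud=filtered, plane=plane, inliers=inliers,
                     threshold_mm=threshold)


def refine_candidate(
    mask: BinaryMask,
    frame: MultimodalFrame,
    stat_cfg: StatFilterConfig = StatFilterConfig(),
    ransac_cfg: RansacConfig = RansacConfig(),
    camera: CameraModel = DEFAULT_IR_CAMERA,
    undeprojectable_policy: str = "drop",
) -> SpdResult:
    """Depth-refine an externally produced candidate mask (the UPD scenario:
    a CNN prediction, or any other proposal) with the same stages as
    :func:`segment_spd` minus the skin threshold."""
    with _stage("deproject"):
        cloud = mask_to_pointcloud(mask, frame.depth, camera)
    with _stage("statistical_filter"):
        filtered = statistical_outlier_filter(cloud, stat_cfg)
    with _stage("threshold"):
        if ransac_cfg.distance_threshold_mm is not None:
            threshold = ransac_cfg.distance_threshold_mm
        else:
            threshold = auto_distance_threshold(
                frame.depth, mask, ransac_cfg.auto_scale_c)
            if threshold <= 0:
                raise DegenerateInputError(
                    "masked depth is constant; AUTO threshold is 0 — "
                    "set distance_threshold_mm explicitly")
    with _stage("ransac"):
        plane, inliers = ransac_plane(filtered, ransac_cfg, threshold)
    with _stage("refine"):
        refined = refine_mask(mask, plane, filtered, threshold,
                              undeprojectable_policy)
    return SpdResult(mask=refined, skin=mask, cloud=cloud,
                     filtered_cloud=filtered, plane=plane, inliers=inliers,
                     threshold_mm=threshold)


def export_ply(pc: PointCloud, path: str | Path) -> None:
    """Write the cloud as ASCII PLY for debugging in external viewers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pc)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in pc.points:
            fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")
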