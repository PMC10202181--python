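"""Road segmentation and CVT sub-goal generation.

Pipeline: an RGB frame from the robot's downward-pitched camera is
binarized by 2-means color clustering, cleaned by morphological
close/open, and the 4-connected component containing the bottom-center
pixel (the ground "under the robot's feet") is taken as the drivable road
region Ω. A Centroidal Voronoi Tessellation of Ω — computed by Lloyd's
alternating assign/centroid iteration on the pixel grid — places ``n``
generators that end up coinciding with their cells' mass centroids. Each
converged generator, back-projected through the camera's ground-plane
geometry and the robot pose, becomes one numbered navigation sub-goal.

The CVT objective is the discrete form of

    J(X, V) = sum_i  sum_{y in V_i} ||y - x_i||^2

with cells V_i the nearest-generator partition of Ω; Lloyd's iteration
weakly decreases J at both the assignment and the centroid step.

Coordinate conventions (used everywhere in this package):

* image: origin top-left, ``x`` right (columns), ``y`` down (rows), 0-based,
  pixel centers on integer coordinates;
* robot frame: ``x`` forward, ``y`` left, meters;
* world frame: planar, heading counterclockwise in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from skimage import measure, morphology
from sklearn.cluster import KMeans

__all__ = [
    "DegenerateImageError",
    "NoRoadFoundError",
    "RoadRegion",
    "CvtConfig",
    "VoronoiPartition",
    "CvtResult",
    "CameraGeometry",
    "SubGoal",
    "binarize_kmeans",
    "denoise",
    "extract_road_region",
    "voronoi_assign",
    "cell_centroid",
    "objective",
    "cvt_lloyd",
    "pixel_to_robot",
    "robot_to_pixel",
    "robot_to_world",
    "world_to_robot",
    "ground_plane_grid",
    "generate_subgoals",
]


class DegenerateImageError(ValueError):
    """The image has a single distinct color; 2-means cannot split it."""


class NoRoadFoundError(ValueError):
    """The bottom-center pixel is not foreground; no road region anchors."""


# ------------------------------------------------------------------- types


@dataclass
class RoadRegion:
    """Drivable road pixels: binary mask, pixel coordinate list, boundary.

    ``pixels`` is ``(N, 2)`` float ``(x, y)`` pixel-center coordinates;
    ``boundary`` is the traced outline of the region as ``(M, 2)`` ``(x, y)``
    points.
    """

    mask: np.ndarray
    pixels: np.ndarray
    boundary: np.ndarray

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RoadRegion":
        mask = np.asarray(mask, dtype=bool)
        ys, xs = np.nonzero(mask)
        if xs.size == 0:
            raise ValueError("empty region")
        pixels = np.column_stack([xs, ys]).astype(float)
        # trace the outer boundary; pad so contours close at image edges
        padded = np.pad(mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        boundary = np.empty((0, 2))
        if contours:
            longest = max(contours, key=len)
            boundary = np.column_stack([longest[:, 1] - 1, longest[:, 0] - 1])
        return cls(mask, pixels, boundary)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


@dataclass
class CvtConfig:
    """Lloyd-iteration settings.

    ``n_generators`` defaults to 11 — one per numeric command in the
    selection interface. ``density`` is an optional weight over Ω: either a
    callable ``rho(x, y)`` or an array aligned with the region mask; omitted
    means uniform. ``tol`` is the convergence threshold on generator
    displacement, in pixels.
    """

    n_generators: int = 11
    density: Callable[[np.ndarray, np.ndarray], np.ndarray] | np.ndarray | None = None
    tol: float = 0.5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generators < 1:
            raise ValueError("n_generators must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class VoronoiPartition:
    """Nearest-generator assignment of region pixels.

    ``generators`` is ``(n, 2)`` continuous ``(x, y)``; ``labels`` assigns
    each row of ``pixels`` to a generator index, ties broken toward the
    lowest index. ``weights`` are the density values at the pixels (ones if
    uniform).
    """

    generators: np.ndarray
    labels: np.ndarray
    pixels: np.ndarray
    weights: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.generators.shape[0]

    def cell_pixels(self, i: int) -> np.ndarray:
        return self.pixels[self.labels == i]


@dataclass
class CvtResult:
    """Outcome of Lloyd's iteration: converged generators, final partition,
    and the objective value recorded at every iteration."""

    generators: np.ndarray
    partition: VoronoiPartition
    j_history: list[float]
    n_iterations: int
    converged: bool


@dataclass
class CameraGeometry:
    """Forward camera pitched toward the ground plane.

    Rays are mapped per pixel *center*: pixel row ``v`` looks down at
    ``pitch - vfov/2 + (v + 0.5)/H * vfov`` degrees below the horizon, and
    column ``u`` bears ``hfov/2 - (u + 0.5)/W * hfov`` degrees (positive
    left). The defaults put the top image edge exactly on the horizon, so
    only pixel centers (never the edge itself) are back-projected.
    """

    height: float = 0.65
    pitch_deg: float = 30.0
    hfov_deg: float = 70.0
    vfov_deg: float = 60.0
    image_size: tuple[int, int] = (160, 120)  # (width, height) pixels

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("camera height must be positive")
        if self.pitch_deg - self.vfov_deg / 2 < 0:
            raise ValueError("top of view must not look above the horizon")
        if self.pitch_deg + self.vfov_deg / 2 >= 90:
            raise ValueError("bottom of view must stay in front of the robot")


@dataclass
class SubGoal:
    """One numbered navigation sub-goal in all three frames."""

    number: int
    pixel: tuple[float, float]
    robot: tuple[float, float]
    world: tuple[float, float]


# -------------------------------------------------------------- extraction


def binarize_kmeans(image: np.ndarray, seed: int = 0) -> np.ndarray:
    """Split an RGB image into road/background by 2-means color clustering.

    The cluster containing the bottom-center pixel is labeled road
    (foreground), anchoring on geometry rather than brightness, so swapping
    road and background colors leaves the mask unchanged.

    Initialization is deterministic: the color farthest from the mean color,
    then the color farthest from that one.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    H, W = image.shape[:2]
    flat = image.reshape(-1, 3)
    mean = flat.mean(axis=0)
    c0 = flat[np.argmax(((flat - mean) ** 2).sum(axis=1))]
    c1 = flat[np.argmax(((flat - c0) ** 2).sum(axis=1))]
    if np.allclose(c0, c1):
        raise DegenerateImageError("image has a single distinct color")
    km = KMeans(n_clusters=2, init=np.vstack([c0, c1]), n_init=1, random_state=seed)
    labels = km.fit_predict(flat).reshape(H, W)
    return labels == labels[H - 1, W // 2]


def denoise(mask: np.ndarray, struct_size: int = 5) -> np.ndarray:
    """Morphological closing then opening with a square structuring element,
    removing small isolated specks and holes."""
    mask = np.asarray(mask, dtype=bool)
    footprint = np.ones((struct_size, struct_size), dtype=bool)
    return morphology.opening(morphology.closing(mask, footprint), footprint)


def extract_road_region(mask: np.ndarray) -> RoadRegion:
    """The 4-connected foreground component containing the bottom-center
    pixel — the area "under the robot's feet"."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    labeled = measure.label(mask, connectivity=1)
    anchor = labeled[H - 1, W // 2]
    if anchor == 0:
        raise NoRoadFoundError("bottom-center pixel is not foreground")
    return RoadRegion.from_mask(labeled == anchor)


# --------------------------------------------------------------------- CVT


def _density_weights(region_or_pixels, density) -> np.ndarray:
    if isinstance(region_or_pixels, RoadRegion):
        pixels = region_or_pixels.pixels
    else:
        pixels = np.asarray(region_or_pixels, dtype=float)
    if density is None:
        return np.ones(len(pixels))
    if callable(density):
        w = np.asarray(density(pixels[:, 0], pixels[:, 1]), dtype=float)
    else:
        arr = np.asarray(density, dtype=float)
        w = arr[pixels[:, 1].astype(int), pixels[:, 0].astype(int)]
    if w.shape != (len(pixels),) or (w < 0).any():
        raise ValueError("density must yield one non-negative weight per pixel")
    return w


def voronoi_assign(
    region: RoadRegion,
    generators: np.ndarray,
    density: Callable | np.ndarray | None = None,
) -> VoronoiPartition:
    """Assign every region pixel to its nearest generator (Euclidean).

    ``argmin`` breaks distance ties toward the lowest generator index. Cells
    are disjoint and cover Ω exactly by construction.
    """
    generators = np.atleast_2d(np.asarray(generators, dtype=float))
    if generators.shape[0] < 1 or generators.shape[1] != 2:
        raise ValueError("generators must be (n, 2)")
    if region.n_pixels == 0:
        raise ValueError("empty region")
    d = cdist(region.pixels, generators)
    labels = np.argmin(d, axis=1)
    return VoronoiPartition(
        generators, labels, region.pixels, _density_weights(region, density)
    )


def cell_centroid(partition: VoronoiPartition, cell: int) -> np.ndarray:
    """Density-weighted mean of a cell's pixel coordinates (discrete
    centroid); invariant to scaling the density by a constant."""
    sel = partition.labels == cell
    if not sel.any():
        raise ValueError(f"cell {cell} is empty")
    w = partition.weights[sel]
    if w.sum() == 0:
        w = np.ones(sel.sum())
    return np.average(partition.pixels[sel], axis=0, weights=w)


def objective(partition: VoronoiPartition) -> float:
    """Discrete CVT objective: sum of squared pixel-to-generator distances."""
    diffs = partition.pixels - partition.generators[partition.labels]
    return float((diffs**2).sum())


def cvt_lloyd(region: RoadRegion, config: CvtConfig | None = None) -> CvtResult:
    """Compute a CVT of the region by Lloyd's descent.

    Generators start at ``n`` distinct random region pixels (seeded), then
    alternate nearest-generator assignment and centroid moves until the
    largest generator displacement is at most ``tol`` pixels or ``max_iter``
    is hit. The recorded objective history is non-increasing (both Lloyd
    steps weakly decrease J); at convergence each generator sits within
    ``tol`` of its cell's centroid — the CVT fixed-point condition.

    An emptied cell (possible on sparse discrete regions) keeps its
    generator in place for that iteration.
    """
    config = config or CvtConfig()
    n = config.n_generators
    if n > region.n_pixels:
        raise ValueError(
            f"{n} generators requested but region has {region.n_pixels} pixels"
        )
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(region.n_pixels, size=n, replace=False)
    generators = region.pixels[idx].copy()

    j_history: list[float] = []
    converged = False
    iteration = 0
    partition = voronoi_assign(region, generators, config.density)
    for iteration in range(1, config.max_iter + 1):
        j_history.append(objective(partition))
        new_gen = generators.copy()
        for i in range(n):
            if (partition.labels == i).any():
                new_gen[i] = cell_centroid(partition, i)
        displacement = np.linalg.norm(new_gen - generators, axis=1).max()
        generators = new_gen
        partition = voronoi_assign(region, generators, config.density)
        if displacement <= config.tol:
            converged = True
            break
    j_history.append(objective(partition))
    return CvtResult(generators, partition, j_history, iteration, converged)


# ------------------------------------------------------------- projection


def _as_xy(p) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(p, dtype=float)
    return arr[..., 0], arr[..., 1]


def pixel_to_robot(pixel, camera: CameraGeometry) -> np.ndarray:
    """Back-project image coordinates onto the ground plane (robot frame).

    ``pixel`` is ``(u, v)`` (or an array of them) in continuous image
    coordinates. The pixel row fixes a depression angle below the horizon,
    so forward distance is ``height / tan(angle)``; the column fixes a
    bearing (positive left), so lateral offset is ``forward * tan(bearing)``.
    Raises if the ray is at or above the horizon.
    """
    u, v = _as_xy(pixel)
    W, H = camera.image_size
    depression = np.deg2rad(
        camera.pitch_deg - camera.vfov_deg / 2 + (v + 0.5) / H * camera.vfov_deg
    )
    if np.any(depression <= 0):
        raise ValueError("pixel ray at or above the horizon")
    forward = camera.height / np.tan(depression)
    bearing = np.deg2rad(camera.hfov_deg / 2 - (u + 0.5) / W * camera.hfov_deg)
    lateral = forward * np.tan(bearing)
    return np.stack([forward, lateral], axis=-1)


def robot_to_pixel(point, camera: CameraGeometry) -> np.ndarray:
    """Inverse of :func:`pixel_to_robot` for ground-plane points ahead of
    the robot."""
    x, y = _as_xy(point)
    if np.any(x <= 0):
        raise ValueError("point must be in front of the camera (x > 0)")
    W, H = camera.image_size
    depression = np.rad2deg(np.arctan2(camera.height, x))
    v = (depression - camera.pitch_deg + camera.vfov_deg / 2) * H / camera.vfov_deg - 0.5
    bearing = np.rad2deg(np.arctan2(y, x))
    u = (camera.hfov_deg / 2 - bearing) * W / camera.hfov_deg - 0.5
    return np.stack([u, v], axis=-1)


def robot_to_world(point, pose) -> np.ndarray:
    """Rigid transform of robot-frame points by the robot's planar pose.

    ``pose`` is anything with ``x``, ``y``, ``heading`` attributes (heading
    counterclockwise radians, robot x-axis forward).
    """
    px, py = _as_xy(point)
    c, s = np.cos(pose.heading), np.sin(pose.heading)
    return np.stack([pose.x + c * px - s * py, pose.y + s * px + c * py], axis=-1)


def world_to_robot(point, pose) -> np.ndarray:
    """Inverse of :func:`robot_to_world`."""
    wx, wy = _as_xy(point)
    dx, dy = wx - pose.x, wy - pose.y
    c, s = np.cos(pose.heading), np.sin(pose.heading)
    return np.stack([c * dx + s * dy, -s * dx + c * dy], axis=-1)


def ground_plane_grid(camera: CameraGeometry) -> np.ndarray:
    """Robot-frame ground point for every pixel center: ``(H, W, 2)``."""
    W, H = camera.image_size
    u, v = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    return pixel_to_robot(np.stack([u, v], axis=-1), camera)


# ----------------------------------------------------------------- pipeline


def generate_subgoals(
    image: np.ndarray,
    camera: CameraGeometry,
    pose,
    config: CvtConfig | None = None,
    struct_size: int = 5,
    kmeans_seed: int = 0,
) -> list[SubGoal]:
    """Full pipeline: image -> road region -> CVT -> numbered world sub-goals.

    Sub-goals are ordered row-major by image position (top-to-bottom, then
    left-to-right) so the numbering presented in the selection interface is
    stable; the farthest goals get the lowest numbers.
    """
    config = config or CvtConfig()
    mask = denoise(binarize_kmeans(image, seed=kmeans_seed), struct_size)
    region = extract_road_region(mask)
    result = cvt_lloyd(region, config)
    gens = result.generators
    order = np.lexsort((gens[:, 0], gens[:, 1]))  # by y (image row), then x
    goals = []
    for number, i in enumerate(order, start=1):
        px = tuple(gens[i])
        robot_pt = pixel_to_robot(gens[i], camera)
        world_pt = robot_to_world(robot_pt, pose)
        goals.append(SubGoal(number, px, tuple(robot_pt), tuple(world_pt)))
    return goals
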