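"""Planar omnidirectional robot: kinematics, step motions, and navigation.

The robot is a disc of chassis radius R = 0.2 m with three omnidirectional
wheels at 120° to each other. Two layers are modeled:

* **Wheel kinematics** — the printed kinematic matrix

      [va]   [cos θ  -cos θ  0] [vx]
      [vb] = [sin θ   sin θ  0] [vy]
      [vc]   [  r       r    r] [θ']

  with θ = 30°, is implemented verbatim as the default (``variant=
  "printed"``). Its third row couples translation into wheel c and omits
  rotation from wheels a and b, which is dimensionally odd for a 120°
  omniwheel platform; a conventional omniwheel matrix is available as
  ``variant="standard"``. The discrepancy is documented, not silently fixed.

* **Navigation** — single-step body-frame motions (the arrow commands:
  ±30° turns, 20 cm steps in the 8-neighborhood directions, 40 cm forward)
  and autonomous waypoint navigation. The planner is an 8-connected grid A*
  with robot-radius inflation that knows only about *radar-visible*
  obstacles; radar-invisible (extremely low) obstacles are ignored by
  planning but still collide during execution — exactly the situation that
  requires human intervention.

The navigation field is a rectangle enclosed by baffle walls; touching a
wall or an obstacle at exactly radius distance counts as contact.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "KinematicParams",
    "RobotState",
    "Obstacle",
    "WorldMap",
    "Trajectory",
    "UnreachableError",
    "wheel_speeds",
    "check_collision",
    "execute_step_command",
    "plan_path",
    "navigate_to",
    "comparison_world",
    "STEP_COMMANDS",
]

ROBOT_RADIUS = 0.2
GRID_RESOLUTION = 0.025  # m; resolves the 20 cm steps and the 0.2 m radius
GOAL_TOLERANCE = 0.05


class UnreachableError(RuntimeError):
    """No collision-free path exists on the planning grid."""


@dataclass
class KinematicParams:
    """Geometry entering the kinematic matrix: wheel offset ``r`` (center to
    wheel), wheel angle θ (30°), chassis radius R, chassis length L."""

    r: float = 0.2
    theta_deg: float = 30.0
    chassis_radius: float = ROBOT_RADIUS
    length: float = 0.7

    def __post_init__(self) -> None:
        if not self.r > 0 or not self.chassis_radius > 0:
            raise ValueError("r and chassis_radius must be positive")


@dataclass
class RobotState:
    """Planar pose: position in meters, heading counterclockwise radians."""

    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.heading))):
            raise ValueError("pose must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Obstacle:
    """Axis-aligned rectangular obstacle; ``radar_visible=False`` marks an
    extremely low obstacle the range sensor cannot see."""

    x: float
    y: float
    w: float
    h: float
    radar_visible: bool = True

    def distance_to(self, px: float, py: float) -> float:
        """Euclidean distance from a point to the rectangle (0 inside)."""
        dx = max(self.x - px, 0.0, px - (self.x + self.w))
        dy = max(self.y - py, 0.0, py - (self.y + self.h))
        return math.hypot(dx, dy)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2, self.y + self.h / 2)


@dataclass
class WorldMap:
    """Rectangular baffle-enclosed field with obstacles, start, destination."""

    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    obstacles: list[Obstacle] = field(default_factory=list)
    start: tuple[float, float] = (0.0, 0.0)
    destination: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("bounds must be a non-empty rectangle")
        for ob in self.obstacles:
            if not (
                xmin <= ob.x and ob.x + ob.w <= xmax
                and ymin <= ob.y and ob.y + ob.h <= ymax
            ):
                raise ValueError("obstacle outside field bounds")
        for name, (px, py) in (("start", self.start), ("destination", self.destination)):
            if check_collision(RobotState(px, py), self):
                raise ValueError(f"{name} point is not collision-free")

    def visible_obstacles(self) -> list[Obstacle]:
        return [o for o in self.obstacles if o.radar_visible]

    def invisible_obstacles(self) -> list[Obstacle]:
        return [o for o in self.obstacles if not o.radar_visible]

    # ------------------------------------------------------------------- io

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "bounds": list(self.bounds),
            "start": list(self.start),
            "destination": list(self.destination),
            "obstacles": [
                {"x": o.x, "y": o.y, "w": o.w, "h": o.h,
                 "radar_visible": o.radar_visible}
                for o in self.obstacles
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorldMap":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            bounds=tuple(doc["bounds"]),
            obstacles=[Obstacle(**o) for o in doc.get("obstacles", [])],
            start=tuple(doc.get("start", (0.0, 0.0))),
            destination=tuple(doc.get("destination", (1.0, 0.0))),
        )


@dataclass
class Trajectory:
    """Executed path: sampled points, whether a collision cut it short, and
    whether the goal was reached (within 5 cm)."""

    points: np.ndarray  # (K, 2)
    reached: bool
    collided: bool = False
    collision_point: tuple[float, float] | None = None

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def comparison_world() -> WorldMap:
    """The comparison-experiment scenario: a 4.60 m x 2.25 m baffled field,
    start near the upper-left corner, destination near the lower-right, and
    two 0.35 m x 0.60 m radar-invisible obstacles astride the direct route.
    """
    return WorldMap(
        bounds=(-0.3, -0.625, 4.3, 1.625),
        obstacles=[
            Obstacle(1.125, 0.025, 0.35, 0.60, radar_visible=False),
            Obstacle(2.625, 0.40, 0.35, 0.60, radar_visible=False),
        ],
        start=(0.0, 0.0),
        destination=(4.0, 1.0),
    )


# ------------------------------------------------------------- kinematics


def wheel_speeds(
    vx: float,
    vy: float,
    theta_term: float,
    params: KinematicParams | None = None,
    variant: str = "printed",
) -> tuple[float, float, float]:
    """Wheel linear velocities for a body-frame velocity command.

    ``variant="printed"`` multiplies the kinematic matrix exactly as
    published; ``variant="standard"`` uses the conventional three-omniwheel
    matrix (wheels at 90°, 210°, 330°) where ``theta_term`` is the yaw rate.
    """
    params = params or KinematicParams()
    if variant == "printed":
        th = math.radians(params.theta_deg)
        va = math.cos(th) * vx - math.cos(th) * vy
        vb = math.sin(th) * vx + math.sin(th) * vy
        vc = params.r * (vx + vy + theta_term)
        return va, vb, vc
    if variant == "standard":
        speeds = []
        for phi_deg in (90.0, 210.0, 330.0):
            phi = math.radians(phi_deg)
            speeds.append(
                -math.sin(phi) * vx + math.cos(phi) * vy + params.r * theta_term
            )
        return tuple(speeds)
    raise ValueError(f"unknown kinematics variant {variant!r}")


# -------------------------------------------------------------- collision


def check_collision(
    state: RobotState,
    world: WorldMap,
    radius: float = ROBOT_RADIUS,
    visible_only: bool = False,
) -> bool:
    """True iff the robot disc touches any obstacle or baffle wall.

    Contact at exactly ``radius`` counts (closed contact rule).
    """
    xmin, ymin, xmax, ymax = world.bounds
    wall_clearance = min(state.x - xmin, xmax - state.x, state.y - ymin, ymax - state.y)
    if wall_clearance <= radius:
        return True
    obstacles = world.visible_obstacles() if visible_only else world.obstacles
    return any(o.distance_to(state.x, state.y) <= radius for o in obstacles)


# ------------------------------------------------------------ step motions

_SQ2 = math.sqrt(0.5)

#: Body-frame (forward, left) unit direction and distance per step command.
STEP_COMMANDS: dict[str, tuple[tuple[float, float], float] | float] = {
    "turn_left_30": math.radians(30.0),
    "turn_right_30": math.radians(-30.0),
    "forward_40": ((1.0, 0.0), 0.40),
    "forward_20": ((1.0, 0.0), 0.20),
    "backward_20": ((-1.0, 0.0), 0.20),
    "left_20": ((0.0, 1.0), 0.20),
    "right_20": ((0.0, -1.0), 0.20),
    "left_front_20": ((_SQ2, _SQ2), 0.20),
    "right_front_20": ((_SQ2, -_SQ2), 0.20),
    "left_rear_20": ((-_SQ2, _SQ2), 0.20),
    "right_rear_20": ((-_SQ2, -_SQ2), 0.20),
}

_SWEEP_STEP = 0.005  # m; collision scan granularity along a step


@dataclass
class StepResult:
    state: RobotState
    collided: bool
    requested: str
    moved: float  # distance actually covered


def execute_step_command(
    state: RobotState,
    command: str,
    world: WorldMap,
    radius: float = ROBOT_RADIUS,
) -> StepResult:
    """Execute one single-step motion command.

    Turns rotate the heading in place; translations move the commanded
    distance along the body-frame direction, stopping at the first point of
    contact if an obstacle or wall is in the way (the collision is
    reported, and the robot is left at the last contact-free position).
    """
    if command not in STEP_COMMANDS:
        raise ValueError(f"unknown step command {command!r}")
    spec = STEP_COMMANDS[command]
    if isinstance(spec, float):  # turn
        new = RobotState(state.x, state.y, state.heading + spec)
        return StepResult(new, False, command, 0.0)
    (bx, by), dist = spec
    c, s = math.cos(state.heading), math.sin(state.heading)
    dx, dy = c * bx - s * by, s * bx + c * by
    n_steps = max(int(math.ceil(dist / _SWEEP_STEP)), 1)
    moved = 0.0
    for k in range(1, n_steps + 1):
        d = min(k * _SWEEP_STEP, dist)
        candidate = RobotState(state.x + dx * d, state.y + dy * d, state.heading)
        if check_collision(candidate, world, radius):
            final = RobotState(state.x + dx * moved, state.y + dy * moved, state.heading)
            return StepResult(final, True, command, moved)
        moved = d
    final = RobotState(state.x + dx * dist, state.y + dy * dist, state.heading)
    return StepResult(final, False, command, dist)


# ---------------------------------------------------------------- planning


def _occupancy(
    world: WorldMap, radius: float, resolution: float
) -> tuple[np.ndarray, float, float]:
    """Blocked-cell grid against walls and radar-visible obstacles only."""
    xmin, ymin, xmax, ymax = world.bounds
    nx = int(round((xmax - xmin) / resolution)) + 1
    ny = int(round((ymax - ymin) / resolution)) + 1
    xs = xmin + np.arange(nx) * resolution
    ys = ymin + np.arange(ny) * resolution
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    wall = np.minimum.reduce([X - xmin, xmax - X, Y - ymin, ymax - Y]) <= radius
    blocked = wall
    for o in world.visible_obstacles():
        dx = np.maximum.reduce([o.x - X, np.zeros_like(X), X - (o.x + o.w)])
        dy = np.maximum.reduce([o.y - Y, np.zeros_like(Y), Y - (o.y + o.h)])
        blocked = blocked | (np.hypot(dx, dy) <= radius)
    return blocked, xmin, ymin


def _astar(blocked: np.ndarray, start: tuple[int, int], goal: tuple[int, int]):
    nx, ny = blocked.shape
    moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def h(c):
        dx, dy = abs(c[0] - goal[0]), abs(c[1] - goal[1])
        return math.hypot(dx, dy)

    open_heap = [(h(start), 0.0, start)]
    g = {start: 0.0}
    came: dict[tuple[int, int], tuple[int, int]] = {}
    closed: set[tuple[int, int]] = set()
    while open_heap:
        _, gc, cur = heapq.heappop(open_heap)
        if cur in closed:
            continue
        if cur == goal:
            path = [cur]
            while cur in came:
                cur = came[cur]
                path.append(cur)
            return path[::-1]
        closed.add(cur)
        for mx, my in moves:
            nxt = (cur[0] + mx, cur[1] + my)
            if not (0 <= nxt[0] < nx and 0 <= nxt[1] < ny) or blocked[nxt]:
                continue
            cost = gc + math.hypot(mx, my)
            if cost < g.get(nxt, math.inf):
                g[nxt] = cost
                came[nxt] = cur
                heapq.heappush(open_heap, (cost + h(nxt), cost, nxt))
    return None


def _nearest_free(blocked: np.ndarray, cell: tuple[int, int], max_r: int = 12):
    if not blocked[cell]:
        return cell
    nx, ny = blocked.shape
    for r in range(1, max_r + 1):
        best = None
        for i in range(max(0, cell[0] - r), min(nx, cell[0] + r + 1)):
            for j in range(max(0, cell[1] - r), min(ny, cell[1] + r + 1)):
                if not blocked[i, j]:
                    d = (i - cell[0]) ** 2 + (j - cell[1]) ** 2
                    if best is None or d < best[0]:
                        best = (d, (i, j))
        if best:
            return best[1]
    return None


def _line_free(blocked, xmin, ymin, resolution, p, q) -> bool:
    dist = math.hypot(q[0] - p[0], q[1] - p[1])
    n = max(int(math.ceil(dist / (resolution / 2))), 1)
    for k in range(n + 1):
        t = k / n
        x = p[0] + t * (q[0] - p[0])
        y = p[1] + t * (q[1] - p[1])
        i = int(round((x - xmin) / resolution))
        j = int(round((y - ymin) / resolution))
        i = min(max(i, 0), blocked.shape[0] - 1)
        j = min(max(j, 0), blocked.shape[1] - 1)
        if blocked[i, j]:
            return False
    return True


def plan_path(
    start: tuple[float, float],
    goal: tuple[float, float],
    world: WorldMap,
    radius: float = ROBOT_RADIUS,
    resolution: float = GRID_RESOLUTION,
) -> list[tuple[float, float]]:
    """Shortest grid path from start to goal against radar-visible obstacles.

    8-connected A* on a robot-radius-inflated occupancy grid, followed by
    greedy line-of-sight shortcutting, so an empty field yields a
    near-straight path. Radar-invisible obstacles are deliberately unknown
    to this planner. Raises :class:`UnreachableError` when no path exists.
    """
    xmin_b, ymin_b, xmax_b, ymax_b = world.bounds
    if not (xmin_b <= goal[0] <= xmax_b and ymin_b <= goal[1] <= ymax_b):
        raise ValueError("goal outside field bounds")
    blocked, xmin, ymin = _occupancy(world, radius, resolution)

    def to_cell(p):
        return (
            int(round((p[0] - xmin) / resolution)),
            int(round((p[1] - ymin) / resolution)),
        )

    def to_point(c):
        return (xmin + c[0] * resolution, ymin + c[1] * resolution)

    start_c = _nearest_free(blocked, to_cell(start))
    goal_c = _nearest_free(blocked, to_cell(goal))
    if start_c is None or goal_c is None:
        raise UnreachableError("start or goal has no free cell nearby")
    cells = _astar(blocked, start_c, goal_c)
    if cells is None:
        raise UnreachableError("no path on the planning grid")
    pts = [tuple(start)] + [to_point(c) for c in cells]
    # append the exact goal when the final hop is clear
    if _line_free(blocked, xmin, ymin, resolution, pts[-1], goal):
        pts.append(tuple(goal))
    # greedy line-of-sight smoothing
    smoothed = [pts[0]]
    i = 0
    while i < len(pts) - 1:
        j = len(pts) - 1
        while j > i + 1 and not _line_free(
            blocked, xmin, ymin, resolution, pts[i], pts[j]
        ):
            j -= 1
        smoothed.append(pts[j])
        i = j
    return smoothed


def navigate_to(
    state: RobotState,
    goal: tuple[float, float],
    world: WorldMap,
    radius: float = ROBOT_RADIUS,
    resolution: float = GRID_RESOLUTION,
) -> Trajectory:
    """Plan against radar-visible obstacles, then execute with full physics.

    Execution walks the planned polyline in ``resolution`` increments and
    checks the robot disc against *all* obstacles: an unseen low obstacle on
    the route stops the robot at contact and flags the collision — the event
    that calls for human intervention.
    """
    path = plan_path((state.x, state.y), goal, world, radius, resolution)
    points = [np.array([state.x, state.y])]
    for seg_start, seg_end in zip(path, path[1:]):
        p, q = np.array(seg_start), np.array(seg_end)
        seg_len = float(np.linalg.norm(q - p))
        if seg_len == 0:
            continue
        n = max(int(math.ceil(seg_len / resolution)), 1)
        for k in range(1, n + 1):
            pt = p + (q - p) * (k / n)
            if check_collision(RobotState(pt[0], pt[1]), world, radius):
                return Trajectory(
                    np.array(points),
                    reached=False,
                    collided=True,
                    collision_point=(float(pt[0]), float(pt[1])),
                )
            points.append(pt)
    pts = np.array(points)
    reached = float(np.linalg.norm(pts[-1] - np.asarray(goal))) <= GOAL_TOLERANCE
    return Trajectory(pts, reached=reached)
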