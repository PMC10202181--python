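"""Asynchronous closed-loop sessions: idle navigation <-> ERP control.

This module simulates the whole system end to end. The robot autonomously
navigates toward the destination (idle state) while a simulated subject
watches the video stream; when the upcoming path runs into a radar-invisible
obstacle, the subject clenches teeth — a synthetic EMG burst that the
1 s-window peak-to-peak switch detects — and the system enters the control
state. There the subject issues selections through simulated oddball trials
decoded by the trained FLDA:

* **CVT mode**: the current camera view is rendered from the world map, the
  CVT pipeline turns its road region into 11 numbered sub-goals, and the
  subject picks the sub-goal that clears the blocking obstacle while best
  approaching the destination. The robot navigates there autonomously.
* **SS mode**: the subject steers around the obstacle one 20 cm step (or 30°
  turn) at a time using the arrow commands.

An Exit selection (item 12) returns to idle. The state machine honors the
asynchronous contract: EMG monitoring runs only in idle, ERP decoding only
in control, and every control entry is caused by a logged EMG trigger.

A simulated clock accrues: navigation at a constant speed, 1 s EMG windows,
and ``n_repetitions * 0.98 s + t`` per ERP selection, so SS and CVT session
durations can be compared qualitatively.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import emg, erp, road, robot, simulate

__all__ = [
    "SessionConfig",
    "SessionLog",
    "SessionFailed",
    "SubjectPolicy",
    "simulated_subject_policy",
    "render_scene",
    "run_session",
]

ROAD_COLOR = (110, 110, 110)
BACKGROUND_COLOR = (40, 150, 60)


class SessionFailed(RuntimeError):
    """The session hit an iteration cap; the partial log is attached."""

    def __init__(self, message: str, log: "SessionLog"):
        super().__init__(message)
        self.log = log


@dataclass
class SessionConfig:
    """Study-condition knobs for one simulated session.

    The subject model is an oracle parametrized by the ERP SNR
    (``erp_amplitude`` vs ``erp_noise_sd``) driving decode accuracy;
    defaults emulate a reliably decodable subject with a clean EMG switch.
    """

    mode: str = "CVT"  # "CVT" or "SS"
    n_repetitions: int = 5
    n_subgoals: int = 11
    seed: int = 0
    erp_amplitude: float = 5.0
    erp_noise_sd: float = 2.0
    speed: float = 0.2  # m/s autonomous travel speed
    lookahead: float = 0.7  # m of upcoming path the subject watches
    exit_horizon: float = 2.5  # m of planned path checked before exiting
    t_inter_trial: float = 3.0
    image_size: tuple[int, int] = (160, 120)
    max_depth: float = 3.5  # camera depth range cutoff, m
    robot_radius: float = robot.ROBOT_RADIUS
    max_selections: int = 40
    max_control_visits: int = 8
    n_training_repetitions: int = 10

    def __post_init__(self) -> None:
        self.mode = self.mode.upper()
        if self.mode not in ("CVT", "SS"):
            raise ValueError("mode must be 'CVT' or 'SS'")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class SessionLog:
    """Timestamped record of one session.

    ``events`` is a list of dicts, each with a simulated-clock time ``t``
    and a ``type`` among ``emg_trigger``, ``state``, ``selection``,
    ``command``, ``subgoal_arrival``, ``collision``, ``done``.
    ``trajectory`` rows are ``(t, x, y, heading)``.
    """

    mode: str
    events: list[dict] = field(default_factory=list)
    trajectory: list[tuple[float, float, float, float]] = field(default_factory=list)
    reached: bool = False
    duration: float = 0.0

    @property
    def n_selections(self) -> int:
        return sum(1 for e in self.events if e["type"] == "selection")

    @property
    def n_collisions(self) -> int:
        return sum(1 for e in self.events if e["type"] == "collision")

    @property
    def n_control_visits(self) -> int:
        return sum(
            1
            for e in self.events
            if e["type"] == "state" and e["state"] == "control"
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "mode": self.mode,
            "reached": self.reached,
            "duration": self.duration,
            "events": self.events,
            "trajectory": [list(row) for row in self.trajectory],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionLog":
        doc = json.loads(Path(path).read_text())
        return cls(
            mode=doc["mode"],
            events=doc["events"],
            trajectory=[tuple(r) for r in doc["trajectory"]],
            reached=doc["reached"],
            duration=doc["duration"],
        )


# ------------------------------------------------------------- rendering


def render_scene(
    world: robot.WorldMap,
    pose: robot.RobotState,
    camera: road.CameraGeometry,
    max_depth: float = 3.5,
    road_color: tuple[int, int, int] = ROAD_COLOR,
    background_color: tuple[int, int, int] = BACKGROUND_COLOR,
) -> np.ndarray:
    """Render the ground plane seen by the robot's camera from the map.

    Every pixel's ray is intersected with the ground; the pixel is road-
    colored when that point lies inside the field, outside every obstacle
    footprint, and within the camera's depth range. This perspective
    projection of the map closes the simulation loop without real images.
    """
    grid = road.ground_plane_grid(camera)  # (H, W, 2) robot frame
    wpts = road.robot_to_world(grid, pose)
    X, Y = wpts[..., 0], wpts[..., 1]
    xmin, ymin, xmax, ymax = world.bounds
    is_road = (
        (X >= xmin) & (X <= xmax) & (Y >= ymin) & (Y <= ymax)
        & (grid[..., 0] <= max_depth)
    )
    for o in world.obstacles:
        is_road &= ~((X >= o.x) & (X <= o.x + o.w) & (Y >= o.y) & (Y <= o.y + o.h))
    img = np.empty(is_road.shape + (3,), dtype=np.uint8)
    img[:] = background_color
    img[is_road] = road_color
    return img


# ---------------------------------------------------------------- policy

_ITEM_OF_COMMAND = {v: k for k, v in erp.SS_COMMANDS.items()}


class SubjectPolicy:
    """Deterministic oracle standing in for the human agent.

    The subject clenches when the upcoming planned path comes within
    clench-margin of a radar-invisible obstacle; in CVT mode picks the
    sub-goal that clears the blocking obstacle with the straight approach
    collision-free and the least remaining distance to the destination; in
    SS mode steps greedily toward a waypoint just past the obstacle; exits
    when the next stretch of planned path is clear.
    """

    def __init__(
        self,
        world: robot.WorldMap,
        radius: float = robot.ROBOT_RADIUS,
        lookahead: float = 0.7,
        exit_horizon: float = 2.5,
        clench_margin: float = 0.1,
    ):
        self.world = world
        self.radius = radius
        self.lookahead = lookahead
        self.exit_horizon = exit_horizon
        self.clench_margin = clench_margin
        self._known: robot.WorldMap | None = None

    # -- obstacle awareness

    def blocking_obstacle(
        self, points: np.ndarray, horizon: float
    ) -> robot.Obstacle | None:
        """First radar-invisible obstacle the path meets within ``horizon``
        meters of arclength, or None."""
        inflation = self.radius + self.clench_margin
        travelled = 0.0
        prev = None
        for pt in np.atleast_2d(points):
            if prev is not None:
                travelled += float(np.linalg.norm(pt - prev))
            prev = pt
            if travelled > horizon:
                break
            for o in self.world.invisible_obstacles():
                if o.distance_to(pt[0], pt[1]) <= inflation:
                    return o
        return None

    def wants_clench(self, upcoming: np.ndarray) -> bool:
        return self.blocking_obstacle(upcoming, self.lookahead) is not None

    def wants_exit(self, pos: tuple[float, float]) -> bool:
        """Exit when the next ``exit_horizon`` meters toward the destination
        are clear of invisible obstacles."""
        try:
            path = robot.plan_path(pos, self.world.destination, self.world, self.radius)
        except robot.UnreachableError:
            return False
        pts = _densify(path, 0.05)
        return self.blocking_obstacle(pts, self.exit_horizon) is None

    # -- CVT choice

    def _segment_clear(self, p, q) -> bool:
        p, q = np.asarray(p, float), np.asarray(q, float)
        n = max(int(math.ceil(np.linalg.norm(q - p) / 0.025)), 1)
        for k in range(n + 1):
            pt = p + (q - p) * (k / n)
            if robot.check_collision(
                robot.RobotState(pt[0], pt[1]), self.world, self.radius + 0.02
            ):
                return False
        return True

    def _known_world(self) -> robot.WorldMap:
        """The world as the *subject* knows it: every obstacle visible.

        The human watches the video stream and sees the low obstacles the
        radar cannot; their mental route planning accounts for all of them.
        """
        if self._known is None:
            self._known = robot.WorldMap(
                bounds=self.world.bounds,
                obstacles=[
                    robot.Obstacle(o.x, o.y, o.w, o.h, radar_visible=True)
                    for o in self.world.obstacles
                ],
                start=self.world.start,
                destination=self.world.destination,
            )
        return self._known

    def _remaining(self, pos: tuple[float, float]) -> float:
        """Path length to the destination avoiding *all* obstacles."""
        path = robot.plan_path(
            pos, self.world.destination, self._known_world(), self.radius + 0.02
        )
        pts = np.asarray(path)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def mental_direction(self, pos: tuple[float, float]) -> float | None:
        """Heading along the subject's intended route around the obstacles.

        The subject aims the (omnidirectional) robot's camera where they
        mean to go next: the initial direction of the shortest path to the
        destination in their mental map, taken ~0.5 m ahead.
        """
        try:
            path = robot.plan_path(
                pos, self.world.destination, self._known_world(), self.radius + 0.02
            )
        except robot.UnreachableError:
            return None
        pts = _densify(path, 0.05)
        k = min(10, len(pts) - 1)  # ~0.5 m along
        if k < 1:
            return None
        dx, dy = pts[k][0] - pos[0], pts[k][1] - pos[1]
        if math.hypot(dx, dy) < 1e-9:
            return None
        return math.atan2(dy, dx)

    def choose_subgoal(
        self,
        pos: tuple[float, float],
        subgoals: list[road.SubGoal],
        blocking: robot.Obstacle | None = None,
    ) -> road.SubGoal | None:
        """Pick the sub-goal minimizing the remaining distance to the
        destination, subject to clearing the obstacles.

        "Distance to destination" is path length in the subject's mental map
        (all obstacles known), so a sub-goal hiding behind the blocking
        obstacle is costed with its detour. The straight approach from the
        current position must be collision-free — that is how the robot will
        drive to it — and the hop must make real progress.
        """
        candidates: list[tuple[float, road.SubGoal]] = []
        try:
            here = self._remaining(pos)
        except robot.UnreachableError:
            return None
        for sg in subgoals:
            w = np.asarray(sg.world)
            hop = float(np.linalg.norm(w - np.asarray(pos)))
            if hop < 0.25:  # not worth a selection
                continue
            if robot.check_collision(
                robot.RobotState(w[0], w[1]), self.world, self.radius + 0.02
            ):
                continue
            # keep maneuvering room: a goal hugging a hidden obstacle makes
            # the *next* straight approach infeasible
            if any(
                o.distance_to(w[0], w[1]) <= self.radius + 0.12
                for o in self.world.invisible_obstacles()
            ):
                continue
            if not self._segment_clear(pos, w):
                continue
            try:
                remaining = self._remaining((w[0], w[1]))
            except robot.UnreachableError:
                continue
            if remaining < here - 0.2:  # meaningful progress
                candidates.append((remaining, sg))
        if not candidates:
            return None
        return min(candidates, key=lambda c: (c[0], c[1].number))[1]

    # -- SS choice

    def ss_waypoint(
        self, pos: tuple[float, float], blocking: robot.Obstacle
    ) -> tuple[float, float]:
        """A point just past the blocking obstacle on its better side."""
        dest = np.asarray(self.world.destination)
        o = blocking
        ahead = o.x + o.w + self.radius + 0.1
        behind = o.x - self.radius - 0.1
        wx = ahead if dest[0] >= o.center[0] else behind
        candidates = [
            (wx, o.y - (self.radius + 0.15)),
            (wx, o.y + o.h + self.radius + 0.15),
        ]
        valid = [
            c
            for c in candidates
            if not robot.check_collision(
                robot.RobotState(c[0], c[1]), self.world, self.radius + 0.02
            )
        ]
        if not valid:
            valid = candidates
        return min(valid, key=lambda c: float(np.linalg.norm(np.asarray(c) - dest)))

    def choose_step_item(
        self, state: robot.RobotState, waypoint: tuple[float, float]
    ) -> int:
        """The arrow command (as its interface item 1..11) whose single step
        brings the robot closest to the waypoint without a collision."""
        best_item, best_cost = None, math.inf
        for cmd, spec in robot.STEP_COMMANDS.items():
            if isinstance(spec, float):
                continue  # turns do not translate; the oracle never needs them
            res = robot.execute_step_command(state, cmd, self.world, self.radius)
            if res.collided:
                continue
            end = np.array([res.state.x, res.state.y])
            near_invisible = any(
                o.distance_to(end[0], end[1]) <= self.radius + 0.02
                for o in self.world.invisible_obstacles()
            )
            if near_invisible:
                continue
            cost = float(np.linalg.norm(end - np.asarray(waypoint)))
            if cost < best_cost:
                best_cost, best_item = cost, _ITEM_OF_COMMAND[cmd]
        if best_item is None:
            best_item = _ITEM_OF_COMMAND["backward_20"]
        return best_item


def simulated_subject_policy(
    state: robot.RobotState,
    world: robot.WorldMap,
    mode: str,
    subgoals: list[road.SubGoal] | None = None,
    lookahead: float = 0.7,
) -> dict:
    """One-shot oracle query: should the subject clench, and which item
    would they select right now?

    Convenience wrapper around :class:`SubjectPolicy` for inspection and
    tests; :func:`run_session` drives the same policy incrementally.
    """
    policy = SubjectPolicy(world, lookahead=lookahead)
    try:
        path = robot.plan_path(
            (state.x, state.y), world.destination, world
        )
        pts = _densify(path, 0.05)
    except robot.UnreachableError:
        pts = np.array([[state.x, state.y]])
    blocking = policy.blocking_obstacle(pts, lookahead)
    intent: dict = {"clench": blocking is not None, "item": None}
    if blocking is None:
        return intent
    if mode.upper() == "CVT" and subgoals:
        choice = policy.choose_subgoal((state.x, state.y), subgoals, blocking)
        intent["item"] = None if choice is None else choice.number
    elif mode.upper() == "SS":
        wp = policy.ss_waypoint((state.x, state.y), blocking)
        intent["item"] = policy.choose_step_item(state, wp)
    return intent


# ----------------------------------------------------------------- session


def _densify(path: list[tuple[float, float]], step: float) -> np.ndarray:
    pts = [np.asarray(path[0], float)]
    for p, q in zip(path, path[1:]):
        p, q = np.asarray(p, float), np.asarray(q, float)
        seg = float(np.linalg.norm(q - p))
        if seg == 0:
            continue
        n = max(int(math.ceil(seg / step)), 1)
        pts.extend(p + (q - p) * (k / n) for k in range(1, n + 1))
    return np.array(pts)


class _Session:
    """Internal driver holding the clock, log, and trained components."""

    def __init__(self, world: robot.WorldMap, config: SessionConfig):
        self.world = world
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.clock = 0.0
        self.log = SessionLog(mode=config.mode)
        self.state = robot.RobotState(*world.start)
        self.policy = SubjectPolicy(
            world,
            radius=config.robot_radius,
            lookahead=config.lookahead,
            exit_horizon=config.exit_horizon,
        )
        self.camera = road.CameraGeometry(image_size=config.image_size)
        self.sim_cfg = simulate.ErpSimConfig(
            erp_amplitude=config.erp_amplitude, noise_sd=config.erp_noise_sd
        )
        self.threshold = self._calibrate_emg()
        self.model = self._train_decoder()

    def _seed(self) -> int:
        return int(self.rng.integers(2**31))

    # -- offline setup (not on the session clock)

    def _calibrate_emg(self) -> emg.ClenchThreshold:
        rest_cfg = simulate.EmgSimConfig(seed=self._seed())
        rest, _ = simulate.generate_emg_trace(rest_cfg, 4.0)
        clench_cfg = simulate.EmgSimConfig(
            burst_intervals=[(0.0, 4.0)], seed=self._seed()
        )
        clench, _ = simulate.generate_emg_trace(clench_cfg, 4.0)
        P = 250
        rest_w = [rest.data[i : i + P, 0] for i in range(0, 1000, P)]
        clench_w = [clench.data[i : i + P, 0] for i in range(0, 1000, P)]
        return emg.calibrate_threshold(rest_w, clench_w)

    def _train_decoder(self) -> erp.FldaModel:
        trials = []
        for item in range(1, erp.N_ITEMS + 1):
            sched = erp.build_schedule(
                self.config.n_training_repetitions, seed=self._seed()
            )
            cfg = replace(self.sim_cfg, seed=self._seed())
            trials.append((simulate.generate_erp_recording(cfg, sched, item), sched, item))
        return erp.train_decoder(trials)

    # -- logging helpers

    def _event(self, type_: str, **extra) -> None:
        self.log.events.append({"t": round(self.clock, 3), "type": type_, **extra})

    def _track(self) -> None:
        self.log.trajectory.append(
            (round(self.clock, 3), self.state.x, self.state.y, self.state.heading)
        )

    def _face(self, target: tuple[float, float]) -> None:
        dx, dy = target[0] - self.state.x, target[1] - self.state.y
        if math.hypot(dx, dy) > 1e-9:
            self.state = robot.RobotState(
                self.state.x, self.state.y, math.atan2(dy, dx)
            )

    # -- simulated subject I/O

    def _emg_trigger(self) -> None:
        cfg = simulate.EmgSimConfig(burst_intervals=[(0.6, 1.4)], seed=self._seed())
        trace, _ = simulate.generate_emg_trace(cfg, 2.0)
        t = emg.monitor_stream(trace, self.threshold)
        if t is None:  # clean switch: should not happen with the defaults
            t = trace.duration
        self.clock += t
        self._event("emg_trigger")

    def _erp_select(self, target_item: int) -> int:
        if self.log.n_selections >= self.config.max_selections:
            raise SessionFailed("selection cap exceeded", self.log)
        sched = erp.build_schedule(self.config.n_repetitions, seed=self._seed())
        cfg = replace(self.sim_cfg, seed=self._seed())
        rec = simulate.generate_erp_recording(cfg, sched, target_item)
        decoded = erp.classify_target(rec, sched, self.model)
        self.clock += self.config.n_repetitions * 0.98 + self.config.t_inter_trial
        self._event(
            "selection", target=target_item, decoded=decoded, mode=self.config.mode
        )
        return decoded

    # -- movement

    def _follow(self, traj: robot.Trajectory) -> None:
        """Advance clock/trajectory along an executed autonomous path."""
        pts = traj.points
        for prev, pt in zip(pts, pts[1:]):
            self.clock += float(np.linalg.norm(pt - prev)) / self.config.speed
            self.state = robot.RobotState(pt[0], pt[1], self.state.heading)
            self._track()
        if traj.collided and traj.collision_point is not None:
            self._event(
                "collision", x=traj.collision_point[0], y=traj.collision_point[1]
            )

    def _at_destination(self) -> bool:
        return (
            float(np.linalg.norm(self.state.position - np.asarray(self.world.destination)))
            <= robot.GOAL_TOLERANCE
        )

    # -- idle phase

    def _idle_phase(self) -> str:
        """Autonomously head for the destination while monitoring EMG.

        Returns ``"arrived"`` or ``"clench"`` (robot stopped, switch fired).
        """
        path = robot.plan_path(
            (self.state.x, self.state.y),
            self.world.destination,
            self.world,
            self.config.robot_radius,
        )
        pts = _densify(path, 0.05)
        for i, pt in enumerate(pts):
            if self.policy.wants_clench(pts[i:]):
                self._face(tuple(self.world.destination))
                self._emg_trigger()
                self._event("state", state="control")
                return "clench"
            if i > 0:
                step = float(np.linalg.norm(pt - pts[i - 1]))
                candidate = robot.RobotState(pt[0], pt[1], self.state.heading)
                if robot.check_collision(candidate, self.world, self.config.robot_radius):
                    self._event("collision", x=float(pt[0]), y=float(pt[1]))
                    self._emg_trigger()
                    self._event("state", state="control")
                    return "clench"
                self.clock += step / self.config.speed
                dx, dy = pt[0] - pts[i - 1][0], pt[1] - pts[i - 1][1]
                heading = math.atan2(dy, dx) if (dx or dy) else self.state.heading
                self.state = robot.RobotState(pt[0], pt[1], heading)
                self._track()
        return "arrived"

    # -- control phases

    def _pick_subgoal_with_refresh(self, blocking):
        """Render the view and pick a sub-goal, letting the display refresh.

        The road-selection system regenerates its sub-goal layout
        continuously; the simulated subject only commits to a selection once
        some goal offers substantial progress (>= 1.2 m off the remaining
        route), waiting through a few refresh cycles (0.5 s each on
        the clock) for a better layout before settling for the best on
        offer.
        """
        pos = (self.state.x, self.state.y)
        try:
            here = self.policy._remaining(pos)
        except robot.UnreachableError:
            here = None
        best: tuple[float, road.SubGoal, list[road.SubGoal]] | None = None
        for attempt in range(6):
            image = render_scene(
                self.world, self.state, self.camera, self.config.max_depth
            )
            subgoals = road.generate_subgoals(
                image,
                self.camera,
                self.state,
                road.CvtConfig(self.config.n_subgoals, seed=self._seed()),
            )
            choice = self.policy.choose_subgoal(pos, subgoals, blocking)
            if choice is not None:
                rem = self.policy._remaining(choice.world)
                if best is None or rem < best[0]:
                    best = (rem, choice, subgoals)
                if here is None or rem <= here - 1.2:
                    break
            self.clock += 0.5  # one sub-goal refresh cycle
        if best is None:
            return None, []
        return best[1], best[2]

    def _control_cvt(self) -> None:
        while True:
            path = robot.plan_path(
                (self.state.x, self.state.y), self.world.destination, self.world
            )
            blocking = self.policy.blocking_obstacle(
                _densify(path, 0.05), self.config.lookahead + 0.3
            )
            heading = self.policy.mental_direction((self.state.x, self.state.y))
            if heading is not None:
                self.state = robot.RobotState(self.state.x, self.state.y, heading)
            choice, subgoals = self._pick_subgoal_with_refresh(blocking)
            if choice is None:  # nothing admissible in view: give control back
                decoded = self._erp_select(erp.N_ITEMS)
            else:
                decoded = self._erp_select(choice.number)
            command = erp.item_to_command(decoded, "CVT")
            self._event("command", command=str(command))
            if command == "exit":
                self._event("state", state="idle")
                return
            goal = subgoals[int(command) - 1].world
            traj = robot.navigate_to(
                self.state, goal, self.world, self.config.robot_radius
            )
            self._face(goal)
            self._follow(traj)
            self._event("subgoal_arrival", number=int(command))
            self._face(tuple(self.world.destination))
            if self.policy.wants_exit((self.state.x, self.state.y)):
                decoded = self._erp_select(erp.N_ITEMS)
                command = erp.item_to_command(decoded, "CVT")
                self._event("command", command=str(command))
                if command == "exit":
                    self._event("state", state="idle")
                    return
                # decode slip: treat as one more sub-goal selection
                goal = subgoals[int(command) - 1].world
                traj = robot.navigate_to(
                    self.state, goal, self.world, self.config.robot_radius
                )
                self._follow(traj)
                self._event("subgoal_arrival", number=int(command))

    def _control_ss(self) -> None:
        stall = 0
        while True:
            path = robot.plan_path(
                (self.state.x, self.state.y), self.world.destination, self.world
            )
            blocking = self.policy.blocking_obstacle(
                _densify(path, 0.05), self.config.lookahead + 0.3
            )
            if blocking is None:
                decoded = self._erp_select(erp.N_ITEMS)
                command = erp.item_to_command(decoded, "SS")
                self._event("command", command=str(command))
                if command == "exit":
                    self._event("state", state="idle")
                    return
                self._execute_ss(command)
                continue
            waypoint = self.policy.ss_waypoint((self.state.x, self.state.y), blocking)
            while (
                float(np.linalg.norm(self.state.position - np.asarray(waypoint)))
                > 0.15
            ):
                before = float(
                    np.linalg.norm(self.state.position - np.asarray(waypoint))
                )
                item = self.policy.choose_step_item(self.state, waypoint)
                decoded = self._erp_select(item)
                command = erp.item_to_command(decoded, "SS")
                self._event("command", command=str(command))
                if command == "exit":  # decode slip
                    self._event("state", state="idle")
                    return
                self._execute_ss(command)
                after = float(
                    np.linalg.norm(self.state.position - np.asarray(waypoint))
                )
                stall = stall + 1 if after >= before - 0.01 else 0
                if stall >= 3:
                    break  # waypoint unreachable by steps; re-assess blocking

    def _execute_ss(self, command: str) -> None:
        res = robot.execute_step_command(
            self.state, command, self.world, self.config.robot_radius
        )
        self.state = res.state
        self.clock += res.moved / self.config.speed
        self._track()
        if res.collided:
            self._event("collision", x=self.state.x, y=self.state.y)

    # -- main loop

    def run(self) -> SessionLog:
        self._face(tuple(self.world.destination))
        self._track()
        visits = 0
        while True:
            outcome = self._idle_phase()
            if outcome == "arrived":
                break
            visits += 1
            if visits > self.config.max_control_visits:
                raise SessionFailed("control-visit cap exceeded", self.log)
            if self.config.mode == "CVT":
                self._control_cvt()
            else:
                self._control_ss()
        self.log.reached = self._at_destination()
        self.log.duration = self.clock
        self._event("done", reached=self.log.reached)
        return self.log


def run_session(world: robot.WorldMap, config: SessionConfig) -> SessionLog:
    """Run one full simulated navigation session and return its log.

    Calibrates the EMG switch and trains the FLDA decoder on synthetic data
    (off the session clock, as the offline calibration was), then loops
    idle navigation and control-state selections until the destination is
    reached. Raises :class:`SessionFailed` (log attached) if an iteration
    cap is exceeded.
    """
    return _Session(world, config).run()
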