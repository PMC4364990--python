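"""Torus geometry, perception, and the event-driven activation queue.

The arena is a continuous 2-D torus.  Coordinates are metres; one
simulated time unit is one minute.  Bearing convention: 0 degrees points
east (+x), angles increase counterclockwise, headings live in [0, 360).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple, Sequence

__all__ = [
    "WorldConfig",
    "Pose",
    "Activation",
    "EventQueue",
    "KIND_PRIORITY",
    "torus_delta",
    "torus_distance",
    "bearing",
    "in_view",
    "candidate_partners",
    "schedule_next",
]


@dataclass(frozen=True)
class WorldConfig:
    """Arena size and the model's perception / interaction radii."""

    width: float = 300.0
    height: float = 300.0
    interact_dist: float = 1.0  # grooming / leaving / attacking range
    pers_dist: float = 5.0  # signalling / avoiding range
    near_dist: float = 20.0  # neighbourhood radius (GROUP_DIST)
    max_dist: float = 50.0  # maximum perceivable distance
    far_dist: float = 100.0  # beyond this, cohesion is considered lost
    min_others: int = 3
    view_angle: float = 120.0  # default view angle, degrees
    max_angle: float = 360.0  # widened view while scanning
    max_partners: int = 10

    def __post_init__(self) -> None:
        if not (
            0
            < self.interact_dist
            < self.pers_dist
            < self.near_dist
            < self.max_dist
            < self.far_dist
        ):
            raise ValueError(
                "distance thresholds must satisfy "
                "0 < interact < pers < near < max < far"
            )
        if not (0 < self.view_angle <= self.max_angle):
            raise ValueError("view_angle must lie in (0, max_angle]")
        if self.max_angle != 360.0:
            raise ValueError("max_angle must be 360 degrees")
        if self.min_others < 1 or self.max_partners < 1:
            raise ValueError("min_others and max_partners must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")

    @property
    def group_dist(self) -> float:
        """Alias: the radius used by the grouping rule."""
        return self.near_dist


@dataclass
class Pose:
    """Position on the torus plus a heading in degrees, [0, 360)."""

    x: float
    y: float
    heading: float = 0.0

    def __post_init__(self) -> None:
        self.heading = self.heading % 360.0


def torus_delta(
    ax: float, ay: float, bx: float, by: float, width: float, height: float
) -> tuple[float, float]:
    """Shortest displacement from a to b on the torus (signed components)."""
    dx = (bx - ax) % width
    if dx > width / 2.0:
        dx -= width
    dy = (by - ay) % height
    if dy > height / 2.0:
        dy -= height
    return dx, dy


def torus_distance(a: Pose, b: Pose, w: WorldConfig) -> float:
    """Shortest-path (wrap-around) Euclidean distance between two poses."""
    dx, dy = torus_delta(a.x, a.y, b.x, b.y, w.width, w.height)
    return math.hypot(dx, dy)


def bearing(ego: Pose, target: Pose, w: WorldConfig) -> float:
    """Torus-shortest bearing from ego to target, degrees in [0, 360)."""
    dx, dy = torus_delta(ego.x, ego.y, target.x, target.y, w.width, w.height)
    return math.degrees(math.atan2(dy, dx)) % 360.0


def in_view(ego: Pose, view_angle: float, target: Pose, w: WorldConfig) -> bool:
    """True iff target lies within ego's view cone of ``view_angle`` degrees.

    A target coincident with ego is trivially visible.  With a 360-degree
    view everything is visible.
    """
    if not (0.0 < view_angle <= 360.0):
        raise ValueError("view_angle must lie in (0, 360]")
    if view_angle == 360.0:
        return True
    dx, dy = torus_delta(ego.x, ego.y, target.x, target.y, w.width, w.height)
    if dx == 0.0 and dy == 0.0:
        return True
    off = (math.degrees(math.atan2(dy, dx)) - ego.heading) % 360.0
    if off > 180.0:
        off = 360.0 - off
    return off <= view_angle / 2.0


def candidate_partners(
    ego_id: int,
    poses: Mapping[int, Pose] | Sequence[Pose],
    w: WorldConfig,
    view_angle: float | None = None,
) -> list[int]:
    """The up-to-``max_partners`` nearest visible others, sorted by distance.

    Only agents within ``max_dist`` and inside ego's view cone qualify.
    Distance ties are broken by ascending agent id.
    """
    if isinstance(poses, Mapping):
        items: Iterator[tuple[int, Pose]] = iter(poses.items())
        ego = poses[ego_id]
    else:
        items = enumerate(poses)
        ego = poses[ego_id]
    va = w.view_angle if view_angle is None else view_angle
    found: list[tuple[float, int]] = []
    for aid, pose in items:
        if aid == ego_id:
            continue
        d = torus_distance(ego, pose, w)
        if d <= w.max_dist and in_view(ego, va, pose, w):
            found.append((d, aid))
    found.sort()
    return [aid for _, aid in found[: w.max_partners]]


# --- activation queue -------------------------------------------------------

#: Lower priority number pops first among same-time events.
KIND_PRIORITY: dict[str, int] = {
    "interrupt-attack": 0,
    "interrupt-signal": 0,
    "interrupt-fight-nearby": 0,
    "movement-substep": 1,
    "scheduled": 2,
    "proximity-notify": 3,
    "sample": 4,
}


class Activation(NamedTuple):
    """One entry in the activation queue.

    Ordering: time, then kind priority (interrupts first), then agent id,
    then insertion order — fully deterministic under a fixed seed.  The
    unique ``seq`` guarantees comparisons never reach the later fields.
    """

    time: float
    priority: int
    agent_id: int
    seq: int = 0
    kind: str = "scheduled"
    epoch: int = 0
    payload: object = None

    @staticmethod
    def make(
        time: float,
        agent_id: int,
        kind: str = "scheduled",
        seq: int = 0,
        epoch: int = 0,
        payload: object = None,
    ) -> "Activation":
        return Activation(
            time=time,
            priority=KIND_PRIORITY[kind],
            agent_id=agent_id,
            seq=seq,
            kind=kind,
            epoch=epoch,
            payload=payload,
        )


class EventQueue:
    """Min-heap of :class:`Activation` with deterministic tie-breaking."""

    def __init__(self) -> None:
        self._heap: list[Activation] = []
        self._seq = 0
        self.last_popped: float = -math.inf

    def __len__(self) -> int:
        return len(self._heap)

    def push(
        self,
        time: float,
        agent_id: int,
        kind: str = "scheduled",
        epoch: int = 0,
        payload: object = None,
    ) -> Activation:
        self._seq += 1
        act = Activation.make(
            time, agent_id, kind=kind, seq=self._seq, epoch=epoch, payload=payload
        )
        heapq.heappush(self._heap, act)
        return act

    def pop_next(self) -> Activation:
        """Remove and return the earliest activation.

        Raises IndexError on an empty queue (end of simulation).
        """
        act = heapq.heappop(self._heap)
        self.last_popped = act.time
        return act

    def peek_time(self) -> float:
        return self._heap[0].time


def schedule_next(
    agent_id: int,
    now: float,
    rng,
    mean: float = 1.0,
    sd: float = 0.05,
    floor: float = 0.01,
) -> Activation:
    """Next routine activation: now + delta, delta ~ N(mean, sd), delta >= floor."""
    delta = rng.normal(mean, sd)
    if delta < floor:
        delta = floor
    return Activation.make(now + delta, agent_id, kind="scheduled")
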