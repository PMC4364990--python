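"""Event-driven simulation core.

Each agent owns at most one pending routine activation (a scheduled
selection, a bout-end wake-up, or a movement substep); interrupt
activations (received attacks, aggressive signals, fights nearby) jump
the queue.  Stale routine events are invalidated with a per-agent epoch
counter, which keeps replay fully deterministic under a fixed seed.

Random numbers are drawn from a single generator in event order.  LIKE
bookkeeping never consumes randomness and LIKE values are not read at
all when selectivity is zero, so the dynamic and fixed attitude variants
draw identical random streams at lps = 0 and produce bit-identical
event logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .affect import (
    AttitudeStore,
    EmotionalState,
    apply_event,
    relax_toward_limit,
    scan_probability,
    tick_satisfaction,
)
from .behavior import (
    BoutState,
    action_probabilities,
    execute_movement,
    resolve_attack,
)
from .config import RunConfig
from .observation import BehaviorLog, sample_proximity
from .world import EventQueue, Pose, torus_delta

__all__ = ["Agent", "Simulation", "LOGGED_BEHAVIORS"]

#: directed behaviours accumulated into rate matrices
LOGGED_BEHAVIORS = (
    "groom",
    "affiliative_signal",
    "approach",
    "leave",
    "submissive_signal",
    "avoid",
    "attack",
    "aggressive_signal",
)


@dataclass
class Agent:
    id: int
    dom: float
    pose: Pose
    state: EmotionalState = field(default_factory=EmotionalState)
    last_settle: float = 0.0
    bout: BoutState | None = None
    epoch: int = 0


class Simulation:
    """One configured run of the group simulator."""

    def __init__(self, cfg: RunConfig, seed: int | None = None) -> None:
        self.cfg = cfg
        self.w = cfg.world
        self.p = cfg.affect
        self.sp = cfg.selectivity
        self.eng = cfg.engine
        self.table = cfg.salience
        self.rng = np.random.default_rng(cfg.seed if seed is None else seed)
        self.queue = EventQueue()
        self.log = BehaviorLog()
        self.now = 0.0
        self.doms = np.asarray(cfg.dom_vector, dtype=float)
        self.attitudes = AttitudeStore(
            self.doms,
            self.p,
            dynamic=(cfg.variant == "dynamic"),
            l0=cfg.like_l0,
            ls=cfg.like_ls,
        )
        self.record_start = cfg.record_start
        self.horizon = cfg.horizon
        self.prox_samples: list[np.ndarray] = []
        self.like_samples: list[np.ndarray] = []
        self.emotion_samples: list[np.ndarray] = []  # (arousal, anxiety, sat) means
        self._init_agents()
        self._init_queue()

    # -- initialization ------------------------------------------------------

    def _init_agents(self) -> None:
        cfg, w, rng = self.cfg, self.w, self.rng
        cx, cy = w.width / 2.0, w.height / 2.0
        radius = 25.0  # agents start inside a 50 m diameter disc
        agents = []
        for i in range(cfg.n_agents):
            r = radius * math.sqrt(rng.random())
            theta = rng.random() * 2.0 * math.pi
            heading = rng.uniform(1.0, 360.0)
            pose = Pose(
                (cx + r * math.cos(theta)) % w.width,
                (cy + r * math.sin(theta)) % w.height,
                heading,
            )
            st = EmotionalState(
                arousal=self.p.def_ar_limit,
                anxiety=0.0,
                satisfaction=0.0,
                arousal_limit=self.p.def_ar_limit,
                anxiety_limit=self.p.anxiety_drift_limit,
                satisfaction_limit=0.0,
            )
            agents.append(Agent(id=i, dom=self.doms[i], pose=pose, state=st))
        self.agents = agents

    def _init_queue(self) -> None:
        for ag in self.agents:
            delta = self.rng.normal(self.eng.schedule_mean, self.eng.schedule_sd)
            if delta < self.eng.schedule_floor:
                delta = self.eng.schedule_floor
            self._schedule(ag, delta, "scheduled")
        cal = self.cfg.calendar
        for k in range(self.cfg.n_intervals):
            self.queue.push(
                self.record_start + k * cal.sample_interval, -1, kind="sample"
            )

    # -- plumbing ------------------------------------------------------------

    def _schedule(self, ag: Agent, time: float, kind: str) -> None:
        """Replace the agent's pending routine activation."""
        ag.epoch += 1
        self.queue.push(time, ag.id, kind=kind, epoch=ag.epoch)

    def _schedule_routine(self, ag: Agent, now: float) -> None:
        delta = self.rng.normal(self.eng.schedule_mean, self.eng.schedule_sd)
        if delta < self.eng.schedule_floor:
            delta = self.eng.schedule_floor
        self._schedule(ag, now + delta, "scheduled")

    def _interrupt(self, ag: Agent, time: float, kind: str = "interrupt-signal") -> None:
        self.queue.push(time, ag.id, kind=kind, epoch=-1)

    def _dist(self, a: Agent, b: Agent) -> float:
        dx, dy = torus_delta(
            a.pose.x, a.pose.y, b.pose.x, b.pose.y, self.w.width, self.w.height
        )
        return math.hypot(dx, dy)

    def _log(self, time: float, actor: int, receiver: int, behavior: str, value=1.0):
        if time >= self.record_start or (
            behavior == "groom" and time + value > self.record_start
        ):
            self.log.add(time, actor, receiver, behavior, value)

    # -- emotional settling --------------------------------------------------

    def _settle(self, ag: Agent, t: float) -> None:
        dt = t - ag.last_settle
        if dt <= 0.0:
            return
        st = ag.state
        st.arousal = relax_toward_limit(
            st.arousal, st.arousal_limit, dt, self.p.arousal_relax_rate
        )
        st.anxiety = relax_toward_limit(
            st.anxiety, st.anxiety_limit, dt, self.p.anxiety_relax_rate
        )
        bout = ag.bout
        role = bout.role if bout is not None and bout.kind == "groom" else "none"
        tick_satisfaction(st, role, dt, self.p)
        ag.last_settle = t

    def _proximity_update(self, ag: Agent, t: float) -> None:
        """Post-movement check of feared agents in personal distance."""
        self._settle(ag, t)
        self._refresh_ar_limit(ag)
        # notify nearby agents that fear ego of its new position
        fear = self.attitudes.fear
        for other in self.agents:
            if other is ag:
                continue
            if fear[other.id, ag.id] > 0.0 and self._dist(other, ag) <= self.w.pers_dist:
                self._settle(other, t)
                self._refresh_ar_limit(other)

    def _refresh_ar_limit(self, ag: Agent) -> None:
        fear_row = self.attitudes.fear[ag.id]
        pers = self.w.pers_dist
        elevated = False
        for other in self.agents:
            if other is not ag and fear_row[other.id] > 0.0:
                if self._dist(ag, other) <= pers:
                    elevated = True
                    break
        ag.state.arousal_limit = (
            self.p.elevated_ar_limit if elevated else self.p.def_ar_limit
        )

    # -- bouts ---------------------------------------------------------------

    def _finalize_groom(self, ag: Agent, t: float, notify_partner: bool) -> None:
        """End a grooming bout for both members; log the accrued minutes."""
        bout = ag.bout
        other = self.agents[bout.partner]
        groomer, groomee = (ag, other) if bout.role == "groomer" else (other, ag)
        self._settle(groomer, t)
        self._settle(groomee, t)
        duration = t - bout.started_at
        self.attitudes.stop_receiving(groomee.id, t)
        apply_event(groomer.state, "give_grooming", self.table)
        apply_event(groomee.state, "receive_grooming", self.table)
        if duration > 0.0:
            self._log(bout.started_at, groomer.id, groomee.id, "groom", duration)
        groomer.bout = None
        groomee.bout = None
        if notify_partner:
            self._interrupt(other, t)

    def _end_bout_early(self, ag: Agent, t: float) -> None:
        """Terminate whatever bout ag is in (interrupt semantics)."""
        bout = ag.bout
        if bout is None:
            return
        if bout.kind == "groom":
            self._finalize_groom(ag, t, notify_partner=True)
        else:  # rest or move: nothing to log
            ag.bout = None

    def _steal_partner(self, other: Agent, t: float) -> None:
        """Free ``other`` from its current bout so it can join a new one."""
        bout = other.bout
        if bout is None:
            return
        if bout.kind == "groom":
            self._finalize_groom(other, t, notify_partner=True)
        else:
            other.bout = None

    # -- the event loop ------------------------------------------------------

    def run(self, until: float | None = None) -> None:
        horizon = self.horizon if until is None else until
        queue = self.queue
        agents = self.agents
        while len(queue) and queue.peek_time() <= horizon:
            act = queue.pop_next()
            self.now = act.time
            if act.agent_id < 0:
                self._take_sample(act.time)
                continue
            ag = agents[act.agent_id]
            if act.epoch >= 0 and act.epoch != ag.epoch:
                continue  # superseded routine event
            if act.kind == "movement-substep":
                self._process_substep(ag, act.time)
            elif act.kind == "scheduled":
                bout = ag.bout
                if bout is not None:
                    if bout.kind == "groom":
                        self._finalize_groom(ag, act.time, notify_partner=False)
                    else:
                        ag.bout = None
                self._select_and_act(ag, act.time)
            else:  # interrupt
                self._end_bout_early(ag, act.time)
                self._select_and_act(ag, act.time)
        self._flush(horizon)
        self.now = horizon

    def start_grooming(self, groomer: int, groomee: int, t: float = 0.0) -> None:
        """Begin a grooming bout directly (scenario hook for analyses)."""
        self._start_groom(self.agents[groomer], self.agents[groomee], t)

    def settle_to(self, t: float) -> None:
        """Advance every agent's emotional kinetics to time t (no events)."""
        for ag in self.agents:
            self._settle(ag, t)

    def _flush(self, t: float) -> None:
        """Close out grooming bouts still running at the horizon."""
        for ag in self.agents:
            if ag.bout is not None and ag.bout.kind == "groom":
                self._finalize_groom(ag, t, notify_partner=False)

    def _take_sample(self, t: float) -> None:
        poses = [ag.pose for ag in self.agents]
        self.prox_samples.append(sample_proximity(poses, self.w))
        self.like_samples.append(self.attitudes.like_matrix(t))
        for ag in self.agents:
            self._settle(ag, t)
        st = np.array(
            [
                (ag.state.arousal, ag.state.anxiety, ag.state.satisfaction)
                for ag in self.agents
            ]
        )
        self.emotion_samples.append(st.mean(axis=0))

    # -- movement ------------------------------------------------------------

    def _process_substep(self, ag: Agent, t: float) -> None:
        bout = ag.bout
        if bout is None or bout.kind != "move":
            self._select_and_act(ag, t)
            return
        w, eng = self.w, self.eng
        if bout.mode == "random":
            if t >= bout.planned_end:
                ag.bout = None
                self._proximity_update(ag, t)
                self._select_and_act(ag, t)
                return
            turn = self.rng.uniform(-eng.random_walk_turn, eng.random_walk_turn)
            ag.pose.heading = (ag.pose.heading + turn) % 360.0
            execute_movement(ag.pose, bout, None, w, eng.move_speed, eng.move_substep)
            self._schedule(ag, t + eng.move_substep, "movement-substep")
            return
        referent = self.agents[bout.partner].pose
        cont = execute_movement(
            ag.pose, bout, referent, w, eng.move_speed, eng.move_substep
        )
        if t >= bout.planned_end:
            cont = False  # chase timed out: re-decide
        if cont:
            self._schedule(ag, t + eng.move_substep, "movement-substep")
        else:
            ag.bout = None
            self._proximity_update(ag, t)
            self._select_and_act(ag, t)

    def _start_move(
        self, ag: Agent, t: float, mode: str, partner: int | None, stop: float,
        planned_end: float | None = None,
    ) -> None:
        if planned_end is None:
            planned_end = t + self.eng.max_move_duration
        ag.bout = BoutState(
            kind="move",
            partner=partner,
            mode=mode,
            stop_dist=stop,
            started_at=t,
            planned_end=planned_end,
        )
        self._schedule(ag, t + self.eng.move_substep, "movement-substep")

    # -- action selection ----------------------------------------------------

    def _candidates(self, ag: Agent, view_angle: float) -> list[tuple[int, float]]:
        w = self.w
        ego = ag.pose
        heading = ego.heading
        full = view_angle >= 360.0
        half = view_angle / 2.0
        found: list[tuple[float, int]] = []
        for other in self.agents:
            if other is ag:
                continue
            dx, dy = torus_delta(
                ego.x, ego.y, other.pose.x, other.pose.y, w.width, w.height
            )
            d = math.hypot(dx, dy)
            if d > w.max_dist:
                continue
            if not full and d > 0.0:
                off = (math.degrees(math.atan2(dy, dx)) - heading) % 360.0
                if off > 180.0:
                    off = 360.0 - off
                if off > half:
                    continue
            found.append((d, other.id))
        found.sort()
        return [(aid, d) for d, aid in found[: w.max_partners]]

    def _grouping_needed(self, ag: Agent) -> bool:
        # inline equivalent of behavior.grouping_needed, engine hot path
        w = self.w
        ex, ey = ag.pose.x, ag.pose.y
        width, height = w.width, w.height
        near = 0
        far2 = w.far_dist * w.far_dist
        group2 = w.group_dist * w.group_dist
        for other in self.agents:
            if other is ag:
                continue
            dx = (other.pose.x - ex) % width
            if dx > width * 0.5:
                dx -= width
            dy = (other.pose.y - ey) % height
            if dy > height * 0.5:
                dy -= height
            d2 = dx * dx + dy * dy
            if d2 > far2:
                return True
            if d2 <= group2:
                near += 1
        return near < w.min_others

    def _select_and_act(self, ag: Agent, t: float) -> None:
        self._settle(ag, t)
        w, eng, rng = self.w, self.eng, self.rng
        if self._grouping_needed(ag):
            pick = int(rng.integers(0, len(self.agents) - 1))
            if pick >= ag.id:
                pick += 1
            self._start_move(ag, t, "toward", pick, eng.grouping_stop_dist)
            return
        va = w.view_angle
        if rng.random() < scan_probability(ag.state.arousal, self.p):
            va = w.max_angle
        cands = self._candidates(ag, va)
        behavior, target = self._draw_action(ag, t, cands, allow_scan=(va < 360.0))
        if behavior == "scan":
            cands = self._candidates(ag, w.max_angle)
            behavior, target = self._draw_action(ag, t, cands, allow_scan=False)
        self._execute(ag, t, behavior, target)

    def _draw_action(
        self, ag: Agent, t: float, cands: list[tuple[int, float]], allow_scan: bool
    ) -> tuple[str, int | None]:
        att = self.attitudes
        if self.sp.lps > 0.0:
            like = {j: att.like_value(ag.id, j, t) for j, _ in cands}
        else:
            like = None  # null model: LIKE not consulted
        dist = action_probabilities(
            ag.state,
            like,
            att.fear[ag.id],
            cands,
            self.sp,
            self.w,
            include_scan=allow_scan and not cands,
        )
        return dist.draw(self.rng)

    # -- behaviour execution -------------------------------------------------

    def _execute(self, ag: Agent, t: float, behavior: str, target: int | None) -> None:
        eng, rng = self.eng, self.rng
        if behavior == "rest":
            dur = rng.uniform(eng.bout_min, eng.bout_max)
            ag.bout = BoutState(kind="rest", started_at=t, planned_end=t + dur)
            self._schedule(ag, t + dur, "scheduled")
        elif behavior == "random_move":
            self._start_move(
                ag, t, "random", None, 0.0, planned_end=t + eng.random_walk_duration
            )
        elif behavior == "groom":
            self._start_groom(ag, self.agents[target], t)
        elif behavior == "approach":
            self._log(t, ag.id, target, "approach")
            self._start_move(ag, t, "toward", target, self.w.interact_dist)
        elif behavior in ("leave", "avoid"):
            self._log(t, ag.id, target, behavior)
            self._start_move(ag, t, "away", target, eng.flee_stop_dist)
        elif behavior == "attack":
            self._resolve_attack(ag, self.agents[target], t)
        else:  # signals
            self._signal(ag, self.agents[target], t, behavior)

    def _start_groom(self, groomer: Agent, groomee: Agent, t: float) -> None:
        self._settle(groomee, t)
        self._steal_partner(groomee, t)
        dur = self.rng.uniform(self.eng.bout_min, self.eng.bout_max)
        end = t + dur
        groomer.bout = BoutState(
            kind="groom", partner=groomee.id, role="groomer",
            started_at=t, planned_end=end,
        )
        groomee.bout = BoutState(
            kind="groom", partner=groomer.id, role="groomee",
            started_at=t, planned_end=end,
        )
        self.attitudes.start_receiving(groomee.id, groomer.id, t)
        self._schedule(groomer, end, "scheduled")
        self._schedule(groomee, end, "scheduled")

    def _signal(self, ag: Agent, other: Agent, t: float, behavior: str) -> None:
        self._settle(other, t)
        table = self.table
        if behavior == "affiliative_signal":
            apply_event(ag.state, "give_affiliative_signal", table)
            apply_event(other.state, "receive_affiliative_signal", table)
        elif behavior == "submissive_signal":
            apply_event(other.state, "receive_submissive_signal", table)
        else:
            apply_event(ag.state, "give_aggressive_signal", table)
            apply_event(other.state, "receive_aggressive_signal", table)
            if other.bout is not None and other.bout.kind in ("groom", "rest"):
                self._interrupt(other, t)
        self._log(t, ag.id, other.id, behavior)
        self._schedule_routine(ag, t)

    def _resolve_attack(self, ag: Agent, target: Agent, t: float) -> None:
        table = self.table
        self._settle(target, t)
        if target.bout is not None:
            if target.bout.kind == "groom":
                self._finalize_groom(target, t, notify_partner=True)
            else:
                target.bout = None
        apply_event(ag.state, "give_attack", table)
        apply_event(target.state, "receive_attack", table)
        self._log(t, ag.id, target.id, "attack")
        outcome = resolve_attack(
            ag.id,
            target.id,
            self.doms,
            target.state,
            self.attitudes.fear[target.id, ag.id],
            self.sp,
            self.rng,
        )
        if outcome.escalated:
            self._log(t, target.id, ag.id, "attack")  # the counter-attack
            winner = self.agents[outcome.winner]
            loser = self.agents[outcome.loser]
            apply_event(winner.state, "win_fight", table)
            apply_event(loser.state, "lose_fight", table)
            for other in self.agents:
                if other is ag or other is target:
                    continue
                if self._dist(other, ag) <= self.eng.observe_fight_dist:
                    self._settle(other, t)
                    apply_event(other.state, "observe_fight", table)
                    self._interrupt(
                        other, t + self.eng.bystander_delay, "interrupt-fight-nearby"
                    )
        else:
            winner, loser = ag, target
        self._start_move(loser, t, "away", winner.id, self.eng.flee_stop_dist)
        self._schedule(winner, t + self.eng.winner_delay, "scheduled")
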