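"""Action selection and behaviour execution semantics.

Weights for every eligible (behaviour, target) pair are built from a
baseline tendency table, modulated by ego's emotional state and its
FEAR/LIKE attitudes.  Affiliative weights toward partner j carry the
selectivity factor ``m_j = (1 - lps) + lps * LIKE_ij``: at lps = 0 LIKE
is irrelevant (the null model), near 1 affiliation concentrates almost
exclusively on highly LIKEd partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .affect import EmotionalState
from .world import Pose, WorldConfig, torus_delta, torus_distance

__all__ = [
    "AFFILIATION",
    "SUBMISSION",
    "AGGRESSION",
    "BEHAVIOR_KINDS",
    "ActionDistribution",
    "SelectivityParams",
    "BoutState",
    "AttackOutcome",
    "eligible_actions",
    "action_probabilities",
    "grouping_needed",
    "win_chance",
    "counter_attack_probability",
    "resolve_attack",
    "execute_movement",
    "draw_bout_duration",
]

AFFILIATION = ("groom", "affiliative_signal", "approach")
SUBMISSION = ("leave", "submissive_signal", "avoid")
AGGRESSION = ("attack", "aggressive_signal")
BEHAVIOR_KINDS = AFFILIATION + SUBMISSION + AGGRESSION + (
    "flee",
    "grouping_move",
    "random_move",
    "rest",
    "scan",
)


@dataclass(frozen=True)
class SelectivityParams:
    """Partner selectivity, baseline tendencies and emotional modulation."""

    lps: float = 0.0
    base: Mapping[str, float] = field(
        default_factory=lambda: dict(
            groom=1.0,
            affiliative_signal=0.3,
            approach=0.7,
            leave=0.25,
            submissive_signal=0.4,
            avoid=0.3,
            attack=0.25,
            aggressive_signal=0.25,
            flee=1.0,
            random_move=0.35,
            rest=2.0,
            scan=0.5,
        )
    )
    c_arousal: float = 1.0  # arousal scales all active behaviours up
    c_anx_aff: float = 1.0  # anxiety scales affiliation up
    c_anx_sub: float = 1.0  # anxiety scales submission up
    c_sat: float = 1.0  # satisfaction scales affiliation down
    c_fear_agg: float = 1.0  # FEAR scales aggression down
    c_anx_risk: float = 2.0  # anxiety * positive FEAR suppresses aggression
    eps_sub: float = 0.01  # residual submission toward non-feared agents
    win_beta: float = 8.0  # sigmoid steepness of contest outcomes

    def __post_init__(self) -> None:
        if not 0.0 <= self.lps < 1.0:
            raise ValueError("lps must lie in [0, 1)")
        if any(wt < 0 for wt in self.base.values()):
            raise ValueError("baseline weights must be >= 0")
        if self.base.get("rest", 0.0) <= 0:
            raise ValueError("rest must have a positive baseline weight")
        if self.win_beta <= 0:
            raise ValueError("win_beta must be positive")


@dataclass
class ActionDistribution:
    """Weighted (behaviour, target) entries; target None for solo acts."""

    entries: list[tuple[str, int | None]]
    weights: list[float]

    @property
    def probabilities(self) -> list[float]:
        total = sum(self.weights)
        if total <= 0:
            raise ValueError("no positive weight in action distribution")
        return [w / total for w in self.weights]

    def weight_of(self, behavior: str, target: int | None = None) -> float:
        for (b, tgt), w in zip(self.entries, self.weights):
            if b == behavior and tgt == target:
                return w
        return 0.0

    def draw(self, rng) -> tuple[str, int | None]:
        u = rng.random() * sum(self.weights)
        acc = 0.0
        for entry, w in zip(self.entries, self.weights):
            acc += w
            if u < acc:
                return entry
        return self.entries[-1]


def eligible_actions(
    candidates: Sequence[tuple[int, float]], w: WorldConfig
) -> list[tuple[str, int | None]]:
    """Distance-gated (behaviour, target) pairs for the candidate set.

    Within 1 m: groom, leave, attack.  Within 5 m: all three signals and
    avoid.  Within 50 m: approach.  Rest and random movement are always
    available; grouping pre-empts selection and is handled separately.
    """
    out: list[tuple[str, int | None]] = []
    for aid, dist in candidates:
        if dist <= w.interact_dist:
            out.append(("groom", aid))
            out.append(("leave", aid))
            out.append(("attack", aid))
        if dist <= w.pers_dist:
            out.append(("affiliative_signal", aid))
            out.append(("submissive_signal", aid))
            out.append(("aggressive_signal", aid))
            out.append(("avoid", aid))
        if dist <= w.max_dist:
            out.append(("approach", aid))
    out.append(("rest", None))
    out.append(("random_move", None))
    return out


def action_probabilities(
    ego_state: EmotionalState,
    like: Mapping[int, float],
    fear: Mapping[int, float],
    candidates: Sequence[tuple[int, float]],
    sp: SelectivityParams,
    w: WorldConfig,
    include_scan: bool | None = None,
) -> ActionDistribution:
    """Build the selection distribution over eligible actions.

    ``like`` and ``fear`` map candidate id -> ego's attitude toward it.
    With an empty candidate set the distribution covers rest, random
    movement and (unless disabled) scanning only.
    """
    ar = ego_state.arousal
    anx = ego_state.anxiety
    sat = ego_state.satisfaction
    act = 1.0 + sp.c_arousal * ar  # all active behaviours
    aff_state = act * (1.0 + sp.c_anx_aff * anx) * max(0.0, 1.0 - sp.c_sat * sat)
    sub_state = act * (1.0 + sp.c_anx_sub * anx)
    lps = sp.lps
    base = sp.base

    # Dyadic weights are split over the candidate set so the overall
    # tendency toward a behaviour class does not grow with crowd size.
    share = 1.0 / len(candidates) if candidates else 1.0
    # Selectivity redistributes affiliation among partners without
    # changing the total affiliative tendency: the per-partner factor
    # m_j = (1 - lps) + lps * LIKE_ij is normalized by its candidate
    # mean, so relative preferences (e.g. 100:1 at lps = 0.99 for LIKE
    # 1 vs 0) are untouched while an all-low-LIKE group still affiliates
    # at the baseline rate (which is what lets preferences bootstrap).
    if lps > 0.0 and candidates:
        m_by_target = {
            j: (1.0 - lps) + lps * like[j] for j, _ in candidates
        }
        m_mean = sum(m_by_target.values()) / len(m_by_target)
        inv_m_mean = 1.0 / m_mean  # m_j >= 1 - lps > 0, mean never zero
    else:
        m_by_target = None
        inv_m_mean = 1.0
    entries: list[tuple[str, int | None]] = []
    weights: list[float] = []
    for behavior, target in eligible_actions(candidates, w):
        if target is None:
            wt = base[behavior] * (act if behavior == "random_move" else 1.0)
        elif behavior in AFFILIATION:
            if m_by_target is not None:
                m = m_by_target[target] * inv_m_mean
            else:
                m = 1.0  # null model: LIKE is never consulted
            wt = base[behavior] * m * aff_state
        elif behavior in SUBMISSION:
            f = fear[target]
            wt = base[behavior] * (sp.eps_sub + max(0.0, f)) * sub_state
        else:  # aggression
            f = fear[target]
            risk = 1.0 / (1.0 + sp.c_anx_risk * anx * max(0.0, f))
            wt = base[behavior] * max(0.0, 1.0 - sp.c_fear_agg * f) * act * risk
        if target is not None:
            wt *= share
        entries.append((behavior, target))
        weights.append(wt)
    if include_scan is None:
        include_scan = not candidates
    if include_scan:
        entries.append(("scan", None))
        weights.append(base.get("scan", 0.0) * act)
    return ActionDistribution(entries, weights)


def grouping_needed(
    ego_id: int, poses: Sequence[Pose] | Mapping[int, Pose], w: WorldConfig
) -> bool:
    """True iff cohesion demands ego approach a random group member.

    Triggered when fewer than ``min_others`` others are within the
    grouping radius (full 360-degree check) or any member is farther
    than ``far_dist``.
    """
    if isinstance(poses, Mapping):
        items = poses.items()
        ego = poses[ego_id]
    else:
        items = enumerate(poses)
        ego = poses[ego_id]
    near = 0
    for aid, pose in items:
        if aid == ego_id:
            continue
        d = torus_distance(ego, pose, w)
        if d > w.far_dist:
            return True
        if d <= w.group_dist:
            near += 1
    return near < w.min_others


def win_chance(dom_i: float, dom_j: float, beta: float = 8.0) -> float:
    """P(i beats j) in an escalated fight: logistic in the dominance gap."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return 1.0 / (1.0 + math.exp(-beta * (dom_i - dom_j)))


def counter_attack_probability(
    target_state: EmotionalState, fear_of_attacker: float, sp: SelectivityParams
) -> float:
    """P(counter-attack | attacked), from the same weight contract.

    The attacked agent weighs counter-attacking (an aggressive act,
    suppressed by FEAR of the attacker and by anxious risk-sensitivity)
    against fleeing.
    """
    anx = target_state.anxiety
    f = fear_of_attacker
    risk = 1.0 / (1.0 + sp.c_anx_risk * anx * max(0.0, f))
    w_counter = sp.base["attack"] * max(0.0, 1.0 - sp.c_fear_agg * f) * risk
    w_flee = sp.base["flee"] * (1.0 + sp.c_anx_sub * anx)
    total = w_counter + w_flee
    if total <= 0:
        return 0.0
    return w_counter / total


@dataclass(frozen=True)
class AttackOutcome:
    attacker: int
    target: int
    escalated: bool
    winner: int
    loser: int


def resolve_attack(
    attacker: int,
    target: int,
    doms: Sequence[float],
    target_state: EmotionalState,
    fear_of_attacker: float,
    sp: SelectivityParams,
    rng,
) -> AttackOutcome:
    """Decide escalation and outcome of an attack (consumes <= 2 draws).

    The target either flees (attacker wins outright) or counter-attacks;
    an escalated fight is settled by the sigmoid win chance.
    """
    p_counter = counter_attack_probability(target_state, fear_of_attacker, sp)
    if rng.random() < p_counter:
        p_win = win_chance(doms[attacker], doms[target], sp.win_beta)
        if rng.random() < p_win:
            return AttackOutcome(attacker, target, True, attacker, target)
        return AttackOutcome(attacker, target, True, target, attacker)
    return AttackOutcome(attacker, target, False, attacker, target)


# --- movement ---------------------------------------------------------------

MOVE_SUBSTEP = 0.05  # minutes: 3 seconds


@dataclass
class BoutState:
    """One agent's ongoing bout (grooming, resting or movement)."""

    kind: str  # groom | rest | move
    partner: int | None = None  # bout partner (groom) or referent (move)
    role: str | None = None  # groomer | groomee
    mode: str | None = None  # toward | away | random (movement)
    stop_dist: float | None = None
    started_at: float = 0.0
    planned_end: float = math.inf
    finalized: bool = False


def execute_movement(
    ego: Pose,
    bout: BoutState,
    referent: Pose | None,
    w: WorldConfig,
    speed: float,
    dt: float = MOVE_SUBSTEP,
) -> bool:
    """Advance one movement substep in place; True means the bout goes on.

    'toward' heads at the referent and stops once within ``stop_dist``;
    'away' heads opposite and stops once beyond it; 'random' keeps the
    current heading (the caller perturbs it) and runs until planned_end.
    """
    step = speed * dt
    if bout.mode in ("toward", "away"):
        if referent is None:
            raise ValueError("directed movement requires a referent pose")
        dx, dy = torus_delta(ego.x, ego.y, referent.x, referent.y, w.width, w.height)
        dist = math.hypot(dx, dy)
        if bout.mode == "toward":
            if dist <= bout.stop_dist:
                return False
            if dist - step < bout.stop_dist:
                step = dist - bout.stop_dist  # land exactly on the stop ring
            ego.heading = math.degrees(math.atan2(dy, dx)) % 360.0
        else:
            if dist > bout.stop_dist:
                return False
            ego.heading = math.degrees(math.atan2(-dy, -dx)) % 360.0
    h = math.radians(ego.heading)
    ego.x = (ego.x + step * math.cos(h)) % w.width
    ego.y = (ego.y + step * math.sin(h)) % w.height
    if bout.mode == "toward":
        dx, dy = torus_delta(ego.x, ego.y, referent.x, referent.y, w.width, w.height)
        return math.hypot(dx, dy) > bout.stop_dist
    if bout.mode == "away":
        dx, dy = torus_delta(ego.x, ego.y, referent.x, referent.y, w.width, w.height)
        return math.hypot(dx, dy) <= bout.stop_dist
    return True


def draw_bout_duration(rng, low: float = 2.0, high: float = 10.0) -> float:
    """Grooming/resting bout length in minutes (uniform by default)."""
    return rng.uniform(low, high)
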