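"""Emotional state dynamics and partner-specific attitudes.

Three general emotional dimensions (arousal, anxiety, satisfaction) are
kept in [0, 1].  Arousal and anxiety relax exponentially toward limit
values; satisfaction changes with linear per-minute rates (it rises while
grooming and decays back to its limit otherwise).

Each agent also holds two attitudes per group member: a fixed FEAR
(dominance difference, theirs minus ego's) and a LIKE in [0, 1].  In the
dynamic variant LIKE integrates grooming received from that partner via a
history-weighted running update of the partner-specific satisfaction
level; in the fixed (control) variant LIKE is a decreasing function of
absolute rank distance and never changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EmotionalState",
    "AffectParams",
    "SalienceTable",
    "DEFAULT_SALIENCE",
    "validate_salience",
    "AttitudeStore",
    "fear",
    "fixed_like",
    "update_like",
    "tick_satisfaction",
    "apply_event",
    "relax_toward_limit",
    "scan_probability",
]


def _clamp(v: float) -> float:
    return 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)


@dataclass
class EmotionalState:
    arousal: float = 0.09
    anxiety: float = 0.0
    satisfaction: float = 0.0
    arousal_limit: float = 0.09  # DEF_AR_LIMIT baseline
    anxiety_limit: float = 0.0
    satisfaction_limit: float = 0.0

    def clamp(self) -> "EmotionalState":
        self.arousal = _clamp(self.arousal)
        self.anxiety = _clamp(self.anxiety)
        self.satisfaction = _clamp(self.satisfaction)
        self.arousal_limit = _clamp(self.arousal_limit)
        self.anxiety_limit = _clamp(self.anxiety_limit)
        self.satisfaction_limit = _clamp(self.satisfaction_limit)
        return self

    def copy(self) -> "EmotionalState":
        return replace(self)


@dataclass(frozen=True)
class AffectParams:
    """Rates governing emotional kinetics (all per model minute)."""

    sat_inc_groomer: float = 0.05
    sat_inc_groomee: float = 0.1  # GR_SAT_INC
    sat_dec: float = 0.02
    def_ar_limit: float = 0.09
    elevated_ar_limit: float = 0.3  # while a feared agent is within pers_dist
    lhw: float = 720.0  # LIKE history weight: one 12-hour model day
    arousal_relax_rate: float = 0.05
    anxiety_relax_rate: float = 0.002
    anxiety_drift_limit: float = 0.5  # anxiety creeps up toward this when idle
    scan_base: float = 0.05
    scan_gain: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "sat_inc_groomer",
            "sat_inc_groomee",
            "sat_dec",
            "arousal_relax_rate",
            "anxiety_relax_rate",
            "scan_base",
            "scan_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lhw <= 0:
            raise ValueError("lhw must be positive")


# --- event salience ---------------------------------------------------------

#: event kind -> (required sign of d_arousal, required sign of d_anxiety);
#: +1 means strictly positive, -1 means <= 0, 0 means unconstrained.
_SIGN_RULES: dict[str, tuple[int, int]] = {
    "receive_attack": (+1, +1),
    "give_attack": (+1, +1),
    "receive_aggressive_signal": (+1, +1),
    "give_aggressive_signal": (+1, +1),
    "observe_fight": (+1, +1),
    "lose_fight": (0, +1),
    "win_fight": (0, -1),
    "receive_submissive_signal": (-1, -1),
    "receive_affiliative_signal": (-1, -1),
    "give_affiliative_signal": (-1, 0),
    "receive_grooming": (-1, -1),
    "give_grooming": (-1, -1),
    "dominant_within_pers_dist": (0, 0),  # applied to arousal_limit
}

#: Default (arousal delta, anxiety delta) per event kind.  Magnitudes are
#: free parameters of the model; signs are fixed and validated.
DEFAULT_SALIENCE: dict[str, tuple[float, float]] = {
    "receive_attack": (0.4, 0.4),
    "give_attack": (0.3, 0.1),
    "receive_aggressive_signal": (0.2, 0.2),
    "give_aggressive_signal": (0.1, 0.05),
    "observe_fight": (0.2, 0.2),
    "lose_fight": (0.1, 0.3),
    "win_fight": (0.0, -0.2),
    "receive_submissive_signal": (-0.1, -0.1),
    "receive_affiliative_signal": (-0.1, -0.1),
    "give_affiliative_signal": (-0.05, 0.0),
    "receive_grooming": (-0.1, -0.1),
    "give_grooming": (-0.05, -0.05),
    "dominant_within_pers_dist": (0.21, 0.0),
}


@dataclass(frozen=True)
class SalienceTable:
    """Per-event (arousal, anxiety) deltas with sign constraints."""

    deltas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SALIENCE)
    )

    def __post_init__(self) -> None:
        validate_salience(self.deltas)

    def __getitem__(self, kind: str) -> tuple[float, float]:
        return self.deltas[kind]

    def __contains__(self, kind: str) -> bool:
        return kind in self.deltas


def validate_salience(deltas: dict[str, tuple[float, float]]) -> None:
    """Enforce the stated sign structure of emotional event responses."""
    for kind, (dar, danx) in deltas.items():
        rule = _SIGN_RULES.get(kind)
        if rule is None:
            raise ValueError(f"unknown salience event kind: {kind!r}")
        sar, sanx = rule
        if sar == +1 and not dar > 0:
            raise ValueError(f"{kind}: arousal delta must be > 0, got {dar}")
        if sar == -1 and not dar <= 0:
            raise ValueError(f"{kind}: arousal delta must be <= 0, got {dar}")
        if sanx == +1 and not danx > 0:
            raise ValueError(f"{kind}: anxiety delta must be > 0, got {danx}")
        if sanx == -1 and not danx <= 0:
            raise ValueError(f"{kind}: anxiety delta must be <= 0, got {danx}")


def apply_event(
    state: EmotionalState, event_kind: str, table: SalienceTable
) -> EmotionalState:
    """Apply one event's emotional salience to ``state`` in place.

    The special kind ``dominant_within_pers_dist`` raises the arousal
    *limit* rather than arousal itself.
    """
    if event_kind not in table:
        raise KeyError(f"event kind not in salience table: {event_kind!r}")
    dar, danx = table[event_kind]
    if event_kind == "dominant_within_pers_dist":
        state.arousal_limit = _clamp(state.arousal_limit + dar)
    else:
        state.arousal = _clamp(state.arousal + dar)
        state.anxiety = _clamp(state.anxiety + danx)
    return state


# --- scalar kinetics --------------------------------------------------------


def fear(dom_i: float, dom_j: float) -> float:
    """FEAR that i assigns to j: j's dominance minus i's."""
    return dom_j - dom_i


def fixed_like(
    dom_i: float, dom_j: float, l0: float = 0.243, ls: float = 0.36
) -> float:
    """Control-variant LIKE: max(0, l0 - ls * |dom_j - dom_i|).  Symmetric."""
    if l0 < 0 or ls < 0:
        raise ValueError("conversion parameters must be >= 0")
    return max(0.0, l0 - ls * abs(dom_j - dom_i))


def update_like(like_prev: float, psat_now: float, dt: float, lhw: float) -> float:
    """History-weighted LIKE update.

    Returns ``max((lhw*like_prev + dt*psat_now) / (lhw + dt), psat_now)``:
    a time-weighted blend of the previous LIKE with the current
    partner-specific satisfaction, floored at that current level so that
    ongoing affiliation raises LIKE immediately while its absence lets
    LIKE decay on the slow time scale set by ``lhw``.
    """
    if dt < 0:
        raise ValueError("negative dt: activations delivered out of order")
    if lhw <= 0:
        raise ValueError("lhw must be positive")
    blended = (lhw * like_prev + dt * psat_now) / (lhw + dt)
    return blended if blended > psat_now else psat_now


def tick_satisfaction(
    state: EmotionalState, role: str, dt: float, p: AffectParams
) -> EmotionalState:
    """Advance satisfaction by ``dt`` minutes in place.

    role 'groomer' gains 0.05/min, 'groomee' 0.1/min, 'none' decays
    0.02/min toward the satisfaction limit; always clamped to [0, 1].
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    s = state.satisfaction
    if role == "groomer":
        s += p.sat_inc_groomer * dt
    elif role == "groomee":
        s += p.sat_inc_groomee * dt
    elif role == "none":
        lim = state.satisfaction_limit
        if s > lim:
            s = max(lim, s - p.sat_dec * dt)
        elif s < lim:
            s = min(lim, s + p.sat_dec * dt)
    else:
        raise ValueError(f"unknown grooming role: {role!r}")
    state.satisfaction = _clamp(s)
    return state


def relax_toward_limit(value: float, limit: float, dt: float, rate: float) -> float:
    """Exponential approach: limit + (value - limit) * exp(-rate*dt)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return limit + (value - limit) * math.exp(-rate * dt)


def scan_probability(arousal: float, p: AffectParams) -> float:
    """Probability of scanning this round; nondecreasing in arousal."""
    if not 0.0 <= arousal <= 1.0:
        raise ValueError("arousal must lie in [0, 1]")
    return _clamp(p.scan_base + p.scan_gain * arousal)


# --- attitude bookkeeping ---------------------------------------------------


class AttitudeStore:
    """Group-wide FEAR / LIKE / PARTNER_SAT matrices.

    Row i, column j holds the attitude that agent i directs to agent j.
    LIKE and PARTNER_SAT are updated lazily: each directed dyad stores
    the time of its last update and is settled on read and at every
    change-point of PARTNER_SAT (grooming start/stop, saturation at 1,
    decay reaching zero), keeping the piecewise-constant approximation
    of the running update tight.
    """

    def __init__(
        self,
        doms: np.ndarray,
        params: AffectParams,
        dynamic: bool = True,
        l0: float = 0.243,
        ls: float = 0.36,
        t0: float = 0.0,
    ) -> None:
        doms = np.asarray(doms, dtype=float)
        if doms.ndim != 1 or len(doms) < 2:
            raise ValueError("doms must be a vector of at least two levels")
        if np.any(doms <= 0) or np.any(doms > 1):
            raise ValueError("dominance levels must lie in (0, 1]")
        n = len(doms)
        self.n = n
        self.doms = doms
        self.params = params
        self.dynamic = dynamic
        self.fear = doms[None, :] - doms[:, None]  # fear[i, j] = dom_j - dom_i
        np.fill_diagonal(self.fear, 0.0)
        if dynamic:
            self.like = np.zeros((n, n))
        else:
            self.like = np.maximum(
                0.0, l0 - ls * np.abs(doms[:, None] - doms[None, :])
            )
            np.fill_diagonal(self.like, 0.0)
        self.psat = np.zeros((n, n))
        self.like_t = np.full((n, n), t0)
        self.psat_t = np.full((n, n), t0)
        # groomed_by[i] = j while i is receiving grooming from j, else -1
        self.groomed_by = np.full(n, -1, dtype=int)

    # -- partner-specific satisfaction --

    def psat_value(self, i: int, j: int, t: float) -> float:
        """PARTNER_SAT_ij at time t (lazy linear growth/decay)."""
        p = self.params
        v = self.psat[i, j]
        dt = t - self.psat_t[i, j]
        if self.groomed_by[i] == j:
            return min(1.0, v + p.sat_inc_groomee * dt)
        return max(0.0, v - p.sat_dec * dt)

    def _settle_like(self, i: int, j: int, t: float) -> float:
        p = self.params
        t_prev = self.like_t[i, j]
        if t <= t_prev:
            return self.like[i, j]
        v0 = self.psat[i, j]
        anchor = self.psat_t[i, j]
        like = self.like[i, j]
        if self.groomed_by[i] == j:
            # growing; change-point where psat saturates at 1
            change = anchor + (1.0 - v0) / p.sat_inc_groomee if v0 < 1.0 else anchor
        else:
            if like == 0.0 and v0 == 0.0:
                self.like_t[i, j] = t  # fast path: nothing to integrate
                return 0.0
            # decaying; change-point where psat hits zero
            change = anchor + v0 / p.sat_dec if v0 > 0.0 else anchor
        lhw = p.lhw
        if t_prev < change < t:
            dt = change - t_prev
            ps = self.psat_value(i, j, change)
            blended = (lhw * like + dt * ps) / (lhw + dt)
            like = blended if blended > ps else ps
            t_prev = change
        dt = t - t_prev
        ps = self.psat_value(i, j, t)
        blended = (lhw * like + dt * ps) / (lhw + dt)
        like = blended if blended > ps else ps
        self.like[i, j] = like
        self.like_t[i, j] = t
        return like

    def like_value(self, i: int, j: int, t: float) -> float:
        """LIKE_ij at time t (settled in the dynamic variant)."""
        if not self.dynamic:
            return self.like[i, j]
        return self._settle_like(i, j, t)

    def like_matrix(self, t: float) -> np.ndarray:
        """Copy of the full LIKE matrix, settled to time t."""
        if self.dynamic:
            n = self.n
            for i in range(n):
                for j in range(n):
                    if i != j:
                        self._settle_like(i, j, t)
        return self.like.copy()

    def start_receiving(self, receiver: int, groomer: int, t: float) -> None:
        """Mark receiver as being groomed by groomer from time t."""
        if receiver == groomer:
            raise ValueError("an agent cannot groom itself")
        if self.groomed_by[receiver] != -1:
            raise RuntimeError("receiver is already being groomed")
        if self.dynamic:
            # settle the dyad through the decay regime before switching
            self._settle_like(receiver, groomer, t)
        self.psat[receiver, groomer] = self.psat_value(receiver, groomer, t)
        self.psat_t[receiver, groomer] = t
        self.groomed_by[receiver] = groomer

    def stop_receiving(self, receiver: int, t: float) -> None:
        """End the receiver's current grooming episode at time t."""
        j = self.groomed_by[receiver]
        if j < 0:
            return
        if self.dynamic:
            self._settle_like(receiver, j, t)
        self.psat[receiver, j] = self.psat_value(receiver, j, t)
        self.psat_t[receiver, j] = t
        self.groomed_by[receiver] = -1

    def fear_matrix_from_doms(self) -> np.ndarray:
        """Recompute FEAR from dominance (consistency check helper)."""
        m = self.doms[None, :] - self.doms[:, None]
        np.fill_diagonal(m, 0.0)
        return m
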