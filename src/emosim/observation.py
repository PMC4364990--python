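"""Sampling and recording protocol.

Behaviour is recorded per directed dyad over consecutive recording
intervals and divided by the interval length in hours to give hourly
rates; instantaneous quantities (proximity, LIKE, emotional levels) are
point-sampled once per interval.  Per-interval values are averaged over
the recording window (the burn-in period never contributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .world import Pose, WorldConfig, torus_distance

__all__ = [
    "Calendar",
    "BehaviorEvent",
    "BehaviorLog",
    "RateMatrices",
    "DURATION_BEHAVIORS",
    "sample_proximity",
    "interval_rates",
    "yearly_average",
    "aggregate_individual",
    "rank_category_means",
]

#: behaviours logged with a duration (minutes); everything else is a count
DURATION_BEHAVIORS = frozenset({"groom"})


@dataclass(frozen=True)
class Calendar:
    """Model calendar; everything is derived from the primitives."""

    minutes_per_hour: int = 60
    hours_per_day: int = 12
    days_per_week: int = 7
    weeks_per_year: int = 50
    sample_interval_days: float = 3.5

    @property
    def day(self) -> float:
        return float(self.minutes_per_hour * self.hours_per_day)

    @property
    def week(self) -> float:
        return self.day * self.days_per_week

    @property
    def year(self) -> float:
        return self.week * self.weeks_per_year

    @property
    def sample_interval(self) -> float:
        """Recording-interval length in minutes."""
        return self.day * self.sample_interval_days

    @property
    def interval_hours(self) -> float:
        return self.sample_interval / self.minutes_per_hour


@dataclass(frozen=True)
class BehaviorEvent:
    time: float
    actor: int
    receiver: int
    behavior: str
    value: float = 1.0  # duration in minutes for duration behaviours, else count

    def __post_init__(self) -> None:
        if self.actor == self.receiver:
            raise ValueError("directed behaviours need distinct actor and receiver")


@dataclass
class BehaviorLog:
    """Time-stamped directed interaction events."""

    events: list[BehaviorEvent] = field(default_factory=list)

    def add(
        self, time: float, actor: int, receiver: int, behavior: str, value: float = 1.0
    ) -> None:
        self.events.append(BehaviorEvent(time, actor, receiver, behavior, value))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def sample_proximity(
    poses: Sequence[Pose], w: WorldConfig, radius: float | None = None
) -> np.ndarray:
    """One-zero proximity sample: 1 iff a dyad is within ``radius`` metres.

    Symmetric with a zero diagonal; the default radius is the
    interaction distance (1 m).
    """
    r = w.interact_dist if radius is None else radius
    n = len(poses)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if torus_distance(poses[i], poses[j], w) <= r:
                out[i, j] = out[j, i] = 1.0
    return out


def interval_rates(
    log: BehaviorLog | Iterable[BehaviorEvent],
    interval_start: float,
    cal: Calendar,
    n_agents: int,
    behaviors: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Hourly-rate matrices for one recording interval.

    Counts (or minutes for duration behaviours) falling in
    ``[interval_start, interval_start + sample_interval)`` divided by the
    interval length in hours.  A duration event contributes only the part
    of its span overlapping the interval.
    """
    end = interval_start + cal.sample_interval
    if behaviors is not None:
        mats = {b: np.zeros((n_agents, n_agents)) for b in behaviors}
    else:
        mats = {}
    for ev in log:
        if ev.behavior in DURATION_BEHAVIORS:
            span = max(
                0.0, min(ev.time + ev.value, end) - max(ev.time, interval_start)
            )
            if span <= 0.0:
                continue
            value = span
        else:
            if not interval_start <= ev.time < end:
                continue
            value = ev.value
        mat = mats.get(ev.behavior)
        if mat is None:
            if behaviors is not None:
                continue
            mat = mats[ev.behavior] = np.zeros((n_agents, n_agents))
        mat[ev.actor, ev.receiver] += value
    hours = cal.interval_hours
    return {b: m / hours for b, m in mats.items()}


def window_rates(
    log: BehaviorLog | Iterable[BehaviorEvent],
    window_start: float,
    n_intervals: int,
    cal: Calendar,
    n_agents: int,
    behaviors: Sequence[str],
) -> list[dict[str, np.ndarray]]:
    """Per-interval hourly-rate matrices for a whole recording window.

    Single pass over the log; equivalent to calling
    :func:`interval_rates` once per interval.  Duration behaviours are
    split pro rata across the interval boundaries they span.
    """
    width = cal.sample_interval
    end = window_start + n_intervals * width
    mats = [
        {b: np.zeros((n_agents, n_agents)) for b in behaviors}
        for _ in range(n_intervals)
    ]
    for ev in log:
        if ev.behavior not in mats[0]:
            continue
        if ev.behavior in DURATION_BEHAVIORS:
            t0 = max(ev.time, window_start)
            t1 = min(ev.time + ev.value, end)
            k = int((t0 - window_start) // width)
            while t0 < t1 and k < n_intervals:
                bound = window_start + (k + 1) * width
                span = min(t1, bound) - t0
                if span > 0:
                    mats[k][ev.behavior][ev.actor, ev.receiver] += span
                t0 = bound
                k += 1
        else:
            if not window_start <= ev.time < end:
                continue
            k = int((ev.time - window_start) // width)
            mats[k][ev.behavior][ev.actor, ev.receiver] += ev.value
    hours = cal.interval_hours
    return [{b: m / hours for b, m in d.items()} for d in mats]


@dataclass
class RateMatrices:
    """Window-averaged dyadic measures for one run."""

    rates: dict[str, np.ndarray]  # behaviour -> directed hourly-rate matrix
    proximity: np.ndarray  # symmetric mean one-zero score
    like_mean: np.ndarray  # mean point-sampled LIKE
    n_intervals: int


def yearly_average(
    per_interval_rates: Sequence[Mapping[str, np.ndarray]],
    proximity_samples: Sequence[np.ndarray],
    like_samples: Sequence[np.ndarray],
) -> RateMatrices:
    """Arithmetic mean of per-interval rates and point samples."""
    if not per_interval_rates:
        raise ValueError("no recording intervals")
    if len(proximity_samples) != len(per_interval_rates) or len(like_samples) != len(
        per_interval_rates
    ):
        raise ValueError("sample series must cover the same intervals")
    behaviors: set[str] = set()
    for d in per_interval_rates:
        behaviors.update(d)
    shape = next(iter(proximity_samples)).shape
    k = len(per_interval_rates)
    rates = {}
    for b in sorted(behaviors):
        acc = np.zeros(shape)
        for d in per_interval_rates:
            m = d.get(b)
            if m is not None:
                acc += m
        rates[b] = acc / k
    proximity = np.mean(np.stack(proximity_samples), axis=0)
    like_mean = np.mean(np.stack(like_samples), axis=0)
    return RateMatrices(rates, proximity, like_mean, k)


def aggregate_individual(matrix: np.ndarray) -> np.ndarray:
    """Per-agent totals: sum of what each row-agent directs to others."""
    m = np.asarray(matrix, dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    return m.sum(axis=1)


def rank_category_means(
    matrix: np.ndarray, doms: Sequence[float], similar_threshold: float = 0.35
) -> dict[str, float]:
    """Category means of a dyadic matrix.

    'subordinate'/'dominant' split individuals into the lower and upper
    halves by dominance and average their individual totals;
    'similar'/'distant' average dyadic entries by absolute rank distance
    (strictly below the threshold = similar).
    """
    doms = np.asarray(doms, dtype=float)
    n = len(doms)
    if matrix.shape != (n, n):
        raise ValueError("matrix and dominance vector disagree on group size")
    totals = aggregate_individual(matrix)
    order = np.argsort(doms, kind="stable")
    lower, upper = order[: n // 2], order[n // 2 :]
    absdist = np.abs(doms[:, None] - doms[None, :])
    offdiag = ~np.eye(n, dtype=bool)
    similar = offdiag & (absdist < similar_threshold)
    distant = offdiag & (absdist >= similar_threshold)
    return {
        "subordinate": float(totals[lower].mean()),
        "dominant": float(totals[upper].mean()),
        "similar": float(matrix[similar].mean()) if similar.any() else float("nan"),
        "distant": float(matrix[distant].mean()) if distant.any() else float("nan"),
    }
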