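"""Run configuration: every model constant in one validated structure.

Configs round-trip through YAML; every free-parameter default is a named
key so experiments are fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .affect import AffectParams, DEFAULT_SALIENCE, SalienceTable
from .behavior import SelectivityParams
from .observation import Calendar
from .world import WorldConfig

__all__ = ["RunConfig", "EngineParams", "default_doms", "load_config", "dump_config"]

LPS_SWEEP = (0.0, 0.5, 0.9, 0.95, 0.99)


def default_doms(n: int = 20) -> tuple[float, ...]:
    """Evenly spaced dominance levels 1/n, 2/n, ..., 1 (0.05..1.00 for n=20)."""
    return tuple(round((k + 1) / n, 10) for k in range(n))


@dataclass(frozen=True)
class EngineParams:
    """Execution-level defaults not pinned by the model description."""

    move_speed: float = 10.0  # metres per minute (0.5 m per 3-s substep)
    move_substep: float = 0.05  # minutes (3 seconds)
    bout_min: float = 2.0  # grooming/resting bout duration, minutes
    bout_max: float = 10.0
    random_walk_duration: float = 1.0  # minutes
    random_walk_turn: float = 30.0  # max |turn| per substep, degrees
    max_move_duration: float = 2.0  # directed bouts re-decide after this long
    flee_stop_dist: float = 5.0  # flee/avoid/leave until beyond this
    grouping_stop_dist: float = 10.0  # grouping approach stops at this range
    winner_delay: float = 0.25  # winner rescheduled this soon after a fight
    bystander_delay: float = 0.1  # nearby agents react this soon after a fight
    observe_fight_dist: float = 20.0
    schedule_mean: float = 1.0  # routine inter-activation interval, minutes
    schedule_sd: float = 0.05
    schedule_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.move_speed <= 0 or self.move_substep <= 0:
            raise ValueError("movement parameters must be positive")
        if not 0 < self.bout_min <= self.bout_max:
            raise ValueError("bout duration bounds must satisfy 0 < min <= max")


@dataclass(frozen=True)
class RunConfig:
    variant: str = "dynamic"  # dynamic | fixed
    lps: float = 0.0
    n_agents: int = 20
    dom_vector: tuple[float, ...] = field(default_factory=default_doms)
    burn_in: float = 21_600.0  # minutes
    run_length: float = 504_000.0  # minutes after burn-in
    record_window: float = 252_000.0  # final stretch used for statistics
    seed: int = 0
    replicates: int = 10
    like_l0: float = 0.243
    like_ls: float = 0.36
    world: WorldConfig = field(default_factory=WorldConfig)
    affect: AffectParams = field(default_factory=AffectParams)
    selectivity: SelectivityParams = field(default_factory=SelectivityParams)
    salience: SalienceTable = field(default_factory=SalienceTable)
    calendar: Calendar = field(default_factory=Calendar)
    engine: EngineParams = field(default_factory=EngineParams)

    def __post_init__(self) -> None:
        if self.variant not in ("dynamic", "fixed"):
            raise ValueError("variant must be 'dynamic' or 'fixed'")
        if not 0.0 <= self.lps < 1.0:
            raise ValueError("lps must lie in [0, 1)")
        if self.n_agents < 2:
            raise ValueError("need at least two agents")
        doms = np.asarray(self.dom_vector, dtype=float)
        if len(doms) != self.n_agents:
            raise ValueError("dom_vector length must equal n_agents")
        if np.any(np.diff(doms) <= 0):
            raise ValueError("dominance values must be strictly increasing")
        if np.any(doms <= 0) or np.any(doms > 1):
            raise ValueError("dominance values must lie in (0, 1]")
        if self.record_window > self.run_length:
            raise ValueError("record_window cannot exceed run_length")
        if self.burn_in < 0 or self.run_length <= 0:
            raise ValueError("durations must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.selectivity.lps != self.lps:
            object.__setattr__(
                self,
                "selectivity",
                dataclasses.replace(self.selectivity, lps=self.lps),
            )

    @property
    def horizon(self) -> float:
        """End of simulated time: burn-in plus the experiment length."""
        return self.burn_in + self.run_length

    @property
    def record_start(self) -> float:
        return self.horizon - self.record_window

    @property
    def n_intervals(self) -> int:
        n = self.record_window / self.calendar.sample_interval
        k = int(round(n))
        if abs(n - k) > 1e-9 or k < 1:
            raise ValueError(
                "record_window must be a whole number of sample intervals"
            )
        return k

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def scaled_down(
        self, burn_in_weeks: float = 1.0, window_weeks: float = 8.0
    ) -> "RunConfig":
        """Desk-scale variant: short burn-in, short recording window."""
        week = self.calendar.week
        return self.replace(
            burn_in=burn_in_weeks * week,
            run_length=window_weeks * week,
            record_window=window_weeks * week,
        )

    # -- serialization --

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "lps": self.lps,
            "n_agents": self.n_agents,
            "dom_vector": list(self.dom_vector),
            "burn_in": self.burn_in,
            "run_length": self.run_length,
            "record_window": self.record_window,
            "seed": self.seed,
            "replicates": self.replicates,
            "like_l0": self.like_l0,
            "like_ls": self.like_ls,
            "world": dataclasses.asdict(self.world),
            "affect": dataclasses.asdict(self.affect),
            "selectivity": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(self.selectivity).items()
                    if k != "base"
                },
                "base": dict(self.selectivity.base),
            },
            "salience": {k: list(v) for k, v in self.salience.deltas.items()},
            "calendar": dataclasses.asdict(self.calendar),
            "engine": dataclasses.asdict(self.engine),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kw: dict = {}
        for key in (
            "variant",
            "lps",
            "n_agents",
            "burn_in",
            "run_length",
            "record_window",
            "seed",
            "replicates",
            "like_l0",
            "like_ls",
        ):
            if key in d:
                kw[key] = d[key]
        if "dom_vector" in d:
            kw["dom_vector"] = tuple(d["dom_vector"])
        elif "n_agents" in d:
            kw["dom_vector"] = default_doms(d["n_agents"])
        if "world" in d:
            kw["world"] = WorldConfig(**d["world"])
        if "affect" in d:
            kw["affect"] = AffectParams(**d["affect"])
        if "selectivity" in d:
            kw["selectivity"] = SelectivityParams(**d["selectivity"])
        if "salience" in d:
            table = dict(DEFAULT_SALIENCE)
            table.update({k: tuple(v) for k, v in d["salience"].items()})
            kw["salience"] = SalienceTable(table)
        if "calendar" in d:
            kw["calendar"] = Calendar(**d["calendar"])
        if "engine" in d:
            kw["engine"] = EngineParams(**d["engine"])
        return cls(**kw)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
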