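"""Run orchestration: group initialization, single runs, the LPS sweep.

Every output bundle is reproducible from (config, seed): the config is
echoed next to the matrices, and replicate seeds are derived
deterministically from the base seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LPS_SWEEP, RunConfig, dump_config
from .engine import LOGGED_BEHAVIORS, Simulation
from .observation import RateMatrices, window_rates, yearly_average
from .socstats import summarize_run

__all__ = [
    "OutputBundle",
    "init_group",
    "run_simulation",
    "run_sweep",
    "derive_seed",
    "write_bundle",
    "load_matrices",
]


def init_group(cfg: RunConfig, seed: int | None = None) -> Simulation:
    """Initialized (but not yet run) simulation for the given config."""
    return Simulation(cfg, seed=seed)


@dataclass
class OutputBundle:
    """Everything a single run produces."""

    config: RunConfig
    seed: int
    matrices: RateMatrices
    fear: np.ndarray
    summary: dict
    sim: Simulation | None = field(default=None, repr=False)


def run_simulation(
    cfg: RunConfig,
    seed: int | None = None,
    outdir: str | Path | None = None,
    keep_sim: bool = False,
) -> OutputBundle:
    """Execute one run and compute its window-averaged matrices and stats."""
    used_seed = cfg.seed if seed is None else seed
    sim = Simulation(cfg, seed=used_seed)
    sim.run()
    per_interval = window_rates(
        sim.log,
        cfg.record_start,
        cfg.n_intervals,
        cfg.calendar,
        cfg.n_agents,
        LOGGED_BEHAVIORS,
    )
    matrices = yearly_average(per_interval, sim.prox_samples, sim.like_samples)
    doms = np.asarray(cfg.dom_vector)
    summary = {
        "seed": used_seed,
        "variant": cfg.variant,
        "lps": cfg.lps,
        "n_agents": cfg.n_agents,
        "n_intervals": cfg.n_intervals,
        "n_events": len(sim.log),
        "mean_emotions": {
            k: float(v)
            for k, v in zip(
                ("arousal", "anxiety", "satisfaction"),
                np.mean(np.stack(sim.emotion_samples), axis=0),
            )
        },
        "stats": summarize_run(
            matrices.rates, matrices.proximity, matrices.like_mean, doms
        ),
    }
    bundle = OutputBundle(
        config=cfg,
        seed=used_seed,
        matrices=matrices,
        fear=sim.attitudes.fear.copy(),
        summary=summary,
        sim=sim if keep_sim else None,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def _matrix_frame(m: np.ndarray, n: int) -> pd.DataFrame:
    ids = [f"a{i:02d}" for i in range(n)]
    return pd.DataFrame(m, index=ids, columns=ids)


def write_bundle(bundle: OutputBundle, outdir: str | Path) -> Path:
    """Write CSV matrices, a JSON summary and a config echo."""
    outdir = Path(outdir)
    matdir = outdir / "matrices"
    matdir.mkdir(parents=True, exist_ok=True)
    n = bundle.config.n_agents
    for name, m in bundle.matrices.rates.items():
        _matrix_frame(m, n).to_csv(matdir / f"{name}.csv")
    _matrix_frame(bundle.matrices.proximity, n).to_csv(matdir / "proximity.csv")
    _matrix_frame(bundle.matrices.like_mean, n).to_csv(matdir / "like.csv")
    _matrix_frame(bundle.fear, n).to_csv(matdir / "fear.csv")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle.summary, fh, indent=2, allow_nan=True, default=float)
    dump_config(bundle.config, outdir / "config.yaml")
    return outdir


def load_matrices(matdir: str | Path) -> dict[str, np.ndarray]:
    """Read back the CSV matrices of one bundle."""
    out = {}
    for path in sorted(Path(matdir).glob("*.csv")):
        out[path.stem] = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
    return out


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic replicate seed from the base seed and a run index."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def run_sweep(
    base_cfg: RunConfig,
    outdir: str | Path,
    variants: tuple[str, ...] = ("dynamic", "fixed"),
    lps_values: tuple[float, ...] = LPS_SWEEP,
    replicates: int | None = None,
    progress: bool = False,
) -> dict:
    """Cross product {variants} x {lps} x {replicates}, one bundle each.

    Runs whose summary already exists on disk are skipped (resume).  A
    top-level JSON aggregates the per-run statistics into per-condition
    means and SDs across replicates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reps = base_cfg.replicates if replicates is None else replicates
    records = []
    index = 0
    for variant in variants:
        for lps in lps_values:
            for rep in range(reps):
                seed = derive_seed(base_cfg.seed, index)
                index += 1
                run_dir = outdir / f"{variant}_lps{lps:g}_rep{rep}"
                summary_path = run_dir / "summary.json"
                if summary_path.exists():
                    with open(summary_path) as fh:
                        summary = json.load(fh)
                else:
                    cfg = base_cfg.replace(variant=variant, lps=lps, seed=seed)
                    bundle = run_simulation(cfg, outdir=run_dir)
                    summary = bundle.summary
                if progress:
                    print(f"done {run_dir.name}")
                records.append(summary)
    aggregate = _aggregate(records)
    with open(outdir / "sweep_summary.json", "w") as fh:
        json.dump(aggregate, fh, indent=2, allow_nan=True, default=float)
    return aggregate


def _aggregate(records: list[dict]) -> dict:
    """Per-condition mean and SD of every statistic across replicates."""
    grouped: dict[tuple, list[dict]] = {}
    for rec in records:
        grouped.setdefault((rec["variant"], rec["lps"]), []).append(rec)
    out = {"conditions": []}
    for (variant, lps), recs in grouped.items():
        cond: dict = {"variant": variant, "lps": lps, "replicates": len(recs)}
        measures: dict[str, dict[str, dict[str, float]]] = {}
        names = recs[0]["stats"].keys()
        for name in names:
            measures[name] = {}
            for stat in recs[0]["stats"][name]:
                vals = np.array(
                    [r["stats"][name][stat] for r in recs], dtype=float
                )
                vals = vals[~np.isnan(vals)]
                measures[name][stat] = {
                    "mean": float(vals.mean()) if vals.size else float("nan"),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    "n": int(vals.size),
                }
        cond["stats"] = measures
        out["conditions"].append(cond)
    return out
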