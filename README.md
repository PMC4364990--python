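# emosim

Event-driven, spatially explicit agent-based simulator of a primate-like
social group.  Twenty agents live on a continuous 300 m × 300 m torus;
their behaviour is regulated by three general emotional dimensions
(arousal, anxiety, satisfaction) and by partner-specific attitudes: a
fixed FEAR (the dominance difference) and a LIKE in [0, 1].  In the
**dynamic** variant LIKE integrates grooming received from each partner
through a history-weighted running update ("emotional bookkeeping"); in
the **fixed** control variant LIKE is a fixed decreasing function of
absolute rank distance.  The parameter **LPS** (LIKE-partner
selectivity, in [0, 1)) controls how strongly LIKE biases affiliative
partner choice; at LPS = 0 both variants are provably identical
(bit-identical event logs under a shared seed).

The package also implements the observation protocol (directed hourly
rate matrices per behaviour over 3.5-day recording intervals, one–zero
proximity sampling, yearly averaging with burn-in exclusion) and the
social-matrix statistics used to analyse the output: rowwise Kendall
Tau-Kr reciprocity, Shannon/Buzas–Gibson evenness H\*, rank-distance
categorization, partner-specificity SD, and rowwise Pearson
predictability pooled by Fisher-z.

## Layout

| module                | contents                                                                  |
| --------------------- | ------------------------------------------------------------------------- |
| `emosim.world`        | torus geometry, view cones, candidate selection, the activation queue     |
| `emosim.affect`       | emotional kinetics, salience table, FEAR/LIKE/PARTNER\_SAT bookkeeping    |
| `emosim.behavior`     | action-selection weights (incl. LPS), contests, movement, bouts           |
| `emosim.engine`       | the discrete-event loop tying the above together                          |
| `emosim.observation`  | calendar, event log, interval/yearly rate matrices, proximity sampling    |
| `emosim.socstats`     | Tau-Kr, H\*, rank-distance classes, partner-specificity SD, Fisher-z      |
| `emosim.config`       | `RunConfig` (every model constant), YAML round-trip                       |
| `emosim.experiment`   | group initialization, single runs, the variant × LPS sweep                |
| `emosim.cli`          | the `emosim` command                                                      |

## CLI

```bash
emosim validate --config cfg.yaml
emosim run    --config cfg.yaml --seed 17 --out out/run1/
emosim sweep  --config cfg.yaml --out out/sweep/        # variants x LPS x replicates
emosim stats  --matrices out/run1/matrices --out summary.json
```

A run directory contains one CSV matrix per behaviour (rows/columns
ordered by ascending dominance), `proximity.csv`, `like.csv`,
`fear.csv`, a `summary.json` with the per-run statistics, and a
`config.yaml` echo that reproduces the run exactly when fed back with
the same seed.

Default full-scale settings (21,600-minute burn-in, 504,000-minute
horizon, final 252,000 minutes recorded) are expensive; for desk-scale
work use `RunConfig().scaled_down()` (1-week burn-in, 8-week window,
~25 s per run), which is what the test suite uses.

```python
from emosim import RunConfig, run_simulation

cfg = RunConfig(variant="dynamic", lps=0.99).scaled_down()
bundle = run_simulation(cfg, seed=1)
print(bundle.summary["stats"]["groom"]["taukr"])
```

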