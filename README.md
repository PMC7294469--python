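# foragesim

Simulation and analysis of **probabilistic traveling-salesman foraging**:
how a forager in an open arena should (and does) route itself through a
handful of food locations when it only has probabilistic knowledge of
where the food will be.

Rats foraging for pellet clusters in a 2.5 m × 1 m arena face a fixed-start
*open* TSP — start at the entrance, visit every pellet once, no return leg
— under three levels of placement predictability: repeated, slowly
drifting, and actively randomized placements. The package provides all of
the computational layers of that experiment:

- **`foragesim.distributions`** — synthetic pellet-placement sequences of
  controlled predictability, with matched optimal path lengths across
  levels, quantified by the across-trial minimum distance metric and the
  relative entropy (KL divergence, bits) of each trial's smoothed pellet
  density against its pooled history.
- **`foragesim.routes`** — the routing layer: an exhaustive oracle, a
  genetic algorithm (groups-of-four selection, flip/swap/slide mutations),
  the nearest-neighbor heuristic, and the efficiency metric
  `fe = lo / la` (optimal over actual path length).
- **`foragesim.agent`** — a Bayesian searcher on the 40 × 80 occupancy
  grid that steps greedily toward the maximum of

  ```
  p(x, y) = sw · s(x, y) + (1 − sw) · m(x, y)
  m(x, y) = pe(x, y) · (max d − d(x, y)) / max d
  s(x, y) = cr(x, y) · ((max d − d(x, y)) / max d)^se
  ```

  where `pe` is the mean pellet occupancy over the last `md` trials
  (memory depth, possibly cumulative), `cr` marks current pellet cells,
  `d` is distance from the agent, `sw ∈ [0, 1]` weights sensing against
  memory and `se ≥ 0` sets how fast sensory evidence decays with
  distance. Detection is perfect at the agent's location: arriving at a
  targeted cell either collects its pellet or zeroes that cell's
  probability.
- **`foragesim.fitting`** — grid fitting of `(sw, se, md)` to
  trial-by-trial path lengths (Pearson correlation), plus the derived
  sensory-acuity index `sa = (1 − se/max(SE) + sw)/2` and
  long-term-memory-usage index
  `mi = (max pr − mean pr(md<3)) / (max pr − min pr)`, and the
  shuffled-prior performance ratio.
- **`foragesim.metrics`** — behavioral read-outs on trajectories:
  nearest-pellet probability, per-pellet ordering error vs a
  nearest-neighbor order, long-range segment efficiency, and speed/pause
  statistics (a pause is speed < 1 cm/s).

## Worked example

```python
import foragesim as fs

seq = fs.generate_sequence("high", n_sessions=12, seed=1,
                           snap_to_grid=True, resample_scatter=True)
agent = fs.AgentParams(sw=0.25, se=8.0, md=None)   # memory-reliant searcher
series = fs.performance_series(seq, agent, start_trial=19)
fit = fs.fit_parameters(series, seq, grid_spec=fs.COARSE_GRID)
print(fit.best_params, round(fit.best_r, 3))
```

prints

```
AgentParams(sw=0.25, se=8.0, md=None) 1.0
```

— the grid scan recovers the generating parameters exactly (correlation
1.0), because the searcher is deterministic given its inputs. The
numbered drivers under `analysis/` run the full studies; for example
`python analysis/05_cohort_effects.py` simulates four subjects in each
predictability cohort, fits each one, and prints

```
high  : RE 5.20 bits, sa 0.125, mi 0.796
medium: RE 6.01 bits, sa 0.625, mi 0.494
low   : RE 10.88 bits, sa 0.812, mi 0.250
Across subjects, sensory acuity rises with training-set entropy (r = 0.78)
while long-term memory usage falls (r = -0.74).
```

i.e. as placements become less predictable, the best-fitting searchers
weight sensing more and long-term memory less, and a wrong prior stops
mattering. `analysis/02_route_benchmarks.py` verifies the solver stack: a
seven-pellet trial admits 5040 acquisition orders, the genetic algorithm
matches the exhaustive oracle, and the nearest-neighbor heuristic lands
within a few percent of optimal.

## Command line

A thin CLI mirrors the pipeline stages:

```bash
foragesim generate --level low --sessions 12 --seed 0 --out pellets.csv
foragesim solve    --pellets pellets.csv --trial 1 --method ga --out route.csv
foragesim simulate --pellets pellets.csv --params sw=0.5,se=8,md=cum \
                   --start-trial 19 --out perf.csv
foragesim fit      --pellets pellets.csv --target perf.csv --grid coarse --out fit.json
foragesim pipeline --out run/
```

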