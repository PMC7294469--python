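# Methods

## Arena and grid

The arena is a 250 × 100 cm rectangle with the entry point at the
midpoint of a short wall, (0, 50). All model computations happen on a
fixed 40-row × 80-column occupancy grid; the grid *shape* is primitive
and cell extents are derived from it (3.125 cm × 2.5 cm). A nominal
square cell size is not geometrically consistent with the arena's aspect
ratio, and nothing in the model depends on cells being square — distances
are always measured between cell centers in continuous centimeters.

## Synthetic pellet placements

Each trial scatters pellets in Gaussian clusters (default 3 clusters,
2–3 pellets each, scatter SD 12 cm, cluster centers uniform with a 20 cm
wall margin; a `paper_mean7` preset fixes the per-trial total at 7).
Draws are rejected until no two pellets share a grid cell. Three
predictability levels:

- **high** — one placement repeated identically on every trial;
- **medium** — cluster centers follow a Gaussian random walk between
  sessions (default step SD 5 cm/session), the placement translating with
  them; trials within a session are identical;
- **low** — a fresh placement each trial, accepted only when every
  pellet lies at least `min_shift_cm` (default 20 cm) from all pellets of
  the previous trial.

The drift SD and minimum shift are free design constants (no empirical
values exist for them); the defaults produce a strict ordering of the
across-trial minimum distance metric (0 ≪ few cm ≪ tens of cm).

Every accepted placement must have an optimal open-path length within
±15% of 250 cm, so all levels pose routes of matched difficulty. The
250 cm target is the median optimal length of unconstrained 3-cluster
draws in this arena, measured once when the generator was designed; the
tolerance keeps rejection sampling fast while holding the spread of
optimal lengths well below the spread of the heuristics being compared.

`resample_scatter` changes `high`/`medium` from verbatim repetition to a
**stationary (or drifting) distribution realized afresh each trial**:
cluster centers stay fixed (or drift), but pellet counts and scatter are
redrawn per trial. This emulates an automated dispenser drawing from a
consistent distribution — the forager can predict *where clusters are*
but never the exact coordinates or count. The simulation studies use
this mode for the predictable cohorts because under verbatim repetition
every memory window yields the same prior, making memory depth
unidentifiable; with per-trial realizations, deeper memory genuinely
helps (it averages over realizations of the stationary distribution).

`snap_to_grid` projects pellets onto the centers of their containing
cells and orders them row-major. The search agent operates on the grid,
so snapped instances make agent-level comparisons (e.g. against the
nearest-neighbor route) exact rather than subject to sub-cell
quantization; generation, metrics and solvers all work with continuous
coordinates as well.

## Predictability metrics

The across-trial minimum distance reports, for each pellet, the distance
to the nearest pellet of the immediately preceding trial. Relative
entropy is the KL divergence RE(P‖Q) = Σ P log2(P/Q) in bits between the
current trial's smoothed pellet density (P) and the density pooled (with
equal weight) over all previous trials (Q). Densities are per-cell
counts passed through a box filter and normalized; a filter width below
one cell rounds up to a single cell, i.e. no smoothing, since sub-cell
convolution is a no-op on this grid. Both densities are floored at
1e−9 per cell and renormalized so the divergence is defined when Q
vanishes somewhere; the floor changes RE(P‖P) by strictly less than
1e−4 bits. The cohort analyses compute RE with a 12 cm filter (the
cluster scale), which measures cluster-level rather than cell-level
surprise and separates the stationary-cluster cohorts from the
randomized one much more cleanly.

## Route solvers

Open fixed-start TSP, no return leg. The exhaustive oracle enumerates
all permutations (guarded at 10 pellets; ties broken lexicographically).
The genetic algorithm follows the classic open-TSP recipe: a population
of random orders (default 80) is shuffled into groups of four each
generation; the group's shortest member survives and seeds three mutants
— segment reversal (flip), endpoint swap, and slide — with an elite
fraction (5%) carried over unchanged, so the best length is monotone.
Termination: generation cap (2000), stall (500 generations without
improvement), or reaching the instance lower bound (distance to the
farthest pellet) within 1e−6. On 100 random 7-pellet instances the GA
matches the oracle in ≥ 95 (observed: 100). The nearest-neighbor
heuristic breaks distance ties toward the lowest pellet index.

## Search agent

State: continuous position (start at the arena entry), the set of
uncollected pellets, and the set of cells already found empty. Each
step the agent rebuilds the combined map p = sw·s + (1−sw)·m (both the
memory discount and the sensory decay depend on its current position),
zeroes visited-empty cells, and steps a fixed distance (default one cell
diagonal, ≈ 4 cm) along the straight line toward the argmax cell center,
landing on it when closer than one step. Argmax ties resolve to the
nearest cell, then row-major order — all behavior is deterministic.

*Detection* is perfect at the agent's location and is applied on arrival
at the **targeted** cell center: any pellet in that cell is collected,
otherwise the cell's target probability is set to zero for the rest of
the trial. Applying detection at the targeted cell (rather than every
cell grazed mid-leg) is what makes the sw=1, se=0 limit an *exact*
nearest-neighbor search.

Degenerate case: when the combined map is identically zero (a memory-only
agent whose remembered cells are exhausted), the agent sweeps
systematically — uniform probability over unvisited cells, i.e. always
the nearest unvisited cell. A deadlock is not acceptable; the sweep
means such an agent still finds everything, just at a path length an
order of magnitude above optimal. Trials are capped at 10× the number
of grid cells steps and report a partial result if capped.

The prior window is L = max(t − md, 1): `md = 1` uses only the previous
trial, cumulative memory (md = None) averages all previous trials. The
prior is built only from true past pellet placements, as the occupancy
average implies. For efficiency the trial loop evaluates the map only on
its support (prior cells ∪ pellet cells — everywhere else p is exactly
zero); the test suite verifies this against a full-grid composition of
the public map operations, step for step.

## Fitting and derived indices

Trial-by-trial performance is the per-trial total path length of the
searcher. Fits scan a coarse grid — default
sw ∈ {0, 0.1, …, 1}, se ∈ {0.5, 1, 2, 4, 8, 16, 32},
md ∈ {1, 2, 3, 5, 10, cumulative}; the simulation studies use the
reduced grid sw ∈ {0, .25, .5, .75, 1}, se ∈ {0.5, 2, 8, 32},
md ∈ {1, 2, cum} — scoring each point by the Pearson correlation with
the target series. Zero-variance series score as missing and can never
win; exact ties break toward smaller sw, then se, then md (cumulative
last). Combinations that cannot differ behaviorally (se at sw = 0, md at
sw = 1) are simulated once and shared. Spearman is deliberately not the
default: path lengths are already on a common scale and the target
series come from the same deterministic process.

Sensory acuity `sa = (1 − se/max(SE) + sw)/2` normalizes the fitted
decay exponent by the maximum across the cohort's best fits — the
reading that maps the set SE to a scalar and bounds sa in [0, 1]; sa
rises with sensory weight and with sensing range. Memory usage
`mi = (max pr − mean pr(md ∈ {1,2})) / (max pr − min pr)` over the
fitted pr-by-md profile; a flat profile defines mi = 0.

The shuffled-prior ratio divides the mean path length obtained with a
*donor* sequence's history as prior by the mean with the sequence's own
history. It is evaluated with each cohort's own typical parameters —
what a per-animal fit would supply — because a randomized-cohort
searcher weights its prior so little that the ratio pins to 1, whereas a
memory-reliant searcher on repeated placements pays heavily for a wrong
prior; a single generic parameter set instead makes the ratio hostage to
rare cross-arena memory chases.

## Study designs and problem sizes

The simulation studies run 12 sessions × 3 trials (36 trials) per
sequence and evaluate from trial 19, giving every fit an 18-trial series
with at least six sessions of prior experience; these sizes keep the
full grid scans comfortably fast while leaving the priors well formed.

- *Route benchmark*: 100 uniform 7-pellet instances; GA (fresh seed per
  instance) vs oracle vs nearest neighbor.
- *Sensory limit*: 100 instances on distinct grid-cell centers; the
  sw=1, se=0 agent must reproduce the nearest-neighbor order exactly.
- *Parameter recovery*: 20 subjects on drifting (per-trial resampled)
  sequences, ground truths drawn from the reduced grid with
  sw ∈ {0.25, 0.5, 0.75} only — at sw = 0 the sensory exponent, and at
  sw = 1 the memory depth, do not enter behavior at all, so boundary
  draws would be graded on structurally unidentifiable parameters.
- *Cohort effects*: 4 subjects per cohort behaving with cohort-typical
  parameters — high: (sw .25, se 8, cumulative md); medium:
  (.5, 2, md 2); low: (.75, 0.5, md 1) — i.e. predictable environments
  are foraged memory-first with short-range sensing, unpredictable ones
  sensing-first with shallow memory. Each subject is grid-fitted; sa
  uses the cohort-wide SE set, mi the fitted pr-by-md profile, and both
  are related to the 12 cm-smoothed RE of the training placements.

## What the synthetic data do and do not show

Synthetic subjects *are* the model: their series contain no behavioral
noise, so recovery fits reach correlation 1.0 at the generating grid
point and recovery rates near 100% are expected, not remarkable. What
the studies establish is internal consistency — identifiability of the
grid over these designs, the direction of the sa/mi/prior effects, and
the exactness of the solver and limit equivalences. Real foraging data
add measurement noise, trial-to-trial behavioral variability, sensory
fields that are not radially symmetric, and paths that are not
piecewise-straight; correlations fit to animals will be far below 1 and
recovery of any "true" animal parameters is not implied. Odor/visual
physics enters only through the single decay exponent se; trajectory
metrics assume complete, inside-arena tracking.
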