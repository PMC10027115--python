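# Methods

## The calibration problem

Settings-file-driven agent-based simulators expose parameters through a
configuration document and report results as output snapshots. `cellcalib`
treats such a simulator as a black box `params → metric vector` and
minimizes an error metric between that vector and target data over a
two-parameter search space. The three stages — settings update, run,
output reduction — are composed explicitly so any of them can be replaced;
a model may also consist of a bare executable (no updater, no processor),
in which case the surrogate "metric" is the output-directory listing.

## Settings schema and validation

The schema models the blocks a parameter study actually edits: simulation
domain (bounds and voxel lengths dx/dy/dz, all > 0), overall clock
(total time and the diffusion/mechanics/phenotype time steps, all > 0),
diffusing substances (diffusion coefficient, decay rate, initial and
Dirichlet boundary conditions, all > 0), and per-cell-type phenotype
blocks: cycle and death (phase durations *or* phase transition rates — a
model is parameterized by exactly one of the two lists, every entry > 0),
volume (positive volumes and rates; fluid and calcified fractions in
[0, 1]), mechanics (positive adhesion/repulsion strengths and relative
maximum adhesion distance), and motility (speed > 0, persistence time > 0,
migration bias in [0, 1]).

Validation runs at parse time and again on every assignment, so a sweep
can never hand the simulator an out-of-range value; violations report the
element path, the offending value and the violated bound. Unmodeled
content (comments, `user_parameters`, options blocks) is kept in the
parsed document and written back untouched; numeric text is only rewritten
when the value actually changed, using the shortest decimal representation
that reparses to the same float, so repeated load→write cycles are exact
fixed points and sweeps lose no precision across levels.

## Multilevel grid sweep

Given an initial center (c₁, c₂), points-per-direction *n*, range fraction
*p* and level count *L*, level *k* (k = 0..L−1) evaluates the black box on
the grid `linspace(cᵢ(1 − p·γᵏ), cᵢ(1 + p·γᵏ), n)` per axis (endpoints
inclusive, clipped below at the parameter's lower bound, default 0), and
recenters on the cell with minimum error. Design choices where the
procedure is genuinely open:

* **Geometric shrinkage** γ (default 0.5): a constant range cannot refine,
  so the range fraction is multiplied by γ each level; γ is exposed on
  `SweepConfig`.
* **Even *n***: the current center is then generally not a grid point;
  this is accepted as-is (an 8 × 8 level has 64 cells, none at the
  center).
* **Tie-break**: first minimum in row-major order (first axis outermost),
  so results are deterministic.
* **Failed cells** (simulator crash, constraint violation such as a
  proposed migration bias > 1): scored +inf with a warning rather than
  aborting the level; only a level with no finite cell aborts.
* **Replicates**: replicate *i* of a cell runs with seed `seed + i` in its
  own workspace; the per-cell error is computed on the mean metric vector
  across replicates (median available). Aggregation lives in the sweep,
  not the black box, which stays a pure map.
* **Common random numbers**: every grid cell is evaluated with the same
  base seed, across levels too. For runners that are deterministic given
  the seed this makes the error surface a deterministic function of the
  parameters (and the whole sweep bitwise reproducible); when the target
  was generated with the same seed the surface has an exact zero at the
  generating parameters.

Monotone non-increase of the per-level best error is not guaranteed in
general — a refined grid need not contain the previous best point — but
holds in practice on smooth surfaces once the sweep has locked onto the
minimum's basin, and is asserted for the logistic reference problem.

## Error metrics

The objective is the summed squared error Σ(sᵢ − tᵢ)². Time series
(population curves) pair naturally index-by-index. Sets of final cell
positions have no natural pairing, so `quantile_sse` sorts both samples
ascending before summing (equal sizes) or reduces both to 21 empirical
quantiles at 0, 5, …, 100 % (unequal sizes) — a permutation-invariant
quantile-matching comparison. This pairing rule is this package's choice;
other distribution distances would be equally defensible.

## Fixture models

**Logistic growth.** N(t) = K·N₀ / (N₀ + (K − N₀)·e^(−rt)) with defaults
N₀ = 10 agents and an observation grid t = 0, 1, …, 100 min. Deterministic
and instantaneous, giving the calibration loop an exactly identifiable
reference problem. The mock executable reads r, K, N₀ from the settings
file's `user_parameters` block and writes one snapshot per time point with
round(N(t)) cell rows.

**Chemotaxis walk.** 100 cells in a 500 × 500 µm domain, seeded in a
20 µm strip along the low-y wall, with a static linear attractant gradient
pointing +y (the gradient field is an idealization; no reaction–diffusion
is solved — that belongs to the external simulator). Each step (dt =
0.1 min, duration 120 min) a cell's persistent random unit vector ξ is
re-drawn with probability dt/τ (τ = 1 min) and its heading is
d = normalize((1 − b)·ξ + b·ĝ); the displacement is speed·d·dt, clamped at
the walls. b = 0 gives an unbiased persistent random walk, b = 1
deterministic gradient climbing. All random draws are made up front from
the seed, so RNG consumption is parameter-independent: with a fixed seed,
final positions vary smoothly with (speed, b), which is what makes grid
calibration of a stochastic walk well behaved. dt > τ is rejected as an
unstable persistence discretization.

What the fixtures do **not** emulate: cell-cell mechanics, volume and
cycle dynamics, substrate consumption, and the attractant's own dynamics.
Passing calibration tests on the fixtures therefore demonstrates the
correctness of the calibration machinery, not the fidelity of any
particular biological model.

## Identifiability of the chemotaxis example

Calibrating (speed, bias) from final y coordinates alone is structurally
ill-posed in the high-bias regime. Because the heading is normalized, its
y component stays close to 1 for b ≳ 0.5 — even when ξ opposes the
gradient, the normalized blend still points nearly straight up — so the
final-y distribution depends on (speed, b) almost entirely through the
mean drift speed·f(b), with f(0.65) ≈ 0.92 and f(0.9) ≈ 0.997. The error
surface is a long, thin valley along speed·f(b) = const: target data
generated at (2.0 µm/min, 0.9) is matched almost equally well by, e.g.,
(2.16, 0.65) (final-y standard deviation 5.8 µm vs 5.4 µm at the truth).
A greedy shrinking grid started at (2.5, 0.7) settles wherever its first
coarse grid happens to touch the valley and cannot subsequently travel
along it, so it recovers the drift product to ~0.1 % but not the
individual parameters — the expected behaviour for this experiment design,
not an optimizer defect. Recovering both parameters would need data that
breaks the degeneracy: transverse (x) spread, trajectories over time, or a
domain short enough that the population piles up against the far wall.

## Problem sizes and numerics

The logistic reference sweep is 7 levels × 64 cells = 448 evaluations of a
closed-form curve (sub-second); the chemotaxis sweep is 4 levels × 25
cells, each a 1200-step vectorized walk of 100 cells (a few seconds).
Errors are compared with strict `<`, so ties resolve to the first cell in
visiting order; +inf marks failed cells and never wins; grids are built
with `numpy.linspace` so axis endpoints are exact. Seeds are plumbed
end-to-end (CLI `--seed`, default 0, recorded in the run manifest) and
every derived seed is `seed + replicate_index`.
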