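# Methods

## Model

Cells are overdamped self-propelled particles of K types (default two,
"blue" and "orange", 60:40) in a periodic square box. Each step,

    x_i(t + Δt) = x_i(t) + (Δt/η) (P_i + Σ_{j≠i} F_ij),

with friction η = 1, time step Δt = 0.02, and a self-propulsion force
P_i of fixed magnitude |P| = 0.005 whose direction is redrawn uniformly
every 2500 steps with a per-cell phase offset (run-and-tumble motility;
the offset prevents synchronized reorientation). The pair force is the
gradient of a Morse potential

    U(r) = -J(T_i, T_j) [ exp(-r/l_A) - ¼ exp(-r/l_R) ],    l_A = 14, l_R = 0.5,

cut off sharply at r_max = 1.5 and evaluated with the minimum-image
separation (periodic boundaries imply the minimum-image convention; the
cutoff is small relative to the box, so images never interact twice).
The sign convention is chosen so that the long-range term attracts: the
force on i points toward j for r > r* and away below, with the two-cell
equilibrium separation r* ≈ 1.009 (the root of dU/dr, which the tests
pin against an independent Brent bisection). r* sets the effective cell
diameter; all pattern length scales are multiples of it. The adhesion
magnitude J(T_i, T_j) is a symmetric per-type-pair table (J_BB, J_OO,
J_BO), each entry in [0, 0.25].

Coincident cell centers have a finite Morse force but an undefined
direction; the integrator applies the r→0 magnitude along a random
direction (the pure `pair_force` API returns the zero vector instead,
preserving exact antisymmetry).

### Proliferation

When enabled, each cell carries a division clock (initialized uniformly
over one cycle to avoid division waves, mirroring the repolarization
offsets). A cell divides when its clock reaches the cell-cycle duration
(default 80,000 steps) *and* contact inhibition permits it: at most 4
neighbors within r_max. One daughter keeps the mother's position and
heading; the other is placed 0.25 length units away in a random
direction with the opposite heading; both clocks reset. The neighbor
definition reuses r_max because it is the model's only interaction
radius. The "at most 4" gate and the 80,000-step cycle are configurable
(`max_neighbors_for_division`, `cell_cycle_steps`).

### Integration

Forces are accumulated from the current positions for all pairs before
any position moves (synchronous update). The production integrator is a
numba kernel with a per-step cell list (bins ≥ r_max, 3×3 scan) and a
4096-point linear-interpolation table of U'(r)/J over [0, r_max]
(interpolation error ~1e-7 force units — orders of magnitude below |P|).
A readable numpy `step_population` is the reference path; a test checks
one-step agreement to 1e-7. Trajectories are bit-reproducible given the
seed: one master `SeedSequence` derives the initialization stream and
the kernel seed.

## Topological featurization

Per snapshot and per channel (blue cells, orange cells, or all cells),
Vietoris–Rips persistence is computed from plain Euclidean distances,
capped at a maximum filtration of 3.0 (≈ 2 r_max: cell spacing ≈ 1 and
the loop scales of interest sit well below it; the cap also bounds
compute). No established Rips library ships in this environment, so the
package implements persistence directly:

- H0 by union-find over the sorted edge list (merge scale = interval
  end; all starts are 0);
- H1 by GF(2) column reduction of the flag-complex triangle boundary,
  with columns stored as integer bitsets over the sorted edges and
  triangles processed in a simplexwise order keyed by their maximal
  edge. Creative edges never killed by a triangle are essential loops.

A fully independent oracle (`rips_diagrams_bruteforce`) recovers
intervals from persistent-Betti ranks with inclusion–exclusion and is
tested to agree exactly on clouds of ≤ 7 points.

Each connected component that survives to the cap is kept as an interval
ending at the cap (convention `cap`; `drop` removes them). This keeps
the H0 interval count equal to the point count, so component counts stay
visible to the featurization.

**Persistence images.** H0: each interval contributes a 1-D Gaussian of
bandwidth σ weighted by its lifespan. Centering H0 Gaussians at the
interval *start* (the generic image convention) would collapse the whole
image onto one location, because H0 starts are identically zero; this
package therefore centers them at the *end* (the merge scale), which is
what makes the 1-D image informative. H1: intervals are mapped
to (start, persistence) coordinates and contribute isotropic 2-D
Gaussians weighted by lifespan (the lifespan weight is kept rather than
the diagonal distance (end−start)/√2 — a pure rescaling that cannot
affect classification). Defaults: domain [0, 3], 100 pixels (H0), 20×20
pixels (H1), σ = 0.1 filtration units — σ resolves structure at the
inter-cell spacing ≈ 1. Optional max-intensity normalization divides an
image by its peak (idempotent; all-zero images pass through).

**Persistence curves.** At each diagonal parameter t, intervals with
start ≤ t ≤ end contribute their count (Betti curve), summed lifespans
(life curve), or the rectangle integral of a diagonal-distance-weighted
Gaussian (Gaussian curve, computed from normal CDFs).

**Order parameters** (the classical baseline): the density- and
population-normalized pair correlation g(r) between channel pairs
(30 bins over [0, 5]), and the hexatic bond-orientational parameter ψ6
over k = 6 nearest neighbors (mean + 10-bin histogram). These are the
field's canonical radial and angular symmetry measures for labeled
point patterns.

## Embedding, clustering, scoring

Feature matrices (one row per simulation condition) are centered per
column and scaled by one matrix-wide standard deviation before
embedding. Per-column z-scoring is available as a switch but is *not*
the default: persistence-image pixels far from any diagram mass carry
almost pure noise, and giving every pixel unit variance drowns the
signal (on the six-class fixture benchmark, column scaling costs
20–55 accuracy points versus global scaling).

Embeddings to 20 dimensions: PCA (scikit-learn), UMAP (umap-learn,
seeded), or the package's dense autoencoder — symmetric 256–64–20–64–256
architecture, ReLU hidden layers, linear latent and output, full-batch
Adam (lr 1e-3, 400 epochs) on the mean squared reconstruction error.
PHATE is dispatched to its external reference implementation when
installed; it is not re-implemented.

Ward-linkage agglomerative clustering is cut when the number of clusters
reaches the number of distinct ground-truth phases. Accuracy is the
fraction matched under the accuracy-maximizing one-to-one cluster→phase
assignment (Hungarian algorithm; tested against exhaustive permutation
search). The supervised cross-check is an RBF soft-margin SVM at several
C values under seeded stratified 5-fold cross-validation (folds shrink
with a warning when a class is smaller than the fold count).

## Ground truth and fixtures

The phase taxonomy (12 labels i–xii at constant population, 10 labels
v–vii, ix–xv with proliferation) is encoded as an ordered predicate
table over (J_BB, J_OO, J_BO) in `data/regime_rules.json` — editable
data, not code. It transcribes the adhesion-regime boundaries of the
model's phase diagram (e.g. "dispersed" below J ≈ 0.03, intermixed when
both homotypic adhesions exceed the heterotypic one, labyrinths when
the orange–orange adhesion dominates an active heterotypic coupling).
Regime boundaries are genuinely ambiguous — phase classification of
simulated snapshots is ultimately a judgment call — so first-match rule
order resolves boundary triples, and the table is total by construction
(terminal catch-all rules).

The synthetic pattern generator emulates the eight pattern classes
(dispersed, sorted, intermixed, checkerboard, stripes, hexagonal spots,
core–shell, labyrinth) as jittered lattice constructions at unit
spacing. It reproduces the *geometry* of the classes, not the
simulator's kinetics, cluster-size distributions, or boundary roughness;
pipeline tests on fixtures therefore demonstrate that the featurization
and classifier separate idealized architectures, not that the simulator
attains them.

## Desk-scale protocol and what it can show

The full study design is 8 values per adhesion axis (512 triples) at
constant population and 6 values (216 triples) with proliferation, each
run for 5×10⁶ steps. The desk-scale protocol used by the tests and the
acceptance script reduces this to 4 values per axis (64 triples per
sweep: {0, 0.05, 0.13, 0.25} constant, {0.05, 0.09, 0.17, 0.25} with
proliferation — chosen to span every phase of the rule table), 100
initial cells, one replicate, and 2×10⁵ steps. The box is shrunk to
halfwidth 14 so the number density (~0.13 cells/area) matches the full
design, preserving the local pattern scales.

The 25-fold step reduction has a real physical cost: aggregation in
this model is diffusion-limited (run length 0.25 per 2500-step
repolarization, capture radius 1.5), so steady-state patterns take on
the order of 10⁶ steps or more to mature. At 2×10⁵ steps,
constant-population patterns are early-stage — small clusters with
partial sorting — so unsupervised accuracies on the reduced sweep are
limited by pattern maturity rather than by the featurization (an RBF-SVM
trained with the true labels on the same clouds does little better,
which localizes the bottleneck in the point clouds). Proliferation runs
fare relatively better (daughters are born into contact, so clusters
grow locally), and the qualitative conclusions survive the reduction:
max-intensity normalization improves the mean H0 accuracy across
channels, and the orange-only channel (the minority type) classifies
worst. The fixture pipeline, run at full pattern maturity by
construction, reaches ≥ 0.95 accuracy over six classes.

## Numerical details and edge cases

- Largest-remainder rounding converts type fractions to exact counts.
- Rejection sampling enforces the 1.0 minimum initial separation and
  raises a "packing infeasible" error after a bounded attempt budget.
- Simulation capacity with proliferation is preallocated from the
  doubling bound min(N·2^(steps/cycle + 2), 30000); reaching capacity
  suppresses further divisions with a warning.
- Rips tie-breaking: edges ordered by (length, i, j); triangles by the
  rank of their maximal edge; zero-persistence H1 pairs are dropped.
- Empty channels yield empty diagrams/zero feature blocks plus a
  warning, never an exception.
- All randomness flows from explicit seeds; UMAP and the autoencoder are
  reproducible run-to-run on the same machine.

## Known limitations

- Unsupervised accuracies at desk scale are not the full-scale
  accuracies; see above.
- The rule table is a surrogate for manual annotation; near regime
  boundaries its labels are conventions.
- The Rips implementation targets 2-D clouds of up to a few thousand
  points below a small filtration cap; it is not a general-purpose TDA
  engine.
- Order-parameter features implement the canonical g(r)/ψ6 pair, not
  the upstream study's (unavailable) exact definitions.
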