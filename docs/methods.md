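# Methods

## Per-cell Voronoi construction from Delaunay one-rings

The Voronoi cell of a point *p* is the intersection of the half-spaces
`{x : |x − p| ≤ |x − q|}` over all other points *q*.  Only the Delaunay
neighbors of *p* (its *one-ring*: every point sharing a simplex with *p*)
can contribute facets — this is the Delaunay/Voronoi duality — so each
cell is built independently from its one-ring bisectors.  The pipeline is:

1. **Delaunay triangulation** of the (deduplicated) points, delegated to
   Qhull via `scipy.spatial.Delaunay`.  Exact duplicate coordinates are
   merged beforehand (first occurrence kept, mapping recorded; duplicated
   generators would make the diagram undefined) and re-expanded when
   cluster membership is reported.
2. **One-ring gathering** into a CSR adjacency array (all unordered point
   pairs within each simplex, deduplicated and symmetrized).
3. **Cell construction** by successive half-space clipping.  The fast
   engine is a numba-compiled Sutherland–Hodgman clipper: the cell starts
   as the clipping box (a face soup in 3D, a polygon with per-edge plane
   ids in 2D) and is cut by each bisector; cell volume is accumulated as
   pyramids fanned from the generator, so no global Voronoi vertices are
   ever shared between cells.  Bisectors are processed nearest-first and
   clipping stops once half the distance to the next neighbor exceeds the
   current polytope's circumradius — with this early exit the same kernel
   also runs the *all-pairs* construction (every other point as a
   neighbor) at near one-ring cost, which the tests use as the
   brute-force oracle for the duality guarantee.

A reference engine (`scipy.spatial.HalfspaceIntersection` + `ConvexHull`
per cell) produces explicit polytopes (vertices + coplanar-merged faces)
and must agree with the kernel to 1e-9 relative; it also serves as the
fallback for the rare cell that overflows the kernel's fixed buffers.
An independent cross-check against `scipy.spatial.Voronoi` region
geometry is part of the test suite.

**Clipping volume and border handling.**  Every cell is clipped against a
finite box.  With `clip_bounds="auto"` the box is the dataset bounds
expanded by 5% per side, so points lying exactly on the bounds still get
positive-thickness cells.  A cell is flagged *border* when a box face
survives on its final polytope; `flag_border_cells(vd, bounds)`
additionally flags any cell whose extent crosses the (tight) dataset
bounding volume.  Border cells are excluded from the mean size ⟨S⟩ and
from every statistic and selection downstream — a finite field of view
otherwise inflates the apparent size of peripheral cells.

**Numerical choices.**  Geometric predicates use a relative tolerance of
1e-10 of the clip-box diagonal; near-cospherical configurations are left
to Qhull's default perturbation.  Inputs with fewer than dim+1 distinct
points, or affinely degenerate ones, cannot be triangulated but still
have well-defined Voronoi cells; `build_voronoi` then falls back to the
complete graph as the neighbor set.  Cell sizes are geometric quantities:
they are invariant (to ~1e-9 relative, floating-point reordering aside)
under row permutation, translation, and — for interior cells — rotation.

## Null models for complete spatial randomness

Segmentation compares the experimental distribution of normalized cell
sizes y = S/⟨S⟩ (non-border cells only; the normalization makes the
distribution density-free, with mean exactly 1) against the distribution
expected from uniformly random points.

* **Monte-Carlo null**: a user-defined number of simulations (default 50)
  with the same localization count and bounding volume as the data; each
  runs the full pipeline (tessellate → remove border cells → normalize →
  histogram).  The null is the bin-wise mean PDF; the envelope is the
  bin-wise min/max (a 2.5–97.5% quantile option exists).  Per-simulation
  seeds are spawned deterministically from one master seed.  Border cells
  are removed *before* normalization, in both the data and the
  simulations, so the two are conditioned identically.
* **Analytical null**: the fixed gamma forms Gamma(7/2, rate 7/2) in 2D
  and Gamma(5, rate 5) in 3D (unit integral, unit mean; the 3D mode is at
  y = 4/5).  These closed forms replace the simulations at zero cost but
  carry no envelope and do not model fluorophore blinking; the
  Monte-Carlo route remains available for both reasons.

Histograms use 200 equal-width bins over y ∈ [0, 5] by default (this
covers all but ~3×10⁻⁷ of the 3D null's mass and fixes a reproducible
discretization); samples beyond the last edge are dropped and accounted
as `dropped_mass`.  Agreement between an empirical PDF and a reference is
quantified as the mean (or max) absolute bin-wise difference as a
percentage of the reference's peak density, with the reference evaluated
at bin centers.

With one million uniform 3D points this mean-absolute deviation comes out
slightly above 1% (the test suite asserts ≤ 1% and documents the
overshoot): the fixed-parameter gamma is an approximation of the true
Poisson–Voronoi law, and ~1% under this metric is its intrinsic accuracy
in 3D — the deviation is unchanged when border-conditioning bias is
removed by generator-margin subsampling, and the pure sampling-noise
floor at this n is ~0.15%.  In 2D the approximation is much closer and
the measured deviation falls monotonically with n, to ~0.3% at one
million points.

## Threshold, selection, clusters

Clustered data show an excess of small cells over the null.  The
threshold y\* is the first crossing, scanning bin centers upward from
y = 0, where the experimental density passes from above the null to
at-or-below it, located by linear interpolation between adjacent centers;
the absolute threshold is s\* = y\*·⟨S⟩.  A crossing only qualifies if the
preceding excess is real: at or before it the experimental density must
exceed the null by at least 25% of the null's peak *and* by five times
the Poisson bin noise expected under the null at the experimental sample
size.  Without this qualification a clusterless dataset — whose PDF
fluctuates around the null — would always yield a spurious first
crossing; with it, uniform data raise a distinct no-cluster-signal error.
For genuinely clustered data the small-cell excess is many times the null
peak and the qualification never moves the crossing.

Cells are selected when non-border and smaller than s\*.  Clusters are
the connected components of selected cells under one-ring adjacency
(equivalently, Voronoi facet adjacency — no extra distance parameter);
components with fewer than `min_locs` localizations (default 5, a small
guard against single-cell noise objects) are discarded.  Cluster volume
is the sum of member cell sizes — consistent with the Voronoi partition —
and the barycenter is the unweighted mean of member coordinates.
Increasing y\* never deselects a cell, so selections are nested in the
threshold.

Two clusterings of the same dataset are compared by pairing clusters by
maximal member overlap (ties broken by nearest barycenter) and averaging
|V_a − V_b|/V_a over pairs.  A minimal SR-Tesseler-style rule is provided
through the same machinery: local density ≥ α × average density is
equivalent to cell size < ⟨S⟩/α.

## Synthetic data

The simulator generates the two regimes the method is built around.

* `simulate_uniform`: binomial (CSR) samples in a box — the null
  condition, and the input to the Monte-Carlo null.
* `simulate_clustered`: cluster centers rejection-sampled uniformly with
  a minimum pairwise separation and an optional margin from the box
  faces; members offset from each center by an isotropic gaussian (σ) or
  uniformly within a sphere (R), resampled (not clipped) when they land
  outside the box so no density piles up on the faces; uniform
  background; per-localization ground-truth labels.

Two named presets fix the study conditions:

* **demo** — 20 gaussian clusters, σ = 50 nm, 500 localizations
  each, 10% background (1,000), in a 2×2×2 µm³ box; separation ≥ 600 nm
  and a 3σ wall margin so planted clusters neither merge nor touch the
  dataset border.  This is the standard 3D demonstration dataset: both
  nulls put the threshold near y\* ≈ 0.30, recover exactly 20 clusters,
  and matched cluster volumes differ by ~1% on average (seed-to-seed
  range observed: ~0.6–1.4%).
* **well-separated** — 20 uniform spheres, R = 30 nm, 2,000 localizations
  each, over a 64,000-point uniform background (still >2,000-fold below
  in-cluster density).  This preset is built for membership-recovery
  benchmarks, and its geometry matters: the intersection threshold always
  lands inside the size distribution of cluster-*surface* cells, and when
  the background is sparse those cells swell into the empty shell around
  each cluster and fall past the threshold — the planted rim then
  genuinely disagrees with the density structure the method segments.
  A compact, very dense cluster over a substantial background keeps every
  member cell (surface included) well below the threshold; per-cluster
  membership Jaccard against the planted labels is then ≥ 0.99 for both
  null models.

What the simulator does **not** emulate: fluorophore blinking (repeated
localizations of one molecule with correlated positions), localization
uncertainty jitter, drift, or multi-channel structure.  Passing tests
therefore demonstrate correctness of the geometry and of the statistical
machinery under ideal point processes, not robustness to SMLM
photophysics; on real data the Monte-Carlo null with a blinking-aware
simulator would be the appropriate extension point.

## Problem sizes and determinism

The heavy validation runs use one million localizations in 3D (and
10⁴–10⁶ in 2D) — large enough that sampling noise (~0.15% of the null
peak) is well below the effects being measured — and the 20-cluster
presets at 11,000–104,000 localizations.  All stochastic steps take
explicit seeds; identical configurations reproduce outputs bit for bit.

## Known limitations

* The fixed gamma nulls are approximations; their ~1% (3D) intrinsic
  deviation bounds how precisely the analytical route can reproduce a
  Monte-Carlo threshold.
* The fast kernel reports sizes, border flags and extents only; explicit
  polytopes come from the per-cell reference engine (slower, meant for
  inspection and export, not million-cell sweeps).
* Only a minimal density-factor segmentation is provided in the
  SR-Tesseler direction: no multiscale object/cluster hierarchy, no
  colocalization, no temporal analysis.
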