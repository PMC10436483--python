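# voroclust

Voronoi tessellation and statistical cluster segmentation for
single-molecule localization microscopy (SMLM) point clouds, in 2D and 3D.

SMLM experiments produce tables of molecular coordinates (nanometer
precision) rather than pixel images.  A natural way to quantify the local
density around each molecule is its Voronoi cell: dense regions have small
cells.  `voroclust` provides

* **per-cell Voronoi construction from Delaunay one-rings** — the Delaunay
  triangulation (dual of the Voronoi diagram) supplies, for each point
  *p*, exactly the neighbors whose perpendicular bisectors bound *p*'s
  cell.  Each cell is then built independently by brute-force half-space
  clipping, with no global mesh.  This works for arbitrarily heterogeneous
  point densities, where *k*-nearest-neighbor shortcuts under-sample the
  vicinity.  Volumes, border flags and per-cell extents come from a
  compiled clipping kernel that handles millions of localizations in
  minutes on one CPU; a scipy-based reference engine produces explicit
  cell polytopes and cross-checks the kernel.
* **statistical cluster segmentation** — cells smaller than a threshold
  are selected and grouped into connected components.  The threshold is
  found automatically as the first intersection of the experimental
  normalized cell-size PDF with a null model of complete spatial
  randomness.  Two interchangeable nulls are provided:

  - *Monte-Carlo*: the mean (plus min/max envelope) of the cell-size PDFs
    of simulated uniform datasets with the same number of localizations
    and bounding volume (50 simulations by default);
  - *analytical*: fixed gamma approximations of the Poisson–Voronoi
    normalized cell-size law,

    f₂D(y) = (343/15)·√(7/2π) · y^{5/2} · e^{−7y/2}   (Gamma, shape 7/2, rate 7/2)

    f₃D(y) = (3125/24) · y⁴ · e^{−5y}                 (Gamma, shape 5, rate 5)

    with y = S/⟨S⟩ the cell size normalized by the mean over non-border
    cells.  The analytical null removes the Monte-Carlo cost entirely.

* **a synthetic-data simulator** (uniform and planted-cluster datasets
  with ground-truth labels) and a small CLI (`simulate`, `tessellate`,
  `cluster`, `nullcheck`).

Cells cut by the dataset bounding volume ("border cells") are flagged and
excluded from all statistics to avoid edge effects.

## Worked example

```python
import voroclust as vc

# a 3D dataset with 20 planted gaussian clusters (sigma 50 nm, 500
# localizations each) plus 10% uniform background in a 2x2x2 um^3 box
locs, labels = vc.simulate_clustered(vc.demo_config(seed=0))

res_mc = vc.cluster_localizations(locs, null="monte_carlo", n_sims=50, seed=1000)
res_an = vc.cluster_localizations(locs, null="analytical")
print(res_mc.threshold.y_star, res_an.threshold.y_star)
print(res_mc.n_clusters, res_an.n_clusters)
print(vc.match_clusters(res_mc, res_an).mean_volume_diff_pct)
```

prints

```
0.30240626931383796 0.2981650975026411
20 20
0.6570477012460416
```

Both null models place the normalized-size threshold near y* ≈ 0.30,
recover exactly the 20 planted clusters, and the volumes of matched
clusters differ by ~0.7% on average — the Monte-Carlo simulations can be
replaced by the closed-form null at no cost in segmentation quality.

The same pipeline from the shell:

```bash
voroclust simulate --preset demo --seed 0 --out locs.csv
voroclust cluster locs.csv --null analytical --out clusters.csv
voroclust nullcheck --n 100000 --seed 1
```

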