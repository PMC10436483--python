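"""Synthetic localization datasets: uniform (CSR) and clustered point clouds.

The generator provides the two kinds of data the segmentation method is
built around: complete-spatial-randomness clouds (the null condition) and
planted-cluster datasets with per-localization ground-truth labels, so the
whole pipeline — tessellation, null models, thresholding, cluster recovery
— is testable end to end without any experimental download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .localization_io import Box, LocalizationSet

__all__ = [
    "ClusterSimConfig",
    "simulate_uniform",
    "simulate_clustered",
    "demo_config",
    "well_separated_config",
]

#: label given to background (non-cluster) localizations
BACKGROUND_LABEL = -1


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_uniform(n: int, bounds: Box, seed=None) -> LocalizationSet:
    """``n`` i.i.d. uniform points in ``bounds`` (a binomial/CSR sample)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if bounds.measure <= 0:
        raise ConfigurationError("bounds must have positive measure")
    rng = _rng(seed)
    coords = rng.uniform(bounds.lo, bounds.hi, size=(n, bounds.dim))
    return LocalizationSet(coords, bounds=bounds)


@dataclass
class ClusterSimConfig:
    """Planted-cluster simulation parameters (lengths in nm).

    ``cluster_profile`` is ``"gaussian"`` (``cluster_size`` = isotropic
    sigma) or ``"uniform_sphere"`` (``cluster_size`` = radius).  Cluster
    centers are rejection-sampled uniformly, pairwise at least
    ``min_center_separation`` apart and at least ``center_margin`` from
    every face of ``bounds``.  Member offsets falling outside ``bounds``
    are resampled (truncation without face pile-up).
    """

    n_clusters: int = 20
    cluster_profile: str = "gaussian"
    cluster_size: float = 50.0
    locs_per_cluster: int | tuple = 500
    n_background: int = 1000
    bounds: Box = field(default_factory=lambda: Box([0, 0, 0], [2000.0, 2000.0, 2000.0]))
    min_center_separation: float = 600.0
    center_margin: float = 0.0
    seed: int | None = None
    dim: int = 3

    def counts(self) -> np.ndarray:
        if np.isscalar(self.locs_per_cluster):
            return np.full(self.n_clusters, int(self.locs_per_cluster))
        c = np.asarray(self.locs_per_cluster, dtype=int)
        if c.size != self.n_clusters:
            raise ConfigurationError("locs_per_cluster list length != n_clusters")
        return c


def demo_config(seed=None) -> ClusterSimConfig:
    """20 gaussian clusters (sigma 50 nm, 500 locs each) + 10% background
    in a 2x2x2 um^3 volume — the standard 3D demonstration dataset."""
    return ClusterSimConfig(
        n_clusters=20,
        cluster_profile="gaussian",
        cluster_size=50.0,
        locs_per_cluster=500,
        n_background=1000,
        bounds=Box([0, 0, 0], [2000.0, 2000.0, 2000.0]),
        min_center_separation=600.0,
        center_margin=150.0,   # 3 sigma: planted clusters clear the border
        seed=seed,
        dim=3,
    )


def well_separated_config(seed=None) -> ClusterSimConfig:
    """Compact, very dense clusters for recovery benchmarks: 20 uniform
    spheres (R = 30 nm, 2,000 locs each) over a substantial uniform
    background (64,000 locs; still >2,000-fold below in-cluster density).

    The background must be dense enough that the cells of cluster-surface
    points do not swell into surrounding empty space past the segmentation
    threshold — otherwise the planted labels and the density structure the
    method segments genuinely disagree at the cluster rim.
    """
    return ClusterSimConfig(
        n_clusters=20,
        cluster_profile="uniform_sphere",
        cluster_size=30.0,
        locs_per_cluster=2000,
        n_background=64000,
        bounds=Box([0, 0, 0], [2000.0, 2000.0, 2000.0]),
        min_center_separation=600.0,
        center_margin=200.0,
        seed=seed,
        dim=3,
    )


def _place_centers(cfg: ClusterSimConfig, rng: np.random.Generator) -> np.ndarray:
    lo = cfg.bounds.lo + cfg.center_margin
    hi = cfg.bounds.hi - cfg.center_margin
    if np.any(hi <= lo):
        raise ConfigurationError("center_margin leaves no room for centers")
    centers = np.empty((cfg.n_clusters, cfg.dim))
    budget = 10_000 * cfg.n_clusters
    placed = 0
    while placed < cfg.n_clusters:
        if budget <= 0:
            raise ConfigurationError(
                "could not place cluster centers honoring min_center_separation"
            )
        budget -= 1
        cand = rng.uniform(lo, hi)
        if placed == 0 or np.all(
            np.linalg.norm(centers[:placed] - cand, axis=1)
            >= cfg.min_center_separation
        ):
            centers[placed] = cand
            placed += 1
    return centers


def _sample_offsets(cfg, n, rng):
    if cfg.cluster_profile == "gaussian":
        return rng.normal(0.0, cfg.cluster_size, size=(n, cfg.dim))
    if cfg.cluster_profile == "uniform_sphere":
        v = rng.normal(size=(n, cfg.dim))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = cfg.cluster_size * rng.uniform(size=(n, 1)) ** (1.0 / cfg.dim)
        return v * r
    raise ConfigurationError(f"unknown cluster_profile {cfg.cluster_profile!r}")


def simulate_clustered(cfg: ClusterSimConfig):
    """Generate a clustered dataset with ground-truth labels.

    Returns ``(locs, labels)`` where ``labels[i]`` is the planted cluster
    id of row ``i`` or ``BACKGROUND_LABEL``.  The labels are also attached
    as the ``"label"`` extras column of the returned set.
    """
    if cfg.dim not in (2, 3) or cfg.bounds.dim != cfg.dim:
        raise ConfigurationError("dim must be 2 or 3 and match bounds")
    rng = _rng(cfg.seed)
    centers = _place_centers(cfg, rng)
    counts = cfg.counts()
    parts = []
    labels = []
    for c, (center, n_c) in enumerate(zip(centers, counts)):
        pts = np.empty((n_c, cfg.dim))
        need = np.arange(n_c)
        while need.size:  # resample members landing outside bounds
            cand = center + _sample_offsets(cfg, need.size, rng)
            ok = cfg.bounds.contains(cand)
            pts[need[ok]] = cand[ok]
            need = need[~ok]
        parts.append(pts)
        labels.append(np.full(n_c, c))
    if cfg.n_background:
        parts.append(rng.uniform(cfg.bounds.lo, cfg.bounds.hi,
                                 size=(cfg.n_background, cfg.dim)))
        labels.append(np.full(cfg.n_background, BACKGROUND_LABEL))
    coords = np.vstack(parts)
    labels = np.concatenate(labels)
    locs = LocalizationSet(coords, bounds=cfg.bounds, extras={"label": labels})
    return locs, labels
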