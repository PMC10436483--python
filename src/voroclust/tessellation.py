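"""Delaunay-dual Voronoi tessellation of localization point clouds.

The diagram is built cell by cell: the Delaunay triangulation supplies, for
every point ``p``, its one-ring ``p_n`` (all points sharing a simplex with
``p``).  By Delaunay/Voronoi duality the bisectors of ``p`` with ``p_n``
are exactly the planes bounding ``p``'s Voronoi cell, so each cell is the
intersection of those half-spaces with the clipping box — no global mesh is
ever assembled, which is what makes the construction embarrassingly
parallel and robust to heterogeneous point densities.

Two engines produce identical cells:

* ``"fast"`` — numba bisector-clipping kernels (:mod:`voroclust._clip`);
  volumes, border flags and per-cell extents only.
* ``"reference"`` — per-cell ``scipy.spatial.HalfspaceIntersection`` +
  ``ConvexHull``; slower, but yields explicit polytope geometry and serves
  as the in-package cross-check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, HalfspaceIntersection, QhullError

from . import _clip
from .errors import EmptyInputError, GeometryError, VoroclustError
from .localization_io import Box, LocalizationSet, _stable_dedup

__all__ = [
    "DelaunayComplex",
    "Polytope",
    "VoronoiCell",
    "VoronoiDiagram",
    "build_delaunay",
    "direct_neighbors",
    "construct_cell",
    "build_voronoi",
    "cell_polytope",
    "flag_border_cells",
    "export_cell_table",
    "export_polytope_off",
]

#: relative geometric tolerance used in predicate comparisons
EPS_REL = 1e-10


@dataclass
class DelaunayComplex:
    """Delaunay triangulation plus per-point one-ring adjacency.

    Triangulation is computed on deduplicated points; ``unique_index`` maps
    each triangulated point back to the first original row with those
    coordinates and ``inverse`` maps every original row to its triangulated
    point.
    """

    locs: LocalizationSet
    coords: np.ndarray          # deduplicated points actually triangulated
    unique_index: np.ndarray    # triangulated -> first original row
    inverse: np.ndarray         # original row -> triangulated point
    simplices: np.ndarray
    indptr: np.ndarray          # CSR one-ring adjacency over coords
    indices: np.ndarray

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def one_ring(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]


@dataclass
class Polytope:
    """Explicit convex polytope: vertex coordinates + faces (vertex cycles)."""

    vertices: np.ndarray
    faces: list
    measure: float


@dataclass
class VoronoiCell:
    index: int
    size: float
    is_border: bool
    neighbors: np.ndarray       # points whose bisector contributes a facet
    aabb: Box | None = None
    polytope: Polytope | None = None


@dataclass
class VoronoiDiagram:
    """Per-point Voronoi cell sizes, border flags and adjacency."""

    dt: DelaunayComplex
    bounds: Box                 # clipping box
    sizes: np.ndarray
    is_border: np.ndarray
    aabb_lo: np.ndarray
    aabb_hi: np.ndarray

    @property
    def dim(self) -> int:
        return self.dt.dim

    @property
    def n_cells(self) -> int:
        return self.sizes.size

    @property
    def mean_size(self) -> float:
        """⟨S⟩: mean cell size over non-border cells, nm² / nm³."""
        keep = ~self.is_border
        if not np.any(keep):
            raise EmptyInputError("every cell is flagged border")
        return float(self.sizes[keep].mean())

    def cell(self, i: int, with_polytope: bool = False) -> VoronoiCell:
        """Reconstruct one cell explicitly via the reference engine."""
        cell = construct_cell(
            self.dt.coords, i, self.dt.one_ring(i), self.bounds,
            with_polytope=with_polytope,
        )
        return cell


def _affine_rank(coords: np.ndarray) -> int:
    c = coords - coords.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    scale = s[0] if s.size and s[0] > 0 else 1.0
    return int(np.sum(s > 1e-12 * scale * max(c.shape[0], 1)))


def build_delaunay(locs: LocalizationSet) -> DelaunayComplex:
    """Triangulate a localization set (exact duplicates merged first).

    Raises :class:`GeometryError` when the points are affinely degenerate
    (all collinear in 2D / coplanar in 3D) and :class:`EmptyInputError`
    when fewer than ``dim + 1`` distinct points remain.
    """
    unique_index, inverse = _stable_dedup(locs.coords)
    coords = np.ascontiguousarray(locs.coords[unique_index])
    dim = coords.shape[1]
    if coords.shape[0] < dim + 1:
        raise EmptyInputError(
            f"need at least {dim + 1} distinct points, got {coords.shape[0]}"
        )
    rank = _affine_rank(coords)
    if rank < dim:
        kind = "collinear" if dim == 2 else ("coplanar" if rank == 2 else "collinear")
        raise GeometryError(f"degenerate configuration: points are {kind}")
    try:
        tri = Delaunay(coords)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise GeometryError(f"Delaunay triangulation failed: {exc}") from exc
    simplices = tri.simplices
    # one-ring adjacency: all unordered pairs within each simplex
    m = coords.shape[0]
    pair_i = []
    pair_j = []
    k = dim + 1
    for a in range(k):
        for b in range(a + 1, k):
            pair_i.append(simplices[:, a])
            pair_j.append(simplices[:, b])
    ii = np.concatenate(pair_i).astype(np.int64)
    jj = np.concatenate(pair_j).astype(np.int64)
    lo = np.minimum(ii, jj)
    hi = np.maximum(ii, jj)
    keys = np.unique(lo * np.int64(m) + hi)
    lo = (keys // m).astype(np.int64)
    hi = (keys % m).astype(np.int64)
    src = np.concatenate([lo, hi])
    dst = np.concatenate([hi, lo])
    order = np.argsort(src, kind="stable")
    src = src[order]
    dst = dst[order]
    counts = np.bincount(src, minlength=m)
    indptr = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    untriangulated = np.flatnonzero(np.diff(indptr) == 0)
    if untriangulated.size:
        raise GeometryError(
            f"{untriangulated.size} point(s) absent from the triangulation "
            "(near-degenerate input)"
        )
    return DelaunayComplex(
        locs=locs,
        coords=coords,
        unique_index=unique_index,
        inverse=inverse,
        simplices=simplices,
        indptr=indptr,
        indices=dst,
    )


def direct_neighbors(dt: DelaunayComplex, i: int) -> np.ndarray:
    """One-ring of point ``i``: every point sharing a Delaunay simplex."""
    if not 0 <= i < dt.n_points:
        raise IndexError(f"point index {i} out of range [0, {dt.n_points})")
    return np.sort(dt.one_ring(i))


def _halfspaces(p: np.ndarray, neighbor_pts: np.ndarray, box: Box, tol: float):
    """Rows [normal | -offset] for scipy's A x + b <= 0 convention."""
    dim = p.size
    diffs = neighbor_pts - p
    norms = np.linalg.norm(diffs, axis=1)
    if np.any(norms <= 1e-3 * tol):
        raise GeometryError("coincident generator among neighbors")
    normals = diffs / norms[:, None]
    mids = 0.5 * (neighbor_pts + p)
    offsets = np.einsum("ij,ij->i", normals, mids)
    rows = [np.column_stack([normals, -offsets])]
    for ax in range(dim):
        e = np.zeros(dim)
        e[ax] = 1.0
        rows.append(np.concatenate([e, [-box.hi[ax]]])[None, :])
        rows.append(np.concatenate([-e, [box.lo[ax]]])[None, :])
    return np.vstack(rows)


def _merge_coplanar_faces(hull: ConvexHull, tol: float) -> list:
    """Group hull simplices into maximal planar faces, each a vertex cycle."""
    eqs = hull.equations
    used = np.zeros(len(eqs), dtype=bool)
    faces = []
    pts = hull.points
    dim = pts.shape[1]
    if dim == 2:
        return [list(hull.vertices)]
    for f in range(len(eqs)):
        if used[f]:
            continue
        same = np.all(np.abs(eqs - eqs[f]) <= tol, axis=1)
        used |= same
        verts = np.unique(hull.simplices[same])
        normal = eqs[f, :dim]
        # order around the face centroid
        c = pts[verts].mean(axis=0)
        e = np.zeros(3)
        e[np.argmin(np.abs(normal))] = 1.0
        u = e - e.dot(normal) * normal
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        rel = pts[verts] - c
        ang = np.arctan2(rel @ w, rel @ u)
        faces.append(list(verts[np.argsort(ang)]))
    return faces


def construct_cell(
    coords: np.ndarray,
    i: int,
    neighbors: np.ndarray,
    clip_bounds: Box,
    with_polytope: bool = False,
) -> VoronoiCell:
    """Build one Voronoi cell by intersecting bisector half-spaces.

    ``neighbors`` must contain at least the Delaunay one-ring of ``i``
    (supersets such as "all other points" give the identical cell).  The
    cell is additionally clipped by ``clip_bounds``; ``is_border`` is set
    when a box face contributes a facet of the final polytope.
    """
    coords = np.asarray(coords, dtype=float)
    p = coords[i]
    tol = EPS_REL * clip_bounds.diagonal
    if not np.all((p > clip_bounds.lo + tol) & (p < clip_bounds.hi - tol)):
        raise GeometryError("generating point is not strictly inside the clip box")
    neighbors = np.asarray(neighbors, dtype=np.int64)
    hs = _halfspaces(p, coords[neighbors], clip_bounds, tol)
    try:
        inter = HalfspaceIntersection(hs, interior_point=p.copy())
        hull = ConvexHull(inter.intersections)
    except QhullError as exc:
        raise GeometryError(f"cell construction failed for point {i}: {exc}") from exc
    size = float(hull.volume)  # scipy's "volume" is the area in 2D
    if size <= 0.0:
        raise GeometryError(f"degenerate (zero-measure) cell for point {i}")
    verts = inter.intersections[hull.vertices]
    # planes active on the final polytope: >= dim hull vertices on the plane
    facet_tol = 10.0 * tol
    act = np.abs(verts @ hs[:, :-1].T + hs[:, -1]) <= facet_tol
    active = act.sum(axis=0) >= coords.shape[1]
    n_bisectors = len(neighbors)
    facet_neighbors = neighbors[active[:n_bisectors]]
    is_border = bool(np.any(active[n_bisectors:]))
    poly = None
    if with_polytope:
        faces = _merge_coplanar_faces(hull, facet_tol)
        # faces index into hull.points; re-index into the vertex list
        remap = {v: k for k, v in enumerate(hull.vertices)}
        faces = [[remap[v] for v in face] for face in faces]
        poly = Polytope(vertices=verts, faces=faces, measure=size)
    aabb = Box(verts.min(axis=0) - tol, verts.max(axis=0) + tol)
    return VoronoiCell(
        index=i, size=size, is_border=is_border,
        neighbors=np.sort(facet_neighbors), aabb=aabb, polytope=poly,
    )


def _resolve_clip(locs: LocalizationSet, clip_bounds) -> Box:
    if isinstance(clip_bounds, Box):
        return clip_bounds
    if clip_bounds == "auto":
        # expand so hull points get finite, positive-thickness cells
        return locs.bounds.expanded(0.05)
    raise ValueError("clip_bounds must be a Box or 'auto'")


def build_voronoi(
    locs: LocalizationSet,
    clip_bounds: Box | str = "auto",
    engine: str = "fast",
) -> VoronoiDiagram:
    """Tessellate a localization set: one clipped Voronoi cell per point.

    ``clip_bounds="auto"`` clips against the data bounds expanded by 5% per
    side; cells touching the clipping box are flagged border.  Use
    :func:`flag_border_cells` afterwards to additionally flag cells cut by
    the (tight) dataset bounding volume.
    """
    try:
        dt = build_delaunay(locs)
    except (EmptyInputError, GeometryError):
        # Too few points (or affinely degenerate): the Voronoi diagram is
        # still well defined — use the complete graph as the neighbor set.
        dt = _complete_complex(locs)
    return _voronoi_from_complex(dt, _resolve_clip(locs, clip_bounds), engine)


def _complete_complex(locs: LocalizationSet) -> DelaunayComplex:
    unique_index, inverse = _stable_dedup(locs.coords)
    coords = np.ascontiguousarray(locs.coords[unique_index])
    m = coords.shape[0]
    if m < 1:
        raise EmptyInputError("no points")
    indptr = np.arange(m + 1, dtype=np.int64) * (m - 1)
    indices = np.concatenate(
        [np.delete(np.arange(m, dtype=np.int64), i) for i in range(m)]
    ) if m > 1 else np.empty(0, dtype=np.int64)
    return DelaunayComplex(
        locs=locs, coords=coords, unique_index=unique_index, inverse=inverse,
        simplices=np.empty((0, coords.shape[1] + 1), dtype=np.int64),
        indptr=indptr, indices=indices,
    )


def _voronoi_from_complex(dt: DelaunayComplex, box: Box, engine: str) -> VoronoiDiagram:
    tol = EPS_REL * box.diagonal
    if not np.all((dt.coords > box.lo + tol) & (dt.coords < box.hi - tol)):
        raise GeometryError("clip box must strictly contain every point")
    n = dt.n_points
    if engine == "fast":
        kernel = _clip.voronoi_cells_3d if dt.dim == 3 else _clip.voronoi_cells_2d
        sizes, border, ab_lo, ab_hi, status = kernel(
            dt.coords, dt.indptr, dt.indices, box.lo, box.hi, tol
        )
        border = border.astype(bool)
        bad = np.flatnonzero(status != _clip.STATUS_OK)
        for i in bad:  # rare: buffer overflow -> per-cell reference fallback
            cell = construct_cell(dt.coords, int(i), dt.one_ring(int(i)), box)
            sizes[i] = cell.size
            border[i] = cell.is_border
            ab_lo[i] = cell.aabb.lo
            ab_hi[i] = cell.aabb.hi
    elif engine == "reference":
        sizes = np.empty(n)
        border = np.empty(n, dtype=bool)
        ab_lo = np.empty((n, dt.dim))
        ab_hi = np.empty((n, dt.dim))
        for i in range(n):
            cell = construct_cell(dt.coords, i, dt.one_ring(i), box)
            sizes[i] = cell.size
            border[i] = cell.is_border
            ab_lo[i] = cell.aabb.lo
            ab_hi[i] = cell.aabb.hi
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if np.any(sizes <= 0):
        raise GeometryError("numerical failure: non-positive cell size")
    return VoronoiDiagram(
        dt=dt, bounds=box, sizes=sizes, is_border=border,
        aabb_lo=ab_lo, aabb_hi=ab_hi,
    )


def cell_polytope(vd: VoronoiDiagram, i: int) -> Polytope:
    """Explicit convex polytope (vertices + faces) of cell ``i``."""
    cell = vd.cell(i, with_polytope=True)
    return cell.polytope


def flag_border_cells(vd: VoronoiDiagram, bounds: Box) -> VoronoiDiagram:
    """Flag every cell cut by (or touching) ``bounds``; returns a new diagram.

    Border cells are excluded from ⟨S⟩ and from all statistics downstream,
    preventing the edge effects a finite field of view induces.
    """
    tol = EPS_REL * bounds.diagonal
    crosses = np.any(
        (vd.aabb_lo < bounds.lo + tol) | (vd.aabb_hi > bounds.hi - tol), axis=1
    )
    return dataclasses.replace(vd, is_border=vd.is_border | crosses)


def export_cell_table(vd: VoronoiDiagram, path) -> None:
    """Per-cell CSV: point index, size (nm^dim), border flag, one-ring size."""
    import pandas as pd

    n_neighbors = np.diff(vd.dt.indptr)
    pd.DataFrame(
        {
            "index": np.arange(vd.n_cells),
            "size": vd.sizes,
            "is_border": vd.is_border.astype(int),
            "n_neighbors": n_neighbors,
        }
    ).to_csv(path, index=False)


def export_polytope_off(poly: Polytope, path) -> None:
    """Write a polytope in OFF format (3D only)."""
    if poly.vertices.shape[1] != 3:
        raise VoroclustError("OFF export requires a 3D polytope")
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(poly.vertices)} {len(poly.faces)} 0\n")
        for v in poly.vertices:
            fh.write(f"{v[0]} {v[1]} {v[2]}\n")
        for face in poly.faces:
            fh.write(" ".join([str(len(face))] + [str(v) for v in face]) + "\n")
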