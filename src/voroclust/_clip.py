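"""Half-space clipping kernels for per-cell Voronoi construction.

Each Voronoi cell is built independently: start from the clipping box and
cut it by the perpendicular bisector plane (3D) / line (2D) of the
generating point and each of its Delaunay one-ring neighbors.  Delaunay /
Voronoi duality guarantees the one-ring bisectors are exactly the planes
that can contribute facets, so the result equals the true Voronoi cell
intersected with the box.

The kernels are numba-compiled and volume-oriented: they return the cell
measure, whether any box face survives on the final polytope (the cell
touches the clipping volume), and the cell's axis-aligned extent.  Explicit
polytope geometry for individual cells is produced by the scipy-based
reference path in :mod:`voroclust.tessellation`.

Neighbors are processed nearest-first with an early exit: once half the
distance to the next neighbor exceeds the circumradius of the current
polytope, no remaining bisector can cut it.  This makes the same kernel
efficient both with one-ring neighbors and with the all-pairs neighbor set
used as a correctness oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Buffer limits per cell.  A Poisson-Voronoi 3D cell has ~15.5 faces on
# average; the tail is generously covered.  Overflow is reported via a
# status flag and the caller falls back to the reference construction.
MAXF = 256
MAXV = 128

STATUS_OK = 0
STATUS_OVERFLOW = 1
STATUS_DEGENERATE = 2


# --------------------------------------------------------------------------
# 3D: polyhedron as a soup of convex planar faces
# --------------------------------------------------------------------------

@njit(cache=True)
def _init_box_3d(lo, hi, fv, fn, fid):
    x0, y0, z0 = lo[0], lo[1], lo[2]
    x1, y1, z1 = hi[0], hi[1], hi[2]
    # face 0: x = x0
    fv[0, 0, 0], fv[0, 0, 1], fv[0, 0, 2] = x0, y0, z0
    fv[0, 1, 0], fv[0, 1, 1], fv[0, 1, 2] = x0, y1, z0
    fv[0, 2, 0], fv[0, 2, 1], fv[0, 2, 2] = x0, y1, z1
    fv[0, 3, 0], fv[0, 3, 1], fv[0, 3, 2] = x0, y0, z1
    # face 1: x = x1
    fv[1, 0, 0], fv[1, 0, 1], fv[1, 0, 2] = x1, y0, z0
    fv[1, 1, 0], fv[1, 1, 1], fv[1, 1, 2] = x1, y1, z0
    fv[1, 2, 0], fv[1, 2, 1], fv[1, 2, 2] = x1, y1, z1
    fv[1, 3, 0], fv[1, 3, 1], fv[1, 3, 2] = x1, y0, z1
    # face 2: y = y0
    fv[2, 0, 0], fv[2, 0, 1], fv[2, 0, 2] = x0, y0, z0
    fv[2, 1, 0], fv[2, 1, 1], fv[2, 1, 2] = x1, y0, z0
    fv[2, 2, 0], fv[2, 2, 1], fv[2, 2, 2] = x1, y0, z1
    fv[2, 3, 0], fv[2, 3, 1], fv[2, 3, 2] = x0, y0, z1
    # face 3: y = y1
    fv[3, 0, 0], fv[3, 0, 1], fv[3, 0, 2] = x0, y1, z0
    fv[3, 1, 0], fv[3, 1, 1], fv[3, 1, 2] = x1, y1, z0
    fv[3, 2, 0], fv[3, 2, 1], fv[3, 2, 2] = x1, y1, z1
    fv[3, 3, 0], fv[3, 3, 1], fv[3, 3, 2] = x0, y1, z1
    # face 4: z = z0
    fv[4, 0, 0], fv[4, 0, 1], fv[4, 0, 2] = x0, y0, z0
    fv[4, 1, 0], fv[4, 1, 1], fv[4, 1, 2] = x1, y0, z0
    fv[4, 2, 0], fv[4, 2, 1], fv[4, 2, 2] = x1, y1, z0
    fv[4, 3, 0], fv[4, 3, 1], fv[4, 3, 2] = x0, y1, z0
    # face 5: z = z1
    fv[5, 0, 0], fv[5, 0, 1], fv[5, 0, 2] = x0, y0, z1
    fv[5, 1, 0], fv[5, 1, 1], fv[5, 1, 2] = x1, y0, z1
    fv[5, 2, 0], fv[5, 2, 1], fv[5, 2, 2] = x1, y1, z1
    fv[5, 3, 0], fv[5, 3, 1], fv[5, 3, 2] = x0, y1, z1
    for f in range(6):
        fn[f] = 4
        fid[f] = f
    return 6


@njit(cache=True)
def _clip_by_plane_3d(ax, ay, az, b, plane_id, fv, fn, fid, nf, tol,
                      tmp, cap, cap_ang):
    """Clip the face soup by the half-space a.x <= b.

    Returns (nf, changed, status).  Crossing points are collected and, if
    the plane actually cuts, assembled into a new cap face (id = plane_id).
    """
    ncap = 0
    changed = False
    f = 0
    while f < nf:
        m = fn[f]
        n_in = 0
        for k in range(m):
            d = ax * fv[f, k, 0] + ay * fv[f, k, 1] + az * fv[f, k, 2] - b
            if d <= tol:
                n_in += 1
        if n_in == m:
            f += 1
            continue
        changed = True
        if n_in == 0:
            # drop face: swap in the last face
            nf -= 1
            if f != nf:
                for k in range(fn[nf]):
                    fv[f, k, 0] = fv[nf, k, 0]
                    fv[f, k, 1] = fv[nf, k, 1]
                    fv[f, k, 2] = fv[nf, k, 2]
                fn[f] = fn[nf]
                fid[f] = fid[nf]
            continue
        # Sutherland-Hodgman on this convex polygon
        nout = 0
        dk = ax * fv[f, 0, 0] + ay * fv[f, 0, 1] + az * fv[f, 0, 2] - b
        for k in range(m):
            k2 = k + 1
            if k2 == m:
                k2 = 0
            dn = ax * fv[f, k2, 0] + ay * fv[f, k2, 1] + az * fv[f, k2, 2] - b
            ink = dk <= tol
            inn = dn <= tol
            if ink:
                if nout >= MAXV:
                    return nf, changed, STATUS_OVERFLOW
                tmp[nout, 0] = fv[f, k, 0]
                tmp[nout, 1] = fv[f, k, 1]
                tmp[nout, 2] = fv[f, k, 2]
                nout += 1
            if ink != inn:
                t = dk / (dk - dn)
                ix = fv[f, k, 0] + t * (fv[f, k2, 0] - fv[f, k, 0])
                iy = fv[f, k, 1] + t * (fv[f, k2, 1] - fv[f, k, 1])
                iz = fv[f, k, 2] + t * (fv[f, k2, 2] - fv[f, k, 2])
                if nout >= MAXV or ncap >= cap.shape[0]:
                    return nf, changed, STATUS_OVERFLOW
                tmp[nout, 0] = ix
                tmp[nout, 1] = iy
                tmp[nout, 2] = iz
                nout += 1
                cap[ncap, 0] = ix
                cap[ncap, 1] = iy
                cap[ncap, 2] = iz
                ncap += 1
            dk = dn
        if nout < 3:
            nf -= 1
            if f != nf:
                for k in range(fn[nf]):
                    fv[f, k, 0] = fv[nf, k, 0]
                    fv[f, k, 1] = fv[nf, k, 1]
                    fv[f, k, 2] = fv[nf, k, 2]
                fn[f] = fn[nf]
                fid[f] = fid[nf]
            continue
        for k in range(nout):
            fv[f, k, 0] = tmp[k, 0]
            fv[f, k, 1] = tmp[k, 1]
            fv[f, k, 2] = tmp[k, 2]
        fn[f] = nout
        f += 1

    if ncap >= 3:
        # Order cap points around the plane and deduplicate.
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for k in range(ncap):
            cx += cap[k, 0]
            cy += cap[k, 1]
            cz += cap[k, 2]
        cx /= ncap
        cy /= ncap
        cz /= ncap
        # in-plane basis: pick the axis least aligned with the normal
        aax = abs(ax)
        aay = abs(ay)
        aaz = abs(az)
        if aax <= aay and aax <= aaz:
            ex, ey, ez = 1.0, 0.0, 0.0
        elif aay <= aaz:
            ex, ey, ez = 0.0, 1.0, 0.0
        else:
            ex, ey, ez = 0.0, 0.0, 1.0
        dot = ex * ax + ey * ay + ez * az
        ux = ex - dot * ax
        uy = ey - dot * ay
        uz = ez - dot * az
        un = np.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= un
        uy /= un
        uz /= un
        wx = ay * uz - az * uy
        wy = az * ux - ax * uz
        wz = ax * uy - ay * ux
        for k in range(ncap):
            px = cap[k, 0] - cx
            py = cap[k, 1] - cy
            pz = cap[k, 2] - cz
            cap_ang[k] = np.arctan2(
                px * wx + py * wy + pz * wz, px * ux + py * uy + pz * uz
            )
        # insertion sort by angle
        for k in range(1, ncap):
            va = cap_ang[k]
            v0 = cap[k, 0]
            v1 = cap[k, 1]
            v2 = cap[k, 2]
            j = k - 1
            while j >= 0 and cap_ang[j] > va:
                cap_ang[j + 1] = cap_ang[j]
                cap[j + 1, 0] = cap[j, 0]
                cap[j + 1, 1] = cap[j, 1]
                cap[j + 1, 2] = cap[j, 2]
                j -= 1
            cap_ang[j + 1] = va
            cap[j + 1, 0] = v0
            cap[j + 1, 1] = v1
            cap[j + 1, 2] = v2
        # dedupe adjacent (and wrap-around) points
        dtol = 8.0 * tol
        if nf >= MAXF:
            return nf, changed, STATUS_OVERFLOW
        nuniq = 0
        for k in range(ncap):
            keep = True
            if nuniq > 0:
                dx = cap[k, 0] - fv[nf, nuniq - 1, 0]
                dy = cap[k, 1] - fv[nf, nuniq - 1, 1]
                dz = cap[k, 2] - fv[nf, nuniq - 1, 2]
                if dx * dx + dy * dy + dz * dz <= dtol * dtol:
                    keep = False
            if keep:
                if nuniq >= MAXV:
                    return nf, changed, STATUS_OVERFLOW
                fv[nf, nuniq, 0] = cap[k, 0]
                fv[nf, nuniq, 1] = cap[k, 1]
                fv[nf, nuniq, 2] = cap[k, 2]
                nuniq += 1
        if nuniq >= 3:
            dx = fv[nf, 0, 0] - fv[nf, nuniq - 1, 0]
            dy = fv[nf, 0, 1] - fv[nf, nuniq - 1, 1]
            dz = fv[nf, 0, 2] - fv[nf, nuniq - 1, 2]
            if dx * dx + dy * dy + dz * dz <= dtol * dtol:
                nuniq -= 1
        if nuniq >= 3:
            fn[nf] = nuniq
            fid[nf] = plane_id
            nf += 1
    return nf, changed, STATUS_OK


@njit(cache=True)
def _cell_3d(px, py, pz, points, nbr, order, box_lo, box_hi, tol,
             fv, fn, fid, tmp, cap, cap_ang, out):
    """Build one 3D cell.  ``out`` receives (volume, border, lox..hiz).

    Returns a STATUS_* code.
    """
    nf = _init_box_3d(box_lo, box_hi, fv, fn, fid)
    # circumradius^2 of the current polytope around p (box corners first)
    maxr2 = 0.0
    for cxi in range(2):
        for cyi in range(2):
            for czi in range(2):
                dx = (box_lo[0] if cxi == 0 else box_hi[0]) - px
                dy = (box_lo[1] if cyi == 0 else box_hi[1]) - py
                dz = (box_lo[2] if czi == 0 else box_hi[2]) - pz
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > maxr2:
                    maxr2 = r2
    for t in range(order.shape[0]):
        q = nbr[order[t]]
        qx = points[q, 0]
        qy = points[q, 1]
        qz = points[q, 2]
        dx = qx - px
        dy = qy - py
        dz = qz - pz
        dd = dx * dx + dy * dy + dz * dz
        if dd <= (1e-3 * tol) ** 2:
            return STATUS_DEGENERATE  # coincident generator
        if 0.25 * dd > maxr2:
            break  # sorted nearest-first: no remaining bisector can cut
        inv = 1.0 / np.sqrt(dd)
        ax = dx * inv
        ay = dy * inv
        az = dz * inv
        b = ax * 0.5 * (px + qx) + ay * 0.5 * (py + qy) + az * 0.5 * (pz + qz)
        nf, changed, status = _clip_by_plane_3d(
            ax, ay, az, b, 6 + q, fv, fn, fid, nf, tol, tmp, cap, cap_ang
        )
        if status != STATUS_OK:
            return status
        if changed:
            maxr2 = 0.0
            for f in range(nf):
                for k in range(fn[f]):
                    dx = fv[f, k, 0] - px
                    dy = fv[f, k, 1] - py
                    dz = fv[f, k, 2] - pz
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 > maxr2:
                        maxr2 = r2
    # volume: fan pyramids from p over every face
    vol = 0.0
    border = 0.0
    lox = 1e300
    loy = 1e300
    loz = 1e300
    hix = -1e300
    hiy = -1e300
    hiz = -1e300
    for f in range(nf):
        m = fn[f]
        if m < 3:
            continue
        if fid[f] < 6:
            border = 1.0
        w0x = fv[f, 0, 0] - px
        w0y = fv[f, 0, 1] - py
        w0z = fv[f, 0, 2] - pz
        s = 0.0
        for k in range(1, m - 1):
            w1x = fv[f, k, 0] - px
            w1y = fv[f, k, 1] - py
            w1z = fv[f, k, 2] - pz
            w2x = fv[f, k + 1, 0] - px
            w2y = fv[f, k + 1, 1] - py
            w2z = fv[f, k + 1, 2] - pz
            cxx = w1y * w2z - w1z * w2y
            cyy = w1z * w2x - w1x * w2z
            czz = w1x * w2y - w1y * w2x
            s += w0x * cxx + w0y * cyy + w0z * czz
        vol += abs(s)
        for k in range(m):
            x = fv[f, k, 0]
            y = fv[f, k, 1]
            z = fv[f, k, 2]
            if x < lox:
                lox = x
            if x > hix:
                hix = x
            if y < loy:
                loy = y
            if y > hiy:
                hiy = y
            if z < loz:
                loz = z
            if z > hiz:
                hiz = z
    out[0] = vol / 6.0
    out[1] = border
    out[2] = lox
    out[3] = loy
    out[4] = loz
    out[5] = hix
    out[6] = hiy
    out[7] = hiz
    return STATUS_OK


@njit(cache=True)
def voronoi_cells_3d(points, indptr, indices, box_lo, box_hi, tol):
    """Clip every cell; returns (volumes, border, aabb_lo, aabb_hi, status)."""
    n = points.shape[0]
    vols = np.zeros(n)
    border = np.zeros(n, np.uint8)
    status = np.zeros(n, np.uint8)
    ab_lo = np.zeros((n, 3))
    ab_hi = np.zeros((n, 3))
    fv = np.empty((MAXF, MAXV, 3))
    fn = np.zeros(MAXF, np.int64)
    fid = np.zeros(MAXF, np.int64)
    tmp = np.empty((MAXV, 3))
    cap = np.empty((2 * MAXF, 3))
    cap_ang = np.empty(2 * MAXF)
    out = np.empty(8)
    for i in range(n):
        lo = indptr[i]
        hi = indptr[i + 1]
        k = hi - lo
        nbr = indices[lo:hi]
        d2 = np.empty(k)
        for t in range(k):
            dx = points[nbr[t], 0] - points[i, 0]
            dy = points[nbr[t], 1] - points[i, 1]
            dz = points[nbr[t], 2] - points[i, 2]
            d2[t] = dx * dx + dy * dy + dz * dz
        order = np.argsort(d2)
        st = _cell_3d(
            points[i, 0], points[i, 1], points[i, 2], points, nbr, order,
            box_lo, box_hi, tol, fv, fn, fid, tmp, cap, cap_ang, out,
        )
        status[i] = st
        if st == STATUS_OK:
            vols[i] = out[0]
            border[i] = np.uint8(out[1] > 0.5)
            ab_lo[i, 0] = out[2]
            ab_lo[i, 1] = out[3]
            ab_lo[i, 2] = out[4]
            ab_hi[i, 0] = out[5]
            ab_hi[i, 1] = out[6]
            ab_hi[i, 2] = out[7]
    return vols, border, ab_lo, ab_hi, status


# --------------------------------------------------------------------------
# 2D: convex polygon with per-edge plane ids
# --------------------------------------------------------------------------

@njit(cache=True)
def _cell_2d(px, py, points, nbr, order, box_lo, box_hi, tol,
             vx, vy, eid, tvx, tvy, teid, out):
    # box polygon CCW; edge k runs from vertex k to k+1; ids 0..3 are box
    vx[0], vy[0], eid[0] = box_lo[0], box_lo[1], 0  # bottom edge
    vx[1], vy[1], eid[1] = box_hi[0], box_lo[1], 1  # right edge
    vx[2], vy[2], eid[2] = box_hi[0], box_hi[1], 2  # top edge
    vx[3], vy[3], eid[3] = box_lo[0], box_hi[1], 3  # left edge
    nv = 4
    maxr2 = 0.0
    for k in range(4):
        dx = vx[k] - px
        dy = vy[k] - py
        r2 = dx * dx + dy * dy
        if r2 > maxr2:
            maxr2 = r2
    for t in range(order.shape[0]):
        q = nbr[order[t]]
        qx = points[q, 0]
        qy = points[q, 1]
        dx = qx - px
        dy = qy - py
        dd = dx * dx + dy * dy
        if dd <= (1e-3 * tol) ** 2:
            return STATUS_DEGENERATE
        if 0.25 * dd > maxr2:
            break
        inv = 1.0 / np.sqrt(dd)
        ax = dx * inv
        ay = dy * inv
        b = ax * 0.5 * (px + qx) + ay * 0.5 * (py + qy)
        # clip polygon by a.x <= b
        nout = 0
        changed = False
        dk = ax * vx[0] + ay * vy[0] - b
        for k in range(nv):
            k2 = k + 1
            if k2 == nv:
                k2 = 0
            dn = ax * vx[k2] + ay * vy[k2] - b
            ink = dk <= tol
            inn = dn <= tol
            if ink:
                if nout >= vx.shape[0]:
                    return STATUS_OVERFLOW
                tvx[nout] = vx[k]
                tvy[nout] = vy[k]
                teid[nout] = eid[k]
                nout += 1
                if not inn:
                    tt = dk / (dk - dn)
                    if nout >= vx.shape[0]:
                        return STATUS_OVERFLOW
                    tvx[nout] = vx[k] + tt * (vx[k2] - vx[k])
                    tvy[nout] = vy[k] + tt * (vy[k2] - vy[k])
                    teid[nout] = 4 + q  # edge leaving this vertex = bisector
                    nout += 1
                    changed = True
            else:
                changed = True
                if inn:
                    tt = dk / (dk - dn)
                    if nout >= vx.shape[0]:
                        return STATUS_OVERFLOW
                    tvx[nout] = vx[k] + tt * (vx[k2] - vx[k])
                    tvy[nout] = vy[k] + tt * (vy[k2] - vy[k])
                    teid[nout] = eid[k]  # remainder of the original edge
                    nout += 1
            dk = dn
        if nout < 3:
            return STATUS_DEGENERATE
        if changed:
            for k in range(nout):
                vx[k] = tvx[k]
                vy[k] = tvy[k]
                eid[k] = teid[k]
            nv = nout
            maxr2 = 0.0
            for k in range(nv):
                ddx = vx[k] - px
                ddy = vy[k] - py
                r2 = ddx * ddx + ddy * ddy
                if r2 > maxr2:
                    maxr2 = r2
    # shoelace area, border flag, aabb
    area = 0.0
    border = 0.0
    lox = 1e300
    loy = 1e300
    hix = -1e300
    hiy = -1e300
    for k in range(nv):
        k2 = k + 1
        if k2 == nv:
            k2 = 0
        area += vx[k] * vy[k2] - vx[k2] * vy[k]
        if eid[k] < 4:
            border = 1.0
        if vx[k] < lox:
            lox = vx[k]
        if vx[k] > hix:
            hix = vx[k]
        if vy[k] < loy:
            loy = vy[k]
        if vy[k] > hiy:
            hiy = vy[k]
    out[0] = abs(area) * 0.5
    out[1] = border
    out[2] = lox
    out[3] = loy
    out[4] = hix
    out[5] = hiy
    return STATUS_OK


@njit(cache=True)
def voronoi_cells_2d(points, indptr, indices, box_lo, box_hi, tol):
    n = points.shape[0]
    areas = np.zeros(n)
    border = np.zeros(n, np.uint8)
    status = np.zeros(n, np.uint8)
    ab_lo = np.zeros((n, 2))
    ab_hi = np.zeros((n, 2))
    nvmax = 4 * MAXV
    vx = np.empty(nvmax)
    vy = np.empty(nvmax)
    eid = np.zeros(nvmax, np.int64)
    tvx = np.empty(nvmax)
    tvy = np.empty(nvmax)
    teid = np.zeros(nvmax, np.int64)
    out = np.empty(6)
    for i in range(n):
        lo = indptr[i]
        hi = indptr[i + 1]
        k = hi - lo
        nbr = indices[lo:hi]
        d2 = np.empty(k)
        for t in range(k):
            dx = points[nbr[t], 0] - points[i, 0]
            dy = points[nbr[t], 1] - points[i, 1]
            d2[t] = dx * dx + dy * dy
        order = np.argsort(d2)
        st = _cell_2d(
            points[i, 0], points[i, 1], points, nbr, order,
            box_lo, box_hi, tol, vx, vy, eid, tvx, tvy, teid, out,
        )
        status[i] = st
        if st == STATUS_OK:
            areas[i] = out[0]
            border[i] = np.uint8(out[1] > 0.5)
            ab_lo[i, 0] = out[2]
            ab_lo[i, 1] = out[3]
            ab_hi[i, 0] = out[4]
            ab_hi[i, 1] = out[5]
    return areas, border, ab_lo, ab_hi, status
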