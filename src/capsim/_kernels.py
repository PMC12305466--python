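"""Numba kernels for pairwise DPD forces, bonds, and angle terms.

The random (thermostat) force uses a counter-based generator: the Gaussian
deviate for a pair (i, j) at step ``s`` is a pure hash of
``(seed, s, i, j)`` with i < j, mapped through the AS241 inverse-normal
rational approximation (|error| < 1e-6).  The noise is therefore
independent of the order in which pairs are visited, so cell-list and
all-pairs evaluation produce identical forces, and reruns with the same
seed are bit-stable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64
_INV53 = 1.1102230246251565e-16  # 2**-53


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = z + U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _norm_ppf(u):
    """AS241 (PPND7) inverse normal CDF, good to ~1e-7."""
    q = u - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = ((59.109374720 * r + 159.29113202) * r + 50.434271938) * r + 3.3871327179
        den = ((67.187563600 * r + 78.757757664) * r + 17.895169469) * r + 1.0
        return q * num / den
    if q < 0.0:
        r = u
    else:
        r = 1.0 - u
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r -= 1.6
        num = ((0.17023821103 * r + 1.3067284816) * r + 2.7568153900) * r + 1.4234372777
        den = (0.12021132975 * r + 0.73700164250) * r + 1.0
    else:
        r -= 5.0
        num = ((0.017337203997 * r + 0.42868294337) * r + 3.0812263860) * r + 6.6579051150
        den = (0.012258202635 * r + 0.24197894225) * r + 1.0
    z = num / den
    if q < 0.0:
        return -z
    return z


@njit(cache=True, inline="always")
def _pair_normal(seed, step, i, j):
    """One standard-normal deviate per (seed, step, i<j) tuple."""
    h = _splitmix64(U64(seed) ^ (U64(step) * U64(0xD1B54A32D192ED03)))
    h = _splitmix64(h ^ (U64(i) * U64(0x8CB92BA72F3D8DD7)))
    h = _splitmix64(h ^ (U64(j) * U64(0xABCD1234DEAD4321)))
    u = (float(h >> U64(11)) + 0.5) * _INV53  # strictly inside (0, 1)
    return _norm_ppf(u)


@njit(cache=True, inline="always")
def _pair_terms(
    gi, gj, r2, dx, dy, dz, dvx, dvy, dvz, a, gamma, sigma, cutoff,
    seed, step, inv_sqrt_dt,
):
    """Force components (fx, fy, fz, overlap) for one in-range pair.

    ``gi``/``gj`` are global bead indices (they key the noise hash); the
    caller guarantees r2 < cutoff^2 and supplies the pre-shifted
    separation and relative velocity.
    """
    r = math.sqrt(r2)
    overlap = 0
    if r < 1e-12:
        # deterministic fallback axis for coincident beads
        ex, ey, ez = 1.0, 0.0, 0.0
        w = 1.0
        overlap = 1
    else:
        inv_r = 1.0 / r
        ex, ey, ez = dx * inv_r, dy * inv_r, dz * inv_r
        w = 1.0 - r / cutoff
    vdot = ex * dvx + ey * dvy + ez * dvz
    if gi < gj:
        zeta = _pair_normal(seed, step, gi, gj)
    else:
        zeta = _pair_normal(seed, step, gj, gi)
    ft = a * w - gamma * w * w * vdot + sigma * w * zeta * inv_sqrt_dt
    return ft * ex, ft * ey, ft * ez, overlap


@njit(cache=True, fastmath=True)
def nonbonded_allpairs(
    pos, vel, species, amat, gamma, sigma, cutoff, box, seed, step,
    inv_sqrt_dt, forces,
):
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    cut2 = cutoff * cutoff
    overlaps = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= lx * round(dx / lx)
            dy -= ly * round(dy / ly)
            dz -= lz * round(dz / lz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2:
                continue
            fx, fy, fz, ov = _pair_terms(
                i, j, r2, dx, dy, dz,
                vel[i, 0] - vel[j, 0], vel[i, 1] - vel[j, 1],
                vel[i, 2] - vel[j, 2],
                amat[species[i], species[j]], gamma, sigma, cutoff,
                seed, step, inv_sqrt_dt,
            )
            overlaps += ov
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return overlaps


@njit(cache=True)
def _sort_by_cell(pos, box, ncx, ncy, ncz):
    """Bead order sorted by cell id plus CSR-style cell start offsets."""
    n = pos.shape[0]
    ncell = ncx * ncy * ncz
    fx = ncx / box[0]
    fy = ncy / box[1]
    fz = ncz / box[2]
    cell = np.empty(n, dtype=np.int64)
    start = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] * fx)
        cy = int(pos[i, 1] * fy)
        cz = int(pos[i, 2] * fz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell[i] = c
        start[c + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    order = np.empty(n, dtype=np.int64)
    cursor = start[:-1].copy()
    for i in range(n):
        c = cell[i]
        order[cursor[c]] = i
        cursor[c] += 1
    return order, start


@njit(cache=True)
def _half_stencil(ncx, ncy, ncz, lx, ly, lz, cutoff):
    """Forward half-stencil of cell offsets, pruned by minimum distance.

    Stencil radius per axis is ceil(cutoff / cell_size); an offset is kept
    when it is lexicographically positive and the closest approach between
    the two cells is below the cutoff.
    """
    cszx = lx / ncx
    cszy = ly / ncy
    cszz = lz / ncz
    rx = int(math.ceil(cutoff / cszx - 1e-12))
    ry = int(math.ceil(cutoff / cszy - 1e-12))
    rz = int(math.ceil(cutoff / cszz - 1e-12))
    offs = np.empty(((rx + 1) * (2 * ry + 1) * (2 * rz + 1), 3), dtype=np.int64)
    m = 0
    for ox in range(0, rx + 1):
        for oy in range(-ry, ry + 1):
            for oz in range(-rz, rz + 1):
                if ox == 0 and (oy < 0 or (oy == 0 and oz <= 0)):
                    continue
                mdx = max(abs(ox) - 1, 0) * cszx
                mdy = max(abs(oy) - 1, 0) * cszy
                mdz = max(abs(oz) - 1, 0) * cszz
                if mdx * mdx + mdy * mdy + mdz * mdz >= cutoff * cutoff:
                    continue
                offs[m, 0] = ox
                offs[m, 1] = oy
                offs[m, 2] = oz
                m += 1
    return offs[:m]


@njit(cache=True, fastmath=True)
def nonbonded_celllist(
    pos, vel, species, amat, gamma, sigma, cutoff, box, seed, step,
    inv_sqrt_dt, forces, ncx, ncy, ncz,
):
    """Cell-sorted half-stencil sweep (requires ncx,ncy,ncz >= 2*radius+1).

    Beads are gathered into cell order so the inner loops run over
    contiguous memory; periodic images are handled with one shift per
    neighbour cell, so the pair loop does no minimum-image arithmetic.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    order, start = _sort_by_cell(pos, box, ncx, ncy, ncz)
    offs = _half_stencil(ncx, ncy, ncz, lx, ly, lz, cutoff)
    noffs = offs.shape[0]
    spos = np.empty((n, 3))
    svel = np.empty((n, 3))
    ssp = np.empty(n, dtype=species.dtype)
    for u in range(n):
        i = order[u]
        spos[u, 0] = pos[i, 0]
        spos[u, 1] = pos[i, 1]
        spos[u, 2] = pos[i, 2]
        svel[u, 0] = vel[i, 0]
        svel[u, 1] = vel[i, 1]
        svel[u, 2] = vel[i, 2]
        ssp[u] = species[i]
    sidx = order  # global index per sorted slot (for the noise hash)
    sf = np.zeros((n, 3))
    cut2 = cutoff * cutoff
    overlaps = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0, a1 = start[c], start[c + 1]
                if a0 == a1:
                    continue
                # same cell: all unordered pairs, no image shift
                for u in range(a0, a1):
                    gi = sidx[u]
                    for v in range(u + 1, a1):
                        dx = spos[u, 0] - spos[v, 0]
                        dy = spos[u, 1] - spos[v, 1]
                        dz = spos[u, 2] - spos[v, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 >= cut2:
                            continue
                        fx, fy, fz, ov = _pair_terms(
                            gi, sidx[v], r2, dx, dy, dz,
                            svel[u, 0] - svel[v, 0],
                            svel[u, 1] - svel[v, 1],
                            svel[u, 2] - svel[v, 2],
                            amat[ssp[u], ssp[v]], gamma, sigma, cutoff,
                            seed, step, inv_sqrt_dt,
                        )
                        overlaps += ov
                        sf[u, 0] += fx
                        sf[u, 1] += fy
                        sf[u, 2] += fz
                        sf[v, 0] -= fx
                        sf[v, 1] -= fy
                        sf[v, 2] -= fz
                for k in range(noffs):
                    nx = cx + offs[k, 0]
                    ny = cy + offs[k, 1]
                    nz = cz + offs[k, 2]
                    sx = 0.0
                    sy = 0.0
                    sz = 0.0
                    if nx >= ncx:
                        nx -= ncx
                        sx = -lx
                    elif nx < 0:
                        nx += ncx
                        sx = lx
                    if ny >= ncy:
                        ny -= ncy
                        sy = -ly
                    elif ny < 0:
                        ny += ncy
                        sy = ly
                    if nz >= ncz:
                        nz -= ncz
                        sz = -lz
                    elif nz < 0:
                        nz += ncz
                        sz = lz
                    c2 = (nx * ncy + ny) * ncz + nz
                    b0, b1 = start[c2], start[c2 + 1]
                    for u in range(a0, a1):
                        gi = sidx[u]
                        px = spos[u, 0] + sx
                        py = spos[u, 1] + sy
                        pz = spos[u, 2] + sz
                        for v in range(b0, b1):
                            dx = px - spos[v, 0]
                            dy = py - spos[v, 1]
                            dz = pz - spos[v, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= cut2:
                                continue
                            fx, fy, fz, ov = _pair_terms(
                                gi, sidx[v], r2, dx, dy, dz,
                                svel[u, 0] - svel[v, 0],
                                svel[u, 1] - svel[v, 1],
                                svel[u, 2] - svel[v, 2],
                                amat[ssp[u], ssp[v]], gamma, sigma, cutoff,
                                seed, step, inv_sqrt_dt,
                            )
                            overlaps += ov
                            sf[u, 0] += fx
                            sf[u, 1] += fy
                            sf[u, 2] += fz
                            sf[v, 0] -= fx
                            sf[v, 1] -= fy
                            sf[v, 2] -= fz
    for u in range(n):
        i = sidx[u]
        forces[i, 0] += sf[u, 0]
        forces[i, 1] += sf[u, 1]
        forces[i, 2] += sf[u, 2]
    return overlaps


@njit(cache=True)
def bond_forces(pos, bonds, bond_k, bond_r0, box, forces):
    """Harmonic bonds E = 0.5 k (r - r0)^2; returns max minimum-image length."""
    lx, ly, lz = box[0], box[1], box[2]
    max_len = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * round(dx / lx)
        dy -= ly * round(dy / ly)
        dz -= lz * round(dz / lz)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > max_len:
            max_len = r
        if r < 1e-12:
            continue
        f = -bond_k * (r - bond_r0) / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    return max_len


@njit(cache=True)
def angle_forces(pos, angles, angle_k, box, forces):
    """Bending term E = k (1 + cos theta), theta the angle at the middle bead.

    With u = r2 - r1, v = r3 - r2 (minimum image) and c = u.v/(|u||v|),
    cos theta = -c, so E = k (1 - c): minimum at the straight chain.
    Forces are the exact analytic negative gradient; the collinear case is
    regular because the energy is expressed in cos theta.
    """
    lx, ly, lz = box[0], box[1], box[2]
    for t in range(angles.shape[0]):
        i1 = angles[t, 0]
        i2 = angles[t, 1]
        i3 = angles[t, 2]
        ux = pos[i2, 0] - pos[i1, 0]
        uy = pos[i2, 1] - pos[i1, 1]
        uz = pos[i2, 2] - pos[i1, 2]
        vx = pos[i3, 0] - pos[i2, 0]
        vy = pos[i3, 1] - pos[i2, 1]
        vz = pos[i3, 2] - pos[i2, 2]
        ux -= lx * round(ux / lx)
        uy -= ly * round(uy / ly)
        uz -= lz * round(uz / lz)
        vx -= lx * round(vx / lx)
        vy -= ly * round(vy / ly)
        vz -= lz * round(vz / lz)
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            continue
        inv = 1.0 / (nu * nv)
        c = (ux * vx + uy * vy + uz * vz) * inv
        # dc/du and dc/dv
        dcux = vx * inv - c * ux / (nu * nu)
        dcuy = vy * inv - c * uy / (nu * nu)
        dcuz = vz * inv - c * uz / (nu * nu)
        dcvx = ux * inv - c * vx / (nv * nv)
        dcvy = uy * inv - c * vy / (nv * nv)
        dcvz = uz * inv - c * vz / (nv * nv)
        # F = -dE/dr with E = k (1 - c)
        f1x = -angle_k * dcux
        f1y = -angle_k * dcuy
        f1z = -angle_k * dcuz
        f3x = angle_k * dcvx
        f3y = angle_k * dcvy
        f3z = angle_k * dcvz
        forces[i1, 0] += f1x
        forces[i1, 1] += f1y
        forces[i1, 2] += f1z
        forces[i3, 0] += f3x
        forces[i3, 1] += f3y
        forces[i3, 2] += f3z
        forces[i2, 0] -= f1x + f3x
        forces[i2, 1] -= f1y + f3y
        forces[i2, 2] -= f1z + f3z


@njit(cache=True)
def bond_angle_energy(pos, bonds, bond_k, bond_r0, angles, angle_k, box):
    """Total bonded potential energy (bond + angle terms)."""
    lx, ly, lz = box[0], box[1], box[2]
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * round(dx / lx)
        dy -= ly * round(dy / ly)
        dz -= lz * round(dz / lz)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * bond_k * (r - bond_r0) ** 2
    for t in range(angles.shape[0]):
        i1 = angles[t, 0]
        i2 = angles[t, 1]
        i3 = angles[t, 2]
        ux = pos[i2, 0] - pos[i1, 0]
        uy = pos[i2, 1] - pos[i1, 1]
        uz = pos[i2, 2] - pos[i1, 2]
        vx = pos[i3, 0] - pos[i2, 0]
        vy = pos[i3, 1] - pos[i2, 1]
        vz = pos[i3, 2] - pos[i2, 2]
        ux -= lx * round(ux / lx)
        uy -= ly * round(uy / ly)
        uz -= lz * round(uz / lz)
        vx -= lx * round(vx / lx)
        vy -= ly * round(vy / ly)
        vz -= lz * round(vz / lz)
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        e += angle_k * (1.0 - c)
    return e
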