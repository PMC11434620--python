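"""Numba kernels for the performance-critical inner loops.

Everything here is deliberately free of Python objects: the public modules
wrap these kernels with validation, dataclasses and friendlier errors.
All kernels draw randomness from numba's internal ``np.random`` state,
seeded explicitly at kernel entry, so results are reproducible bit-for-bit
for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# SRRW generation
# ---------------------------------------------------------------------------

@njit(cache=True)
def srrw_walk(n_beads, alpha, rc_confine, unit_length, local_cutoff, seed,
              max_attempts):
    """Generate one self-returning random walk.

    Returns ``(positions, step_types, step_lengths, status)`` where
    ``step_types`` is 0 for a forward jump and 1 for a return, step lengths
    are in units of ``unit_length`` and ``status`` is 0 on success, -1 if a
    jump could not be placed inside the global cutoff within
    ``max_attempts`` resamplings.
    """
    np.random.seed(seed)

    pos = np.zeros((n_beads, 3))
    step_type = np.zeros(n_beads - 1, dtype=np.int8)
    step_len = np.zeros(n_beads - 1)

    # Backbone stack: positions of the un-retraced backbone vertices and the
    # length (units) of the step that created each stack entry from the one
    # below.  A return pops the stack; consecutive returns therefore walk
    # back along the backbone.
    stack_pos = np.zeros((n_beads, 3))
    stack_len = np.zeros(n_beads)
    top = 0  # stack_pos[0] is the origin; top == 0 means "no backbone step"

    csum = np.zeros(3)  # running sum of generated vertices (for the c.o.m.)
    csum[0] = 0.0

    for i in range(1, n_beads):
        cx = pos[i - 1, 0]
        cy = pos[i - 1, 1]
        cz = pos[i - 1, 2]

        do_return = False
        if top > 0:
            u0 = stack_len[top]
            p_ret = u0 ** (-alpha) / alpha
            if np.random.random() < p_ret:
                do_return = True

        if do_return:
            step_type[i - 1] = 1
            step_len[i - 1] = stack_len[top]
            top -= 1
            pos[i, 0] = stack_pos[top, 0]
            pos[i, 1] = stack_pos[top, 1]
            pos[i, 2] = stack_pos[top, 2]
        else:
            # centre of mass of vertices 0..i-1
            comx = csum[0] / i
            comy = csum[1] / i
            comz = csum[2] / i
            attempts = 0
            while True:
                u = (1.0 - np.random.random()) ** (-1.0 / (alpha + 1.0))
                if u > local_cutoff:
                    continue  # truncation of the jump pdf, not a placement try
                zdir = 2.0 * np.random.random() - 1.0
                theta = 2.0 * math.pi * np.random.random()
                s = math.sqrt(max(0.0, 1.0 - zdir * zdir))
                r = u * unit_length
                nx = cx + r * s * math.cos(theta)
                ny = cy + r * s * math.sin(theta)
                nz = cz + r * zdir
                dx = nx - comx
                dy = ny - comy
                dz = nz - comz
                if dx * dx + dy * dy + dz * dz <= rc_confine * rc_confine:
                    break
                attempts += 1
                if attempts >= max_attempts:
                    return pos, step_type, step_len, -1
            top += 1
            stack_pos[top, 0] = nx
            stack_pos[top, 1] = ny
            stack_pos[top, 2] = nz
            stack_len[top] = u
            step_type[i - 1] = 0
            step_len[i - 1] = u
            pos[i, 0] = nx
            pos[i, 1] = ny
            pos[i, 2] = nz

        csum[0] += pos[i, 0]
        csum[1] += pos[i, 1]
        csum[2] += pos[i, 2]

    return pos, step_type, step_len, 0


# ---------------------------------------------------------------------------
# Overlap relaxation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_cell_list(pos, cell_size, origin, ncell):
    """Counting-sort cell list; returns (cell index per bead, start, order)."""
    n = pos.shape[0]
    ncx, ncy, ncz = ncell[0], ncell[1], ncell[2]
    ntot = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = int((pos[i, 0] - origin[0]) / cell_size)
        iy = int((pos[i, 1] - origin[1]) / cell_size)
        iz = int((pos[i, 2] - origin[2]) / cell_size)
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        if ix >= ncx:
            ix = ncx - 1
        if iy >= ncy:
            iy = ncy - 1
        if iz >= ncz:
            iz = ncz - 1
        cell_of[i] = (ix * ncy + iy) * ncz + iz
    counts = np.zeros(ntot + 1, dtype=np.int64)
    for i in range(n):
        counts[cell_of[i] + 1] += 1
    for c in range(ntot):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:ntot].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    return cell_of, counts, order


@njit(cache=True)
def count_overlaps_grid(pos, contact_dist):
    """Number of non-bonded pairs (|i-j| > 1) closer than ``contact_dist``."""
    n = pos.shape[0]
    if n < 3:
        return 0
    mins = np.empty(3)
    for d in range(3):
        mn = pos[0, d]
        for i in range(1, n):
            if pos[i, d] < mn:
                mn = pos[i, d]
        mins[d] = mn
    maxs = np.empty(3)
    for d in range(3):
        mx = pos[0, d]
        for i in range(1, n):
            if pos[i, d] > mx:
                mx = pos[i, d]
        maxs[d] = mx
    cell = contact_dist
    ncell = np.empty(3, dtype=np.int64)
    for d in range(3):
        ncell[d] = max(1, int((maxs[d] - mins[d]) / cell) + 1)
    cell_of, starts, order = _build_cell_list(pos, cell, mins, ncell)
    ncx, ncy, ncz = ncell[0], ncell[1], ncell[2]
    c2 = contact_dist * contact_dist
    count = 0
    for i in range(n):
        ci = cell_of[i]
        iz = ci % ncz
        iy = (ci // ncz) % ncy
        ix = ci // (ncz * ncy)
        for ddx in range(-1, 2):
            jx = ix + ddx
            if jx < 0 or jx >= ncx:
                continue
            for ddy in range(-1, 2):
                jy = iy + ddy
                if jy < 0 or jy >= ncy:
                    continue
                for ddz in range(-1, 2):
                    jz = iz + ddz
                    if jz < 0 or jz >= ncz:
                        continue
                    cj = (jx * ncy + jy) * ncz + jz
                    for k in range(starts[cj], starts[cj + 1]):
                        j = order[k]
                        if j <= i:
                            continue
                        if j == i + 1 or j == i - 1:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz < c2:
                            count += 1
    return count


@njit(cache=True)
def _bounding_cells(pos, cell, mins, ncell):
    n = pos.shape[0]
    for d in range(3):
        mn = pos[0, d]
        mx = pos[0, d]
        for i in range(1, n):
            if pos[i, d] < mn:
                mn = pos[i, d]
            if pos[i, d] > mx:
                mx = pos[i, d]
        mins[d] = mn
        ncell[d] = max(1, int((mx - mn) / cell) + 1)


@njit(cache=True)
def relax_chain(pos, rest_len, bead_radius, overlap_tol, max_steps,
                step_scale, k_bond, k_rep, max_disp, rc_confine,
                temperature, seed, record_energy, refresh_every=50,
                stall_factor=1.5):
    """Overdamped descent until all non-bonded overlaps are resolved.

    ``pos`` is modified in place.  Every ``refresh_every`` iterations a full
    pair scan counts overlaps, records the repulsive penalty (when
    ``record_energy``) and rebuilds the *active set*: only beads within one
    neighbour cell of a currently interacting pair are moved in between,
    which makes the long sparse tail of the relaxation cheap without
    changing the dynamics of the beads that still interact.

    Returns ``(n_iters, residual_overlaps, energy_history)``; the history
    holds the total overlap penalty at each full scan.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    sigma = 2.0 * bead_radius                 # repulsion range
    contact = sigma * (1.0 - overlap_tol)     # termination contact distance
    s2 = sigma * sigma
    c2 = contact * contact

    # bonded pairs are repelled (and treated as overlaps) only when they
    # start out overlapping; walk-derived bonds are >= one unit length and
    # never do, so this matters only for hand-built chains
    bond_overlap = np.zeros(max(n - 1, 1), dtype=np.bool_)
    for b in range(n - 1):
        dx = pos[b + 1, 0] - pos[b, 0]
        dy = pos[b + 1, 1] - pos[b, 1]
        dz = pos[b + 1, 2] - pos[b, 2]
        if dx * dx + dy * dy + dz * dz < s2:
            bond_overlap[b] = True

    n_scans_max = max_steps // refresh_every + 2
    energy = np.zeros(n_scans_max if record_energy else 1)
    n_energy = 0

    force = np.zeros((n, 3))
    active = np.ones(n, dtype=np.bool_)
    mark = np.zeros(n, dtype=np.bool_)
    mins = np.empty(3)
    ncell = np.empty(3, dtype=np.int64)

    it = 0
    residual = -1
    # stall escalation: if the overlap count stops improving, the repulsion
    # is being pinned by strongly stretched bonds; stiffen it geometrically
    cur_k_rep = k_rep
    best_total = np.iinfo(np.int64).max
    stall = 0
    while True:
        # ---------------- full scan: overlap count, energy, active set
        _bounding_cells(pos, sigma, mins, ncell)
        cell_of, starts, order = _build_cell_list(pos, sigma, mins, ncell)
        ncx, ncy, ncz = ncell[0], ncell[1], ncell[2]
        for i in range(n):
            mark[i] = False
        total = 0
        e_tot = 0.0
        for i in range(n):
            ci = cell_of[i]
            iz = ci % ncz
            iy = (ci // ncz) % ncy
            ix = ci // (ncz * ncy)
            for ddx in range(-1, 2):
                jx = ix + ddx
                if jx < 0 or jx >= ncx:
                    continue
                for ddy in range(-1, 2):
                    jy = iy + ddy
                    if jy < 0 or jy >= ncy:
                        continue
                    for ddz in range(-1, 2):
                        jz = iz + ddz
                        if jz < 0 or jz >= ncz:
                            continue
                        cj = (jx * ncy + jy) * ncz + jz
                        for k in range(starts[cj], starts[cj + 1]):
                            j = order[k]
                            if j <= i:
                                continue
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            d2 = dx * dx + dy * dy + dz * dz
                            if d2 >= s2:
                                continue
                            if j == i + 1 and not bond_overlap[i]:
                                continue
                            d = math.sqrt(d2)
                            depth = sigma - d
                            e_tot += k_rep * depth * depth
                            mark[i] = True
                            mark[j] = True
                            if d2 < c2:
                                total += 1
        if record_energy and n_energy < len(energy):
            energy[n_energy] = e_tot
            n_energy += 1
        if total == 0:
            residual = 0
            break
        residual = total
        if it >= max_steps:
            break
        if total < best_total:
            best_total = total
            stall = 0
        else:
            stall += 1
            if stall >= 20:
                cur_k_rep *= stall_factor
                stall = 0

        # active = beads in or next to a cell holding a marked bead
        ntot = ncx * ncy * ncz
        cell_marked = np.zeros(ntot, dtype=np.bool_)
        for i in range(n):
            if mark[i]:
                cell_marked[cell_of[i]] = True
        for i in range(n):
            ci = cell_of[i]
            iz = ci % ncz
            iy = (ci // ncz) % ncy
            ix = ci // (ncz * ncy)
            act = False
            for ddx in range(-1, 2):
                jx = ix + ddx
                if jx < 0 or jx >= ncx:
                    continue
                for ddy in range(-1, 2):
                    jy = iy + ddy
                    if jy < 0 or jy >= ncy:
                        continue
                    for ddz in range(-1, 2):
                        jz = iz + ddz
                        if jz < 0 or jz >= ncz:
                            continue
                        if cell_marked[(jx * ncy + jy) * ncz + jz]:
                            act = True
            active[i] = act

        # ---------------- inner iterations on the active set
        inner = refresh_every
        if it + inner > max_steps:
            inner = max_steps - it
        for w in range(inner):
            if w > 0:
                _bounding_cells(pos, sigma, mins, ncell)
                cell_of, starts, order = _build_cell_list(pos, sigma, mins, ncell)
                ncx, ncy, ncz = ncell[0], ncell[1], ncell[2]

            for i in range(n):
                force[i, 0] = 0.0
                force[i, 1] = 0.0
                force[i, 2] = 0.0

            # repulsion: full gradient on each active bead
            for i in range(n):
                if not active[i]:
                    continue
                ci = cell_of[i]
                iz = ci % ncz
                iy = (ci // ncz) % ncy
                ix = ci // (ncz * ncy)
                for ddx in range(-1, 2):
                    jx = ix + ddx
                    if jx < 0 or jx >= ncx:
                        continue
                    for ddy in range(-1, 2):
                        jy = iy + ddy
                        if jy < 0 or jy >= ncy:
                            continue
                        for ddz in range(-1, 2):
                            jz = iz + ddz
                            if jz < 0 or jz >= ncz:
                                continue
                            cj = (jx * ncy + jy) * ncz + jz
                            for k in range(starts[cj], starts[cj + 1]):
                                j = order[k]
                                if j == i:
                                    continue
                                if j == i + 1 and not bond_overlap[i]:
                                    continue
                                if j == i - 1 and not bond_overlap[j]:
                                    continue
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dz = pos[i, 2] - pos[j, 2]
                                d2 = dx * dx + dy * dy + dz * dz
                                if d2 >= s2:
                                    continue
                                d = math.sqrt(d2)
                                if d < 1e-9:
                                    # exactly coincident: deterministic split
                                    if j > i:
                                        dx, dy, dz, d = 1e-3, 0.0, 0.0, 1e-3
                                    else:
                                        dx, dy, dz, d = -1e-3, 0.0, 0.0, 1e-3
                                depth = sigma - d
                                f = 2.0 * cur_k_rep * depth / d
                                force[i, 0] += f * dx
                                force[i, 1] += f * dy
                                force[i, 2] += f * dz

            # harmonic bonds at their initial rest lengths
            for b in range(n - 1):
                if not (active[b] or active[b + 1]):
                    continue
                dx = pos[b + 1, 0] - pos[b, 0]
                dy = pos[b + 1, 1] - pos[b, 1]
                dz = pos[b + 1, 2] - pos[b, 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d < 1e-9:
                    continue
                f = k_bond * (d - rest_len[b]) / d
                if active[b]:
                    force[b, 0] += f * dx
                    force[b, 1] += f * dy
                    force[b, 2] += f * dz
                if active[b + 1]:
                    force[b + 1, 0] -= f * dx
                    force[b + 1, 1] -= f * dy
                    force[b + 1, 2] -= f * dz

            # overdamped update with displacement cap (+ optional noise)
            comx = 0.0
            comy = 0.0
            comz = 0.0
            for i in range(n):
                comx += pos[i, 0]
                comy += pos[i, 1]
                comz += pos[i, 2]
            comx /= n
            comy /= n
            comz /= n
            for i in range(n):
                if not active[i]:
                    continue
                ux = step_scale * force[i, 0]
                uy = step_scale * force[i, 1]
                uz = step_scale * force[i, 2]
                if temperature > 0.0:
                    ux += temperature * np.random.normal()
                    uy += temperature * np.random.normal()
                    uz += temperature * np.random.normal()
                um = math.sqrt(ux * ux + uy * uy + uz * uz)
                if um > max_disp:
                    sc = max_disp / um
                    ux *= sc
                    uy *= sc
                    uz *= sc
                nx = pos[i, 0] + ux
                ny = pos[i, 1] + uy
                nz = pos[i, 2] + uz
                # reflecting spherical confinement about the c.o.m.
                rx = nx - comx
                ry = ny - comy
                rz = nz - comz
                rr = math.sqrt(rx * rx + ry * ry + rz * rz)
                if rr > rc_confine:
                    sc = (2.0 * rc_confine - rr) / rr
                    if sc < 0.0:
                        sc = rc_confine / rr
                    nx = comx + rx * sc
                    ny = comy + ry * sc
                    nz = comz + rz * sc
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
            it += 1

    return it, residual, energy[:n_energy]


# ---------------------------------------------------------------------------
# Gaussian voxel deposition
# ---------------------------------------------------------------------------

@njit(cache=True)
def deposit_gaussian(pos, origin, voxel, shape, sigma, truncate):
    """Deposit unit mass per bead as an isotropic Gaussian, integrated per voxel.

    The per-voxel contribution is the product of 1-D Gaussian integrals
    (erf differences) over the voxel extent in each axis, which is the exact
    integral of the separable 3-D normal over the voxel volume.
    """
    nx, ny, nz = shape[0], shape[1], shape[2]
    vol = np.zeros((nx, ny, nz))
    half = truncate * sigma
    inv = 1.0 / (math.sqrt(2.0) * sigma)
    n = pos.shape[0]
    for b in range(n):
        x = pos[b, 0] - origin[0]
        y = pos[b, 1] - origin[1]
        z = pos[b, 2] - origin[2]
        ix0 = max(0, int((x - half) / voxel))
        ix1 = min(nx - 1, int((x + half) / voxel))
        iy0 = max(0, int((y - half) / voxel))
        iy1 = min(ny - 1, int((y + half) / voxel))
        iz0 = max(0, int((z - half) / voxel))
        iz1 = min(nz - 1, int((z + half) / voxel))
        if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
            continue
        mx = ix1 - ix0 + 1
        my = iy1 - iy0 + 1
        mz = iz1 - iz0 + 1
        wx = np.empty(mx)
        wy = np.empty(my)
        wz = np.empty(mz)
        for i in range(mx):
            lo = (ix0 + i) * voxel
            wx[i] = 0.5 * (math.erf((lo + voxel - x) * inv) - math.erf((lo - x) * inv))
        for i in range(my):
            lo = (iy0 + i) * voxel
            wy[i] = 0.5 * (math.erf((lo + voxel - y) * inv) - math.erf((lo - y) * inv))
        for i in range(mz):
            lo = (iz0 + i) * voxel
            wz[i] = 0.5 * (math.erf((lo + voxel - z) * inv) - math.erf((lo - z) * inv))
        for i in range(mx):
            for j in range(my):
                wxy = wx[i] * wy[j]
                for k in range(mz):
                    vol[ix0 + i, iy0 + j, iz0 + k] += wxy * wz[k]
    return vol
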