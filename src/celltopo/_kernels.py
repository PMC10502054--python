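"""Numba-compiled inner loop of the self-propelled particle simulation.

The kernel advances the whole population in place for a block of steps.
Neighbor search uses a per-step cell list with bins no smaller than the
interaction cutoff, so each cell scans its 3x3 bin neighborhood. The pair
force magnitude per unit adhesion, U'(r)/J, is tabulated on a dense grid
over [0, r_max] and linearly interpolated (grid spacing ~4e-4 length
units; interpolation error ~1e-7 in force units).
"""

import numpy as np
from numba import njit

FORCE_TABLE_SIZE = 4096


def force_magnitude_table(r_max, l_a, l_r, ratio, n=FORCE_TABLE_SIZE):
    """U'(r)/J sampled on a uniform grid over [0, r_max].

    Positive values mean attraction (force on i points toward j)."""
    r = np.linspace(0.0, r_max, n)
    return (np.exp(-r / l_a) / l_a) - ratio * np.exp(-r / l_r) / l_r


@njit(cache=True)
def simulate_block(pos, ang, types, offsets, clocks, n0, jmat, pmag, dt_eta,
                   r_max, box_l, period, step0, n_steps, prolif, cycle,
                   max_div_neighbors, daughter_dist, seed, ftab, coin_mag):
    """Advance ``n_steps`` steps in place; returns the final cell count.

    Arrays are preallocated to capacity; cells [0, n) are live. ``ftab``
    is the per-unit-J force magnitude table over [0, r_max].
    """
    np.random.seed(seed)
    n = n0
    cap = pos.shape[0]
    half = 0.5 * box_l
    nb = int(box_l / r_max)
    if nb < 3:
        nb = 3
    binw = box_l / nb
    nbins = nb * nb
    ntab = ftab.shape[0]
    dr_tab = r_max / (ntab - 1)
    r_max2 = r_max * r_max

    fx = np.empty(cap)
    fy = np.empty(cap)
    ncnt = np.zeros(cap, np.int32)
    count = np.empty(nbins, np.int32)
    start = np.empty(nbins + 1, np.int32)
    fill = np.empty(nbins, np.int32)
    order = np.empty(cap, np.int32)
    binid = np.empty(cap, np.int32)
    two_pi = 2.0 * np.pi

    for s in range(n_steps):
        step = step0 + s
        # repolarization: resample heading for cells whose phase is due
        for i in range(n):
            if (step + offsets[i]) % period == 0:
                ang[i] = np.random.uniform(0.0, two_pi)
        # cell list (counting sort)
        for b in range(nbins):
            count[b] = 0
        for i in range(n):
            bx = int((pos[i, 0] + half) / binw)
            if bx >= nb:
                bx = nb - 1
            elif bx < 0:
                bx = 0
            by = int((pos[i, 1] + half) / binw)
            if by >= nb:
                by = nb - 1
            elif by < 0:
                by = 0
            b = bx * nb + by
            binid[i] = b
            count[b] += 1
        start[0] = 0
        for b in range(nbins):
            start[b + 1] = start[b] + count[b]
            fill[b] = start[b]
        for i in range(n):
            b = binid[i]
            order[fill[b]] = i
            fill[b] += 1
        for i in range(n):
            fx[i] = 0.0
            fy[i] = 0.0
            ncnt[i] = 0
        # pairwise forces, each pair visited once (j > i)
        for i in range(n):
            bi = binid[i]
            bxi = bi // nb
            byi = bi % nb
            xi = pos[i, 0]
            yi = pos[i, 1]
            ti = types[i]
            for ox in range(-1, 2):
                bx = bxi + ox
                if bx < 0:
                    bx += nb
                elif bx >= nb:
                    bx -= nb
                for oy in range(-1, 2):
                    by = byi + oy
                    if by < 0:
                        by += nb
                    elif by >= nb:
                        by -= nb
                    b = bx * nb + by
                    for q in range(start[b], start[b + 1]):
                        j = order[q]
                        if j <= i:
                            continue
                        dx = pos[j, 0] - xi
                        if dx > half:
                            dx -= box_l
                        elif dx < -half:
                            dx += box_l
                        dy = pos[j, 1] - yi
                        if dy > half:
                            dy -= box_l
                        elif dy < -half:
                            dy += box_l
                        r2 = dx * dx + dy * dy
                        if r2 > r_max2:
                            continue
                        ncnt[i] += 1
                        ncnt[j] += 1
                        jv = jmat[ti, types[j]]
                        if r2 < 1e-18:
                            # coincident centers: finite Morse magnitude,
                            # undefined direction -> random direction
                            th = np.random.uniform(0.0, two_pi)
                            fm = jv * coin_mag
                            cx = fm * np.cos(th)
                            cy = fm * np.sin(th)
                            fx[i] -= cx
                            fy[i] -= cy
                            fx[j] += cx
                            fy[j] += cy
                            continue
                        r = np.sqrt(r2)
                        t = r / dr_tab
                        k = int(t)
                        if k >= ntab - 1:
                            k = ntab - 2
                        fu = ftab[k] + (ftab[k + 1] - ftab[k]) * (t - k)
                        c = jv * fu / r
                        fx[i] += c * dx
                        fy[i] += c * dy
                        fx[j] -= c * dx
                        fy[j] -= c * dy
        # synchronous position update
        for i in range(n):
            x = pos[i, 0] + dt_eta * (pmag * np.cos(ang[i]) + fx[i])
            y = pos[i, 1] + dt_eta * (pmag * np.sin(ang[i]) + fy[i])
            if x >= half:
                x -= box_l
            elif x < -half:
                x += box_l
            if y >= half:
                y -= box_l
            elif y < -half:
                y += box_l
            pos[i, 0] = x
            pos[i, 1] = y
            clocks[i] += 1
        # contact-inhibited divisions
        if prolif:
            n_old = n
            for i in range(n_old):
                if clocks[i] >= cycle and ncnt[i] <= max_div_neighbors and n < cap:
                    th = np.random.uniform(0.0, two_pi)
                    x = pos[i, 0] + daughter_dist * np.cos(th)
                    y = pos[i, 1] + daughter_dist * np.sin(th)
                    if x >= half:
                        x -= box_l
                    elif x < -half:
                        x += box_l
                    if y >= half:
                        y -= box_l
                    elif y < -half:
                        y += box_l
                    pos[n, 0] = x
                    pos[n, 1] = y
                    a = ang[i] + np.pi
                    if a >= two_pi:
                        a -= two_pi
                    ang[n] = a
                    types[n] = types[i]
                    offsets[n] = np.random.randint(0, period)
                    clocks[i] = 0
                    clocks[n] = 0
                    n += 1
    return n
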