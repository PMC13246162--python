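"""Numba kernels: neighbor lists, forces, Langevin integration, Widom scans.

All kernels use orthogonal periodic boxes with minimum-image distances.
Positions are never wrapped by the integrator (bookkeeping such as MSD needs
unwrapped coordinates); wrapping happens only inside distance computations
and when histogramming.

Pair interactions are table-driven by bead-type pair: ``kind_tab[ti, tj]``
selects the functional form and ``p_tab[ti, tj, :3]`` its parameters.
Sparse bead types (free particles, few in number but with long interaction
ranges) are neighbor-listed by a wide cell scan so that the cell size can
follow the short bulk cutoffs.
"""

import numpy as np
from numba import njit

PAIR_NONE = 0
PAIR_WCA = 1  # params: eps, sigma
PAIR_COS_WELL = 2  # params: U0, r0  (sticker-sticker soft attraction)
PAIR_SHELL_WELL = 3  # params: eps, R, ra  (client-sticker shell attraction)

BOND_FENE = 0  # params: k, rmax
BOND_HARMONIC = 1  # params: kb, rb


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.rint(d / L)


@njit(cache=True)
def build_neighbors(
    pos, types, box, sparse_mask, rlist2_tab, bulk_rlist, max_rlist, excl_keys, pairs
):
    """Fill ``pairs`` with candidate interacting pairs; return count (-1 on overflow).

    Bulk-bulk pairs come from a 27-cell scan with cell size >= bulk_rlist;
    pairs involving a sparse-type bead come from a wide scan out to
    max_rlist.  Pairs in ``excl_keys`` (sorted i*n+j keys, i<j) are skipped.
    """
    n = pos.shape[0]
    cap = pairs.shape[0]
    count = 0
    ncx = max(1, int(box[0] / bulk_rlist))
    ncy = max(1, int(box[1] / bulk_rlist))
    ncz = max(1, int(box[2] / bulk_rlist))
    if ncx < 3 or ncy < 3 or ncz < 3:
        # box too small for cells: all-pairs with per-pair range check
        for i in range(n - 1):
            ti = types[i]
            for j in range(i + 1, n):
                tj = types[j]
                r2tab = rlist2_tab[ti, tj]
                if r2tab <= 0.0:
                    continue
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < r2tab:
                    key = i * n + j
                    k = np.searchsorted(excl_keys, key)
                    if k < excl_keys.shape[0] and excl_keys[k] == key:
                        continue
                    if count >= cap:
                        return -1
                    pairs[count, 0] = i
                    pairs[count, 1] = j
                    count += 1
        return count

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, np.int32)
    nxt = np.full(n, -1, np.int32)
    cix = np.empty(n, np.int32)
    ciy = np.empty(n, np.int32)
    ciz = np.empty(n, np.int32)
    for i in range(n):
        x = pos[i, 0] / box[0]
        y = pos[i, 1] / box[1]
        z = pos[i, 2] / box[2]
        cx = int((x - np.floor(x)) * ncx)
        cy = int((y - np.floor(y)) * ncy)
        cz = int((z - np.floor(z)) * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        cix[i] = cx
        ciy[i] = cy
        ciz[i] = cz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i

    # bulk-bulk pairs: 27-cell scan
    for i in range(n):
        if sparse_mask[types[i]]:
            continue
        ti = types[i]
        for ox in range(-1, 2):
            cx = (cix[i] + ox) % ncx
            for oy in range(-1, 2):
                cy = (ciy[i] + oy) % ncy
                for oz in range(-1, 2):
                    cz = (ciz[i] + oz) % ncz
                    j = head[(cx * ncy + cy) * ncz + cz]
                    while j >= 0:
                        if j > i and not sparse_mask[types[j]]:
                            tj = types[j]
                            r2tab = rlist2_tab[ti, tj]
                            if r2tab > 0.0:
                                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < r2tab:
                                    key = i * n + j
                                    k = np.searchsorted(excl_keys, key)
                                    if not (k < excl_keys.shape[0] and excl_keys[k] == key):
                                        if count >= cap:
                                            return -1
                                        pairs[count, 0] = i
                                        pairs[count, 1] = j
                                        count += 1
                        j = nxt[j]

    # sparse beads: wide scan out to max_rlist
    rcx = int(np.ceil(max_rlist / (box[0] / ncx)))
    rcy = int(np.ceil(max_rlist / (box[1] / ncy)))
    rcz = int(np.ceil(max_rlist / (box[2] / ncz)))
    for i in range(n):
        if not sparse_mask[types[i]]:
            continue
        ti = types[i]
        nx_span = min(2 * rcx + 1, ncx)
        ny_span = min(2 * rcy + 1, ncy)
        nz_span = min(2 * rcz + 1, ncz)
        for ax in range(nx_span):
            cx = (cix[i] - rcx + ax) % ncx if nx_span < ncx else ax
            for ay in range(ny_span):
                cy = (ciy[i] - rcy + ay) % ncy if ny_span < ncy else ay
                for az in range(nz_span):
                    cz = (ciz[i] - rcz + az) % ncz if nz_span < ncz else az
                    j = head[(cx * ncy + cy) * ncz + cz]
                    while j >= 0:
                        if j != i and (not sparse_mask[types[j]] or j > i):
                            tj = types[j]
                            r2tab = rlist2_tab[ti, tj]
                            if r2tab > 0.0:
                                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < r2tab:
                                    lo = min(i, j)
                                    hi = max(i, j)
                                    key = lo * n + hi
                                    k = np.searchsorted(excl_keys, key)
                                    if not (k < excl_keys.shape[0] and excl_keys[k] == key):
                                        if count >= cap:
                                            return -1
                                        pairs[count, 0] = lo
                                        pairs[count, 1] = hi
                                        count += 1
                        j = nxt[j]
    return count


@njit(cache=True, fastmath=True)
def compute_forces(
    pos, types, box, pairs, npairs, kind_tab, p_tab, cut2_tab,
    bond_i, bond_j, bond_kind, bond_p, frc,
):
    """Accumulate forces (kBT/nm) into ``frc``; return (epot, virial, ok).

    ``virial`` is sum over interactions of r_ij . f_ij (kBT); ``ok`` turns
    False on FENE overextension (r >= rmax), a numerical-instability signal.
    """
    frc[:] = 0.0
    epot = 0.0
    vir = 0.0
    ok = True
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        ti = types[i]
        tj = types[j]
        kind = kind_tab[ti, tj]
        if kind == PAIR_NONE:
            continue
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2_tab[ti, tj]:
            continue
        u = 0.0
        fr = 0.0  # -(dU/dr)/r; force on i is fr * (r_i - r_j)
        if kind == PAIR_WCA:
            eps = p_tab[ti, tj, 0]
            sig = p_tab[ti, tj, 1]
            s2 = sig * sig / r2
            s6 = s2 * s2 * s2
            u = 4.0 * eps * (s6 * s6 - s6) + eps
            fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        elif kind == PAIR_COS_WELL:
            u0 = p_tab[ti, tj, 0]
            r0 = p_tab[ti, tj, 1]
            r = np.sqrt(r2)
            u = -0.5 * u0 * (1.0 + np.cos(np.pi * r / r0))
            if r > 1e-12:
                fr = -0.5 * u0 * np.pi / r0 * np.sin(np.pi * r / r0) / r
        elif kind == PAIR_SHELL_WELL:
            eps = p_tab[ti, tj, 0]
            rc = p_tab[ti, tj, 1]
            ra = p_tab[ti, tj, 2]
            r = np.sqrt(r2)
            if np.abs(r - rc) <= ra:
                arg = np.pi * (r - rc) / ra
                u = -0.5 * eps * (1.0 + np.cos(arg))
                fr = -0.5 * eps * np.pi / ra * np.sin(arg) / r
        epot += u
        frc[i, 0] += fr * dx
        frc[i, 1] += fr * dy
        frc[i, 2] += fr * dz
        frc[j, 0] -= fr * dx
        frc[j, 1] -= fr * dy
        frc[j, 2] -= fr * dz
        vir += fr * r2

    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        fr = 0.0
        if bond_kind[b] == BOND_FENE:
            # finitely extensible spring plus its own WCA core (the bonded
            # pair is excluded from the nonbonded loop)
            k = bond_p[b, 0]
            rmax2 = bond_p[b, 1] * bond_p[b, 1]
            if r2 >= rmax2:
                ok = False
                continue
            epot += -0.5 * k * rmax2 * np.log(1.0 - r2 / rmax2)
            fr = -k / (1.0 - r2 / rmax2)
            eps = bond_p[b, 2]
            sig = bond_p[b, 3]
            if eps > 0.0 and r2 < 2.0 ** (1.0 / 3.0) * sig * sig:
                s2 = sig * sig / r2
                s6 = s2 * s2 * s2
                epot += 4.0 * eps * (s6 * s6 - s6) + eps
                fr += 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        else:  # harmonic, U = kb (r - rb)^2
            kb = bond_p[b, 0]
            rb = bond_p[b, 1]
            r = np.sqrt(r2)
            epot += kb * (r - rb) * (r - rb)
            if r > 1e-12:
                fr = -2.0 * kb * (r - rb) / r
        frc[i, 0] += fr * dx
        frc[i, 1] += fr * dy
        frc[i, 2] += fr * dz
        frc[j, 0] -= fr * dx
        frc[j, 1] -= fr * dy
        frc[j, 2] -= fr * dz
        vir += fr * r2
    return epot, vir, ok


@njit(cache=True, fastmath=True)
def add_wall_forces(pos, frc, wall_mask, wall_x, wall_k):
    """Harmonic confinement U = k (|x| - wall_x)^2 beyond |x| = wall_x."""
    e = 0.0
    for i in range(pos.shape[0]):
        if not wall_mask[i]:
            continue
        x = pos[i, 0]
        if x > wall_x:
            e += wall_k * (x - wall_x) ** 2
            frc[i, 0] -= 2.0 * wall_k * (x - wall_x)
        elif x < -wall_x:
            e += wall_k * (x + wall_x) ** 2
            frc[i, 0] -= 2.0 * wall_k * (x + wall_x)
    return e


@njit(cache=True, fastmath=True)
def baoab_chunk(
    pos, vel, frc, types, box, dt, acc_scale, c1_t, c2_t, noise,
    kind_tab, p_tab, cut2_tab, bond_i, bond_j, bond_kind, bond_p,
    wall_on, wall_mask, wall_x, wall_k,
    sparse_mask, rlist2_tab, bulk_rlist, max_rlist, excl_keys,
    pairs, skin,
):
    """Advance ``noise.shape[0]`` BAOAB Langevin steps.

    acc_scale[t] = kBT_mech / m_t converts forces (kBT/nm) to accelerations
    (nm/ns^2).  c1_t = exp(-dt/tau), c2_t = sqrt((1-c1^2) kBT_mech/m_t); with
    c1 = 1, c2 = 0 the scheme reduces to plain velocity Verlet.  ``frc``
    must contain forces consistent with ``pos`` on entry.  The neighbor
    list is rebuilt whenever twice the largest displacement since the last
    build approaches the skin.  Returns (epot, virial, status) with status
    0 ok, 1 FENE overextension, 2 neighbor-list overflow, 3 displacement
    blow-up.
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    half = 0.5 * dt
    epot = 0.0
    vir = 0.0
    npairs = build_neighbors(
        pos, types, box, sparse_mask, rlist2_tab, bulk_rlist, max_rlist, excl_keys, pairs
    )
    if npairs < 0:
        return 0.0, 0.0, 2
    ref = pos.copy()
    trigger = (0.45 * skin) ** 2  # rebuild when max displacement nears skin/2
    max_disp = 0.25 * min(box[0], min(box[1], box[2]))
    for s in range(nsteps):
        for i in range(n):
            a = acc_scale[types[i]]
            c1 = c1_t[types[i]]
            c2 = c2_t[types[i]]
            for d in range(3):
                v = vel[i, d] + half * frc[i, d] * a
                dx1 = half * v
                v = c1 * v + c2 * noise[s, i, d]
                dx2 = half * v
                if np.abs(dx1 + dx2) > max_disp:
                    return epot, vir, 3
                pos[i, d] += dx1 + dx2
                vel[i, d] = v
        moved = 0.0
        for i in range(n):
            d2 = (
                (pos[i, 0] - ref[i, 0]) ** 2
                + (pos[i, 1] - ref[i, 1]) ** 2
                + (pos[i, 2] - ref[i, 2]) ** 2
            )
            if d2 > moved:
                moved = d2
        if moved > trigger and s + 1 < nsteps:
            npairs = build_neighbors(
                pos, types, box, sparse_mask, rlist2_tab, bulk_rlist, max_rlist,
                excl_keys, pairs,
            )
            if npairs < 0:
                return epot, vir, 2
            ref[:] = pos
        epot, vir, ok = compute_forces(
            pos, types, box, pairs, npairs, kind_tab, p_tab, cut2_tab,
            bond_i, bond_j, bond_kind, bond_p, frc,
        )
        if not ok:
            return epot, vir, 1
        if wall_on:
            epot += add_wall_forces(pos, frc, wall_mask, wall_x, wall_k)
        for i in range(n):
            a = acc_scale[types[i]]
            for d in range(3):
                vel[i, d] += half * frc[i, d] * a
    return epot, vir, 0


@njit(cache=True, fastmath=True)
def widom_scan_points(points, pos, r_excl, box, radii):
    """Histogram of nearest-surface distances for hard-sphere insertion.

    For each probe point, d_eff = min_j (|p - r_j| - r_excl[j]); a probe of
    radius R is accepted iff R < d_eff.  Returns hist of length
    len(radii)+1 where hist[k] counts points accepting exactly the k
    smallest radii, so the acceptance count of radii[k] is sum(hist[k+1:]).
    ``radii`` must be sorted ascending.
    """
    nb = pos.shape[0]
    nr = radii.shape[0]
    hist = np.zeros(nr + 1, np.int64)
    rmax_c = 0.0
    for j in range(nb):
        if r_excl[j] > rmax_c:
            rmax_c = r_excl[j]
    q = radii[nr - 1] + rmax_c + 1e-9 if nr > 0 else rmax_c + 1e-9
    ncx = max(1, int(box[0] / q))
    ncy = max(1, int(box[1] / q))
    ncz = max(1, int(box[2] / q))
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3 and nb > 32
    head = np.full(ncx * ncy * ncz, -1, np.int32)
    nxt = np.full(nb, -1, np.int32)
    if use_cells:
        for j in range(nb):
            x = pos[j, 0] / box[0]
            y = pos[j, 1] / box[1]
            z = pos[j, 2] / box[2]
            cx = min(int((x - np.floor(x)) * ncx), ncx - 1)
            cy = min(int((y - np.floor(y)) * ncy), ncy - 1)
            cz = min(int((z - np.floor(z)) * ncz), ncz - 1)
            c = (cx * ncy + cy) * ncz + cz
            nxt[j] = head[c]
            head[c] = j
    big = 1e30
    for p in range(points.shape[0]):
        px = points[p, 0]
        py = points[p, 1]
        pz = points[p, 2]
        dmin = big
        if use_cells:
            fx = px / box[0]
            fy = py / box[1]
            fz = pz / box[2]
            cx0 = min(int((fx - np.floor(fx)) * ncx), ncx - 1)
            cy0 = min(int((fy - np.floor(fy)) * ncy), ncy - 1)
            cz0 = min(int((fz - np.floor(fz)) * ncz), ncz - 1)
            for ox in range(-1, 2):
                cx = (cx0 + ox) % ncx
                for oy in range(-1, 2):
                    cy = (cy0 + oy) % ncy
                    for oz in range(-1, 2):
                        cz = (cz0 + oz) % ncz
                        j = head[(cx * ncy + cy) * ncz + cz]
                        while j >= 0:
                            dx = _min_image(px - pos[j, 0], box[0])
                            dy = _min_image(py - pos[j, 1], box[1])
                            dz = _min_image(pz - pos[j, 2], box[2])
                            d = np.sqrt(dx * dx + dy * dy + dz * dz) - r_excl[j]
                            if d < dmin:
                                dmin = d
                            j = nxt[j]
        else:
            for j in range(nb):
                dx = _min_image(px - pos[j, 0], box[0])
                dy = _min_image(py - pos[j, 1], box[1])
                dz = _min_image(pz - pos[j, 2], box[2])
                d = np.sqrt(dx * dx + dy * dy + dz * dz) - r_excl[j]
                if d < dmin:
                    dmin = d
        # number of radii accepted = count of R strictly below d_eff
        # (R == d_eff is rejected, matching the hard-sphere indicator)
        idx = np.searchsorted(radii, dmin, side="left")
        hist[idx] += 1
    return hist
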