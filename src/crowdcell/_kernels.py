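"""Numba kernels: obstacle queries, random-walk propagation, reaction sweeps.

All lengths are in micrometres and times in seconds.  A geometry is passed
around as flat arrays (cylinder centres/axes/half-lengths/radii, sphere
centres/radii) plus a uniform-grid index.  The grid registers every obstacle
in all cells whose centre lies within ``r_obstacle + reach + h*sqrt(3)/2`` of
the obstacle, so a query that looks only at the cell containing the query
point sees a superset of all obstacles within ``r_obstacle + probe`` of it,
for any probe radius ``probe <= reach``.
"""

import numpy as np
from numba import njit

_SQ3H = 0.8660254037844386  # sqrt(3)/2


@njit(cache=True, inline="always")
def _seg_dist2(px, py, pz, cx, cy, cz, ax, ay, az, h):
    """Squared distance from point to the axis segment of a capsule."""
    vx = px - cx
    vy = py - cy
    vz = pz - cz
    t = vx * ax + vy * ay + vz * az
    if t > h:
        t = h
    elif t < -h:
        t = -h
    dx = vx - t * ax
    dy = vy - t * ay
    dz = vz - t * az
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _grid_register(cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                   gmin, h, nx, ny, nz, reach, counts, starts, entries, fill):
    """One rasterisation pass. fill=0 counts per cell, fill=1 writes entries."""
    ncyl = cyl_h.shape[0]
    nsph = sph_r.shape[0]
    if fill == 1:
        cursor = counts.astype(np.int64)  # running offset per cell
    else:
        cursor = np.zeros(1, np.int64)  # unused in count pass
    for o in range(ncyl + nsph):
        if o < ncyl:
            reg = cyl_r[o] + reach + h * _SQ3H
            ex = cyl_h[o] * abs(cyl_a[o, 0]) + reg
            ey = cyl_h[o] * abs(cyl_a[o, 1]) + reg
            ez = cyl_h[o] * abs(cyl_a[o, 2]) + reg
            cx = cyl_c[o, 0]
            cy = cyl_c[o, 1]
            cz = cyl_c[o, 2]
        else:
            s = o - ncyl
            reg = sph_r[s] + reach + h * _SQ3H
            ex = reg
            ey = reg
            ez = reg
            cx = sph_c[s, 0]
            cy = sph_c[s, 1]
            cz = sph_c[s, 2]
        i0 = max(0, int((cx - ex - gmin[0]) / h))
        i1 = min(nx - 1, int((cx + ex - gmin[0]) / h))
        j0 = max(0, int((cy - ey - gmin[1]) / h))
        j1 = min(ny - 1, int((cy + ey - gmin[1]) / h))
        k0 = max(0, int((cz - ez - gmin[2]) / h))
        k1 = min(nz - 1, int((cz + ez - gmin[2]) / h))
        reg2 = reg * reg
        for ix in range(i0, i1 + 1):
            qx = gmin[0] + (ix + 0.5) * h
            for iy in range(j0, j1 + 1):
                qy = gmin[1] + (iy + 0.5) * h
                for iz in range(k0, k1 + 1):
                    qz = gmin[2] + (iz + 0.5) * h
                    if o < ncyl:
                        d2 = _seg_dist2(qx, qy, qz, cx, cy, cz,
                                        cyl_a[o, 0], cyl_a[o, 1], cyl_a[o, 2],
                                        cyl_h[o])
                    else:
                        dx = qx - cx
                        dy = qy - cy
                        dz = qz - cz
                        d2 = dx * dx + dy * dy + dz * dz
                    if d2 <= reg2:
                        cell = (ix * ny + iy) * nz + iz
                        if fill == 0:
                            counts[cell] += 1
                        else:
                            entries[starts[cell] + cursor[cell]] = o
                            cursor[cell] += 1


def build_grid(cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
               gmin, h, nx, ny, nz, reach):
    """Build CSR cell lists (starts, entries) for the obstacle set."""
    K = nx * ny * nz
    counts = np.zeros(K, np.int64)
    dummy_s = np.zeros(1, np.int64)
    dummy_e = np.zeros(1, np.int32)
    _grid_register(cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                   gmin, h, nx, ny, nz, reach, counts, dummy_s, dummy_e, 0)
    starts = np.zeros(K + 1, np.int64)
    np.cumsum(counts, out=starts[1:])
    entries = np.empty(starts[-1], np.int32)
    counts[:] = 0
    _grid_register(cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                   gmin, h, nx, ny, nz, reach, counts, starts, entries, 1)
    return starts, entries


@njit(cache=True, inline="always")
def _point_free(x, y, z, probe, Rcell,
                cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                gmin, h, nx, ny, nz, starts, entries):
    """True iff a probe sphere at (x,y,z) is inside the cell and obstacle-free."""
    lim = Rcell - probe
    if lim < 0.0:
        return False
    if x * x + y * y + z * z > lim * lim:
        return False
    ix = int((x - gmin[0]) / h)
    iy = int((y - gmin[1]) / h)
    iz = int((z - gmin[2]) / h)
    if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
        return True
    cell = (ix * ny + iy) * nz + iz
    ncyl = cyl_h.shape[0]
    for e in range(starts[cell], starts[cell + 1]):
        o = entries[e]
        if o < ncyl:
            rr = cyl_r[o] + probe
            d2 = _seg_dist2(x, y, z, cyl_c[o, 0], cyl_c[o, 1], cyl_c[o, 2],
                            cyl_a[o, 0], cyl_a[o, 1], cyl_a[o, 2], cyl_h[o])
            if d2 < rr * rr:
                return False
        else:
            s = o - ncyl
            rr = sph_r[s] + probe
            dx = x - sph_c[s, 0]
            dy = y - sph_c[s, 1]
            dz = z - sph_c[s, 2]
            if dx * dx + dy * dy + dz * dz < rr * rr:
                return False
    return True


@njit(cache=True, inline="always")
def _min_structure_sep(x, y, z, radius,
                       cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                       gmin, h, nx, ny, nz, starts, entries):
    """Smallest surface-to-surface gap to obstacles registered at this cell.

    Only reliable when the true gap is below the grid's reach margin; larger
    returns just mean "far away".
    """
    best = 1.0e30
    ix = int((x - gmin[0]) / h)
    iy = int((y - gmin[1]) / h)
    iz = int((z - gmin[2]) / h)
    if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
        return best
    cell = (ix * ny + iy) * nz + iz
    ncyl = cyl_h.shape[0]
    for e in range(starts[cell], starts[cell + 1]):
        o = entries[e]
        if o < ncyl:
            d2 = _seg_dist2(x, y, z, cyl_c[o, 0], cyl_c[o, 1], cyl_c[o, 2],
                            cyl_a[o, 0], cyl_a[o, 1], cyl_a[o, 2], cyl_h[o])
            sep = np.sqrt(d2) - cyl_r[o] - radius
        else:
            s = o - ncyl
            dx = x - sph_c[s, 0]
            dy = y - sph_c[s, 1]
            dz = z - sph_c[s, 2]
            sep = np.sqrt(dx * dx + dy * dy + dz * dz) - sph_r[s] - radius
        if sep < best:
            best = sep
    return best


@njit(cache=True)
def _sample_excluded(n, probe, seed, Rcell,
                     cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                     gmin, h, nx, ny, nz, starts, entries):
    """Count uniform points in the cell ball that are blocked for the probe."""
    np.random.seed(seed)
    blocked = 0
    # sample the probe-centre domain (radius R - probe) so the fraction
    # reflects obstacle crowding, not the trivial membrane shell
    Rs = Rcell - probe
    R2 = Rs * Rs
    for _ in range(n):
        while True:
            x = (2.0 * np.random.random() - 1.0) * Rs
            y = (2.0 * np.random.random() - 1.0) * Rs
            z = (2.0 * np.random.random() - 1.0) * Rs
            if x * x + y * y + z * z <= R2:
                break
        if not _point_free(x, y, z, probe, Rcell, cyl_c, cyl_a, cyl_h, cyl_r,
                           sph_c, sph_r, gmin, h, nx, ny, nz, starts, entries):
            blocked += 1
    return blocked


@njit(cache=True)
def _sample_access(n_centers, n_shell, r_i, r_j, seed, max_tries, Rcell,
                   cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                   gmin, h, nx, ny, nz, starts, entries):
    """Mean accessible fraction of the interaction ball over accessible centres.

    Centres are drawn accessible for a probe of radius r_i (inside the cell,
    off the obstacles); partner positions in the interaction ball are scored
    against the obstacles only, so an empty geometry gives exactly 1.
    Returns (mean, sum of squared deviations accumulator, n_done); n_done <
    n_centers signals rejection-sampling saturation.
    """
    np.random.seed(seed)
    R2 = Rcell * Rcell
    Rint = r_i + r_j
    mean = 0.0
    m2 = 0.0
    n_done = 0
    for c in range(n_centers):
        ok = False
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for _ in range(max_tries):
            while True:
                cx = (2.0 * np.random.random() - 1.0) * Rcell
                cy = (2.0 * np.random.random() - 1.0) * Rcell
                cz = (2.0 * np.random.random() - 1.0) * Rcell
                if cx * cx + cy * cy + cz * cz <= R2:
                    break
            if _point_free(cx, cy, cz, r_i, Rcell, cyl_c, cyl_a, cyl_h, cyl_r,
                           sph_c, sph_r, gmin, h, nx, ny, nz, starts, entries):
                ok = True
                break
        if not ok:
            break
        acc = 0
        for _ in range(n_shell):
            while True:
                dx = (2.0 * np.random.random() - 1.0) * Rint
                dy = (2.0 * np.random.random() - 1.0) * Rint
                dz = (2.0 * np.random.random() - 1.0) * Rint
                if dx * dx + dy * dy + dz * dz <= Rint * Rint:
                    break
            if _point_free(cx + dx, cy + dy, cz + dz, r_j, 1.0e30,
                           cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                           gmin, h, nx, ny, nz, starts, entries):
                acc += 1
        f = acc / n_shell
        n_done += 1
        d = f - mean
        mean += d / n_done
        m2 += d * (f - mean)
    return mean, m2, n_done


@njit(cache=True)
def _sample_surface_accessible(n, probe, seed, area_cum, Rcell,
                               cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                               gmin, h, nx, ny, nz, starts, entries):
    """Fraction of obstacle surface reachable by a probe of given radius.

    Surface points are drawn proportional to nominal area (cylinder lateral
    surfaces first, then spheres, per ``area_cum``); a point counts as
    reachable when a probe centre offset outward by the probe radius is
    accessible.
    """
    np.random.seed(seed)
    ncyl = cyl_h.shape[0]
    total = area_cum[-1]
    hits = 0
    eps = 1.0 + 1.0e-9
    for _ in range(n):
        u = np.random.random() * total
        o = np.searchsorted(area_cum, u)
        if o < ncyl:
            t = (2.0 * np.random.random() - 1.0) * cyl_h[o]
            # random unit vector perpendicular to the axis
            while True:
                vx = np.random.normal()
                vy = np.random.normal()
                vz = np.random.normal()
                dot = vx * cyl_a[o, 0] + vy * cyl_a[o, 1] + vz * cyl_a[o, 2]
                vx -= dot * cyl_a[o, 0]
                vy -= dot * cyl_a[o, 1]
                vz -= dot * cyl_a[o, 2]
                nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
                if nrm > 1.0e-12:
                    break
            off = (cyl_r[o] + probe) * eps / nrm
            x = cyl_c[o, 0] + t * cyl_a[o, 0] + vx * off
            y = cyl_c[o, 1] + t * cyl_a[o, 1] + vy * off
            z = cyl_c[o, 2] + t * cyl_a[o, 2] + vz * off
        else:
            s = o - ncyl
            vx = np.random.normal()
            vy = np.random.normal()
            vz = np.random.normal()
            nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
            off = (sph_r[s] + probe) * eps / nrm
            x = sph_c[s, 0] + vx * off
            y = sph_c[s, 1] + vy * off
            z = sph_c[s, 2] + vz * off
        if _point_free(x, y, z, probe, Rcell, cyl_c, cyl_a, cyl_h, cyl_r,
                       sph_c, sph_r, gmin, h, nx, ny, nz, starts, entries):
            hits += 1
    return hits


@njit(cache=True)
def _tracer_run(pos, bound, radius, D0, dt, n_steps, record_every,
                kappa_ads, k_diss, bind_membrane, bind_structures, seed,
                Rcell, cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
                gmin, h, nx, ny, nz, starts, entries,
                out_pos, out_bound):
    """Propagate inert tracers; optional surface adsorption/dissociation.

    Positions and bound flags are recorded every ``record_every`` steps
    (including the initial state) into the pre-allocated outputs.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    sigma = np.sqrt(2.0 * D0 * dt)
    layer = kappa_ads * dt
    p_diss = k_diss * dt
    rec = 0
    for i in range(n):
        out_pos[rec, i, 0] = pos[i, 0]
        out_pos[rec, i, 1] = pos[i, 1]
        out_pos[rec, i, 2] = pos[i, 2]
        out_bound[rec, i] = bound[i]
    rec += 1
    for step in range(1, n_steps + 1):
        for i in range(n):
            if not bound[i] and sigma > 0.0:
                x = pos[i, 0] + sigma * np.random.normal()
                y = pos[i, 1] + sigma * np.random.normal()
                z = pos[i, 2] + sigma * np.random.normal()
                if _point_free(x, y, z, radius, Rcell, cyl_c, cyl_a, cyl_h,
                               cyl_r, sph_c, sph_r, gmin, h, nx, ny, nz,
                               starts, entries):
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
            if bound[i]:
                if p_diss > 0.0 and np.random.random() < p_diss:
                    bound[i] = False
            elif layer > 0.0:
                sep = 1.0e30
                if bind_structures:
                    sep = _min_structure_sep(pos[i, 0], pos[i, 1], pos[i, 2],
                                             radius, cyl_c, cyl_a, cyl_h,
                                             cyl_r, sph_c, sph_r, gmin, h,
                                             nx, ny, nz, starts, entries)
                if bind_membrane:
                    nrm = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2
                                  + pos[i, 2] ** 2)
                    msep = Rcell - nrm - radius
                    if msep < sep:
                        sep = msep
                if sep < layer:
                    bound[i] = True
        if step % record_every == 0:
            for i in range(n):
                out_pos[rec, i, 0] = pos[i, 0]
                out_pos[rec, i, 1] = pos[i, 1]
                out_pos[rec, i, 2] = pos[i, 2]
                out_bound[rec, i] = bound[i]
            rec += 1
    return rec


@njit(cache=True)
def _advance(pos, sp, bound, alive, n_used0,
             sp_radius, sp_D, sp_kads, sp_kdiss, sp_bind_mem, sp_bind_str,
             sp_static,
             dt, n_steps, obs_every, seed,
             Rcell, cyl_c, cyl_a, cyl_h, cyl_r, sph_c, sph_r,
             gmin, gh, gnx, gny, gnz, gstarts, gentries,
             bi_e1, bi_e2, bi_rcrit2, bi_p, bi_pr1, bi_pr2,
             un_e, un_prob, un_pr1, un_pr2,
             z_sp, z_mean, z_region, z_thick,
             x_sp, x_layer,
             pg_n, pg_h, st_n, st_h,
             out_counts, out_bound_counts, out_events):
    """Advance the full simulation state by ``n_steps`` timesteps.

    Step order: diffusion -> adsorption/dissociation -> bimolecular ->
    unimolecular -> zero-order creation -> membrane export -> observation.
    Returns (n_used, overflow_flag, placement_fail_flag).
    """
    np.random.seed(seed)
    C = pos.shape[0]
    S = sp_radius.shape[0]
    nbi = bi_e1.shape[0]
    nun = un_e.shape[0]
    nz_ = z_sp.shape[0]
    nx_ = x_sp.shape[0]
    n_used = n_used0
    overflow = 0
    placement_fail = 0

    any_ads = False
    for s in range(S):
        if sp_kads[s] > 0.0 or sp_kdiss[s] > 0.0:
            any_ads = True

    # dynamic pair grid: epoch-stamped linked lists (no per-step clearing);
    # particles of permanently immobile species go into a CSR grid built once
    K = pg_n * pg_n * pg_n
    pg_head = np.full(K, -1, np.int32)
    pg_epoch = np.full(K, -1, np.int64)
    pg_next = np.empty(C, np.int32)
    pg_cell = np.empty(C, np.int32)
    pg_org = -Rcell - pg_h

    mob = np.empty(C, np.int32)
    n_mob = 0
    for i in range(n_used):
        if not sp_static[sp[i]]:
            mob[n_mob] = i
            n_mob += 1

    KS = st_n * st_n * st_n
    st_org = -Rcell - st_h
    st_count = np.zeros(KS, np.int32)
    st_start = np.zeros(KS + 1, np.int32)
    st_items = np.empty(C, np.int32)
    for i in range(n_used):
        if alive[i] and sp_static[sp[i]]:
            ix = int((pos[i, 0] - st_org) / st_h)
            iy = int((pos[i, 1] - st_org) / st_h)
            iz = int((pos[i, 2] - st_org) / st_h)
            st_count[(ix * st_n + iy) * st_n + iz] += 1
    acc0 = 0
    for c in range(KS):
        st_start[c] = acc0
        acc0 += st_count[c]
        st_count[c] = 0
    st_start[KS] = acc0
    for i in range(n_used):
        if alive[i] and sp_static[sp[i]]:
            ix = int((pos[i, 0] - st_org) / st_h)
            iy = int((pos[i, 1] - st_org) / st_h)
            iz = int((pos[i, 2] - st_org) / st_h)
            cell = (ix * st_n + iy) * st_n + iz
            st_items[st_start[cell] + st_count[cell]] = i
            st_count[cell] += 1

    cand_cap = 65536
    cand_i = np.empty(cand_cap, np.int32)
    cand_j = np.empty(cand_cap, np.int32)
    cand_ch = np.empty(cand_cap, np.int32)
    stamp = np.full(C, -1, np.int32)

    events = np.zeros(nbi + nun + nz_ + nx_, np.int64)

    # observation row 0: initial state
    obs_row = 0
    for s in range(S):
        out_counts[obs_row, s] = 0
        out_bound_counts[obs_row, s] = 0
    for i in range(n_used):
        if alive[i]:
            out_counts[obs_row, sp[i]] += 1
            if bound[i]:
                out_bound_counts[obs_row, sp[i]] += 1
    for c in range(events.shape[0]):
        out_events[obs_row, c] = 0
    obs_row += 1

    for step in range(1, n_steps + 1):
        # --- diffusion (whole-step rejection) ---
        for m in range(n_mob):
            i = mob[m]
            if alive[i] and not bound[i]:
                s = sp[i]
                D = sp_D[s]
                if D > 0.0:
                    sg = np.sqrt(2.0 * D * dt)
                    x = pos[i, 0] + sg * np.random.normal()
                    y = pos[i, 1] + sg * np.random.normal()
                    z = pos[i, 2] + sg * np.random.normal()
                    if _point_free(x, y, z, sp_radius[s], Rcell, cyl_c, cyl_a,
                                   cyl_h, cyl_r, sph_c, sph_r, gmin, gh,
                                   gnx, gny, gnz, gstarts, gentries):
                        pos[i, 0] = x
                        pos[i, 1] = y
                        pos[i, 2] = z
        # --- adsorption / dissociation ---
        if any_ads:
            for m in range(n_mob):
                i = mob[m]
                if not alive[i]:
                    continue
                s = sp[i]
                if bound[i]:
                    pd = sp_kdiss[s] * dt
                    if pd > 0.0 and np.random.random() < pd:
                        bound[i] = False
                elif sp_kads[s] > 0.0:
                    layer = sp_kads[s] * dt
                    sep = 1.0e30
                    if sp_bind_str[s]:
                        sep = _min_structure_sep(pos[i, 0], pos[i, 1],
                                                 pos[i, 2], sp_radius[s],
                                                 cyl_c, cyl_a, cyl_h, cyl_r,
                                                 sph_c, sph_r, gmin, gh,
                                                 gnx, gny, gnz, gstarts,
                                                 gentries)
                    if sp_bind_mem[s]:
                        nrm = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2
                                      + pos[i, 2] ** 2)
                        msep = Rcell - nrm - sp_radius[s]
                        if msep < sep:
                            sep = msep
                    if sep < layer:
                        bound[i] = True
        # --- bimolecular reactions ---
        if nbi > 0:
            for m in range(n_mob):
                i = mob[m]
                if alive[i]:
                    ix = int((pos[i, 0] - pg_org) / pg_h)
                    iy = int((pos[i, 1] - pg_org) / pg_h)
                    iz = int((pos[i, 2] - pg_org) / pg_h)
                    cell = (ix * pg_n + iy) * pg_n + iz
                    pg_cell[i] = cell
                    if pg_epoch[cell] != step:
                        pg_epoch[cell] = step
                        pg_head[cell] = -1
                    pg_next[i] = pg_head[cell]
                    pg_head[cell] = i
                else:
                    pg_cell[i] = -1
            ncand = 0
            for ch in range(nbi):
                e1 = bi_e1[ch]
                e2 = bi_e2[ch]
                r2 = bi_rcrit2[ch]
                e2_static = sp_static[e2]
                for m in range(n_mob):
                    i = mob[m]
                    if not alive[i] or sp[i] != e1:
                        continue
                    if e2_static:
                        gi = int((pos[i, 0] - st_org) / st_h)
                        gj = int((pos[i, 1] - st_org) / st_h)
                        gk = int((pos[i, 2] - st_org) / st_h)
                        gn = st_n
                    else:
                        cell = pg_cell[i]
                        gi = cell // (pg_n * pg_n)
                        gj = (cell // pg_n) % pg_n
                        gk = cell % pg_n
                        gn = pg_n
                    for di in range(-1, 2):
                        ai = gi + di
                        if ai < 0 or ai >= gn:
                            continue
                        for dj in range(-1, 2):
                            aj = gj + dj
                            if aj < 0 or aj >= gn:
                                continue
                            for dk in range(-1, 2):
                                ak = gk + dk
                                if ak < 0 or ak >= gn:
                                    continue
                                nc = (ai * gn + aj) * gn + ak
                                if e2_static:
                                    for q in range(st_start[nc],
                                                   st_start[nc + 1]):
                                        j = st_items[q]
                                        if not alive[j] or sp[j] != e2:
                                            continue
                                        dx = pos[i, 0] - pos[j, 0]
                                        dy = pos[i, 1] - pos[j, 1]
                                        dz = pos[i, 2] - pos[j, 2]
                                        if dx * dx + dy * dy + dz * dz < r2:
                                            if ncand < cand_cap:
                                                cand_i[ncand] = i
                                                cand_j[ncand] = j
                                                cand_ch[ncand] = ch
                                                ncand += 1
                                            else:
                                                overflow = 1
                                else:
                                    if pg_epoch[nc] != step:
                                        continue
                                    j = pg_head[nc]
                                    while j >= 0:
                                        if (j != i and alive[j]
                                                and sp[j] == e2
                                                and not (e1 == e2
                                                         and j < i)):
                                            dx = pos[i, 0] - pos[j, 0]
                                            dy = pos[i, 1] - pos[j, 1]
                                            dz = pos[i, 2] - pos[j, 2]
                                            if (dx * dx + dy * dy
                                                    + dz * dz < r2):
                                                if ncand < cand_cap:
                                                    cand_i[ncand] = i
                                                    cand_j[ncand] = j
                                                    cand_ch[ncand] = ch
                                                    ncand += 1
                                                else:
                                                    overflow = 1
                                        j = pg_next[j]
            # visit candidate pairs in uniformly random order
            for c in range(ncand - 1, 0, -1):
                r = np.random.randint(0, c + 1)
                ti = cand_i[c]
                cand_i[c] = cand_i[r]
                cand_i[r] = ti
                tj = cand_j[c]
                cand_j[c] = cand_j[r]
                cand_j[r] = tj
                tc = cand_ch[c]
                cand_ch[c] = cand_ch[r]
                cand_ch[r] = tc
            for c in range(ncand):
                i = cand_i[c]
                j = cand_j[c]
                ch = cand_ch[c]
                if (stamp[i] == step or stamp[j] == step
                        or not alive[i] or not alive[j]):
                    continue
                if np.random.random() < bi_p[ch]:
                    stamp[i] = step
                    stamp[j] = step
                    p1 = bi_pr1[ch]
                    p2 = bi_pr2[ch]
                    if p1 < 0:
                        alive[i] = False
                    elif p1 != sp[i]:
                        sp[i] = p1
                    if p2 < 0:
                        alive[j] = False
                    elif p2 != sp[j]:
                        sp[j] = p2
                    events[ch] += 1
        # --- unimolecular conversions ---
        for ch in range(nun):
            e = un_e[ch]
            pr = un_prob[ch]
            nm0 = n_mob
            for m in range(nm0):
                i = mob[m]
                if alive[i] and sp[i] == e and stamp[i] != step:
                    if np.random.random() < pr:
                        stamp[i] = step
                        p1 = un_pr1[ch]
                        if p1 < 0:
                            alive[i] = False
                        elif p1 != e:
                            sp[i] = p1
                        p2 = un_pr2[ch]
                        if p2 >= 0:
                            if n_used < C:
                                pos[n_used, 0] = pos[i, 0]
                                pos[n_used, 1] = pos[i, 1]
                                pos[n_used, 2] = pos[i, 2]
                                sp[n_used] = p2
                                bound[n_used] = False
                                alive[n_used] = True
                                stamp[n_used] = step
                                mob[n_mob] = n_used
                                n_mob += 1
                                n_used += 1
                            else:
                                overflow = 1
                        events[nbi + ch] += 1
        # --- zero-order creation ---
        for ch in range(nz_):
            nnew = np.random.poisson(z_mean[ch])
            s = z_sp[ch]
            rad = sp_radius[s]
            for _ in range(nnew):
                placed = False
                for _try in range(2000):
                    if z_region[ch] == 0:
                        rmax = Rcell - rad
                        x = (2.0 * np.random.random() - 1.0) * rmax
                        y = (2.0 * np.random.random() - 1.0) * rmax
                        z = (2.0 * np.random.random() - 1.0) * rmax
                        if x * x + y * y + z * z > rmax * rmax:
                            continue
                    else:
                        b = Rcell - rad
                        a = b - z_thick[ch]
                        if a < 0.0:
                            a = 0.0
                        u = np.random.random()
                        rr = (a ** 3 + u * (b ** 3 - a ** 3)) ** (1.0 / 3.0)
                        vx = np.random.normal()
                        vy = np.random.normal()
                        vz = np.random.normal()
                        nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
                        x = vx / nrm * rr
                        y = vy / nrm * rr
                        z = vz / nrm * rr
                    if _point_free(x, y, z, rad, Rcell, cyl_c, cyl_a, cyl_h,
                                   cyl_r, sph_c, sph_r, gmin, gh, gnx, gny,
                                   gnz, gstarts, gentries):
                        placed = True
                        break
                if not placed:
                    placement_fail = 1
                    continue
                if n_used < C:
                    pos[n_used, 0] = x
                    pos[n_used, 1] = y
                    pos[n_used, 2] = z
                    sp[n_used] = s
                    bound[n_used] = False
                    alive[n_used] = True
                    stamp[n_used] = -1
                    mob[n_mob] = n_used
                    n_mob += 1
                    n_used += 1
                    events[nbi + nun + ch] += 1
                else:
                    overflow = 1
        # --- membrane export (capture layer, probability 1) ---
        for ch in range(nx_):
            s = x_sp[ch]
            thr = Rcell - sp_radius[s] - x_layer[ch]
            thr2 = thr * thr
            for m in range(n_mob):
                i = mob[m]
                if alive[i] and sp[i] == s:
                    d2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
                    if d2 > thr2:
                        alive[i] = False
                        events[nbi + nun + nz_ + ch] += 1
        # --- observation ---
        if step % obs_every == 0:
            for s in range(S):
                out_counts[obs_row, s] = 0
                out_bound_counts[obs_row, s] = 0
            for i in range(n_used):
                if alive[i]:
                    out_counts[obs_row, sp[i]] += 1
                    if bound[i]:
                        out_bound_counts[obs_row, sp[i]] += 1
            for c in range(events.shape[0]):
                out_events[obs_row, c] = events[c]
            obs_row += 1
    return n_used, overflow, placement_fail
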