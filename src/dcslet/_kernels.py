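"""Numba-compiled condensed-history transport core.

One compiled routine advances a whole batch of protons, history by history,
through vacuum gaps, nickel trimmer blades and the water phantom.  Each
history index seeds its own random stream, so results are independent of
batch splitting and bit-reproducible for a given base seed.

The physics per step: deterministic mean electronic loss from the stopping
table, Gaussian (Bohr) energy-loss straggling, Highland multiple Coulomb
scattering, and an optional lumped nuclear-interaction surrogate in water.
Every step inside the phantom is split exactly at voxel faces and tallied
into the (sum_e, sum_l, sum_e2/l) accumulators; the straggled energy loss is
both subtracted from the proton and deposited, so energy is conserved per
history to rounding.
"""

import math

import numpy as np
from numba import njit

# medium codes
VACUUM, WATER, NICKEL = 0, 1, 2
# energy-accounting sinks (per-batch ledger indices)
ACC_PHANTOM, ACC_COLLIMATOR, ACC_ESCAPED, ACC_BINDING = 0, 1, 2, 3

MAX_STACK = 64


@njit(cache=True)
def _interp(x, xs, ys):
    """Linear interpolation with flat extrapolation (xs strictly increasing)."""
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    t = (x - xs[lo]) / (xs[lo + 1] - xs[lo])
    return ys[lo] + t * (ys[lo + 1] - ys[lo])


@njit(cache=True)
def _stop_power(E, log_e, log_s):
    """Mass stopping power, MeV cm^2/g, log-log interpolated."""
    return math.exp(_interp(math.log(E), log_e, log_s))


@njit(cache=True)
def _highland_theta0(E, path_gcm2, X0_gcm2):
    """Highland MCS angle (radians) for a proton, clamped >= 0."""
    if path_gcm2 <= 0.0:
        return 0.0
    mp = 938.27208816
    pc = math.sqrt(E * (E + 2.0 * mp))
    beta = pc / (E + mp)
    ratio = path_gcm2 / X0_gcm2
    bracket = 1.0 + 0.038 * math.log(ratio)
    if bracket < 0.0:
        bracket = 0.0
    return 13.6 / (beta * pc) * math.sqrt(ratio) * bracket


@njit(cache=True)
def _bohr_sigma(E, Z_over_A, rho, ds):
    """Bohr energy-loss straggling sigma (MeV) over path ds (cm)."""
    mp = 938.27208816
    gamma = 1.0 + E / mp
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    rel = (1.0 - 0.5 * beta2) / (1.0 - beta2)
    var = 0.1569 * Z_over_A * rho * ds * rel
    return math.sqrt(var)


@njit(cache=True)
def _in_blade(x, y, z, blades):
    for b in range(blades.shape[0]):
        if blades[b, 2] <= z <= blades[b, 3]:
            u = x if blades[b, 0] == 0.0 else y
            side = blades[b, 1]
            edge = side * blades[b, 4] * (z + blades[b, 5]) \
                / (blades[b, 6] + blades[b, 5])
            d = side * u - side * edge
            if 0.0 <= d <= blades[b, 7]:
                return True
    return False


@njit(cache=True)
def _score_segment(sum_e, sum_l, sum_e2l, ox, oy, oz, sx, sy, sz,
                   nx, ny, nz, x0, y0, z0, x1, y1, z1, eps, l):
    """Split segment at voxel faces; tally (eps_j, l_j, eps_j^2/l_j)."""
    dx, dy, dz = x1 - x0, y1 - y0, z1 - z0
    seg = math.sqrt(dx * dx + dy * dy + dz * dz)
    if seg <= 0.0 or l <= 0.0:
        return
    # clip to grid box
    t0, t1 = 0.0, 1.0
    for a in range(3):
        if a == 0:
            p, d, lo, hi = x0, dx, ox, ox + nx * sx
        elif a == 1:
            p, d, lo, hi = y0, dy, oy, oy + ny * sy
        else:
            p, d, lo, hi = z0, dz, oz, oz + nz * sz
        if d == 0.0:
            if p < lo or p >= hi:
                return
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 <= t0:
        return
    t = t0
    while t < t1 - 1e-12:
        # voxel at the current sub-segment start (nudged inward)
        xm = x0 + (t + 1e-12) * dx
        ym = y0 + (t + 1e-12) * dy
        zm = z0 + (t + 1e-12) * dz
        i = int(math.floor((xm - ox) / sx))
        j = int(math.floor((ym - oy) / sy))
        k = int(math.floor((zm - oz) / sz))
        if i < 0:
            i = 0
        if j < 0:
            j = 0
        if k < 0:
            k = 0
        if i >= nx:
            i = nx - 1
        if j >= ny:
            j = ny - 1
        if k >= nz:
            k = nz - 1
        # parametric exit of this voxel
        tn = t1
        if dx > 0.0:
            tc = (ox + (i + 1) * sx - x0) / dx
            if tc < tn:
                tn = tc
        elif dx < 0.0:
            tc = (ox + i * sx - x0) / dx
            if tc < tn:
                tn = tc
        if dy > 0.0:
            tc = (oy + (j + 1) * sy - y0) / dy
            if tc < tn:
                tn = tc
        elif dy < 0.0:
            tc = (oy + j * sy - y0) / dy
            if tc < tn:
                tn = tc
        if dz > 0.0:
            tc = (oz + (k + 1) * sz - z0) / dz
            if tc < tn:
                tn = tc
        elif dz < 0.0:
            tc = (oz + k * sz - z0) / dz
            if tc < tn:
                tn = tc
        if tn <= t:
            tn = t + 1e-10
        lj = (tn - t) * seg
        if lj > 0.0:
            frac = lj / l
            sum_e[i, j, k] += eps * frac
            sum_l[i, j, k] += lj
            sum_e2l[i, j, k] += eps * eps * frac / l
        t = tn


@njit(cache=True)
def _score_point(sum_e, ox, oy, oz, sx, sy, sz, nx, ny, nz, x, y, z, eps):
    i = int(math.floor((x - ox) / sx))
    j = int(math.floor((y - oy) / sy))
    k = int(math.floor((z - oz) / sz))
    if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
        sum_e[i, j, k] += eps


@njit(cache=True)
def run_batch(x0a, y0a, z0a, dxa, dya, dza, E0a, tag0a, base_seed,
              blades,
              log_e, log_s_w, log_s_ni, e_nodes, range_w, range_ni,
              rho_w, rho_ni, za_w, za_ni, x0m_w, x0m_ni,
              max_step_w, max_step_ni, cutoff,
              nuclear_on, nuc_rate, nuc_local_frac,
              straggle_on, scatter_on,
              ph_lo, ph_hi,
              score_on, gox, goy, goz, gsx, gsy, gsz, gnx, gny, gnz,
              sum_e, sum_l, sum_e2l, sum_e_pt,
              plane_z, rec_E, rec_x, rec_y, rec_tag,
              hist_initial, hist_accounted, sinks):
    """Transport a batch; returns the number of plane crossings recorded.

    ``sinks`` accumulates [phantom deposit, collimator deposit, escaped,
    nuclear binding]; ``hist_initial`` / ``hist_accounted`` hold the
    per-history energy ledger for the conservation contract.
    """
    n = x0a.shape[0]
    world_half = 25.0
    world_zmax = ph_hi[2] if ph_hi[2] > 0.0 else 0.1
    # vacuum z boundaries: blade slab faces, phantom entry, world end
    nb = blades.shape[0]
    zb = np.empty(2 * nb + 2)
    for b in range(nb):
        zb[2 * b] = blades[b, 2]
        zb[2 * b + 1] = blades[b, 3]
    zb[2 * nb] = ph_lo[2]
    zb[2 * nb + 1] = world_zmax
    zb = np.sort(zb)

    n_rec = 0
    # secondary stack
    st = np.empty((MAX_STACK, 8))

    for h in range(n):
        np.random.seed((base_seed + h * 2654435761) % 2147483647)
        n_st = 0
        st[0, 0] = x0a[h]
        st[0, 1] = y0a[h]
        st[0, 2] = z0a[h]
        st[0, 3] = dxa[h]
        st[0, 4] = dya[h]
        st[0, 5] = dza[h]
        st[0, 6] = E0a[h]
        st[0, 7] = float(tag0a[h])
        n_st = 1
        hist_initial[h] = E0a[h]
        acc = 0.0

        while n_st > 0:
            n_st -= 1
            x = st[n_st, 0]
            y = st[n_st, 1]
            z = st[n_st, 2]
            dx = st[n_st, 3]
            dy = st[n_st, 4]
            dz = st[n_st, 5]
            E = st[n_st, 6]
            tag = int(st[n_st, 7])

            alive = True
            while alive:
                if abs(x) > world_half or abs(y) > world_half or z >= world_zmax - 1e-9:
                    sinks[ACC_ESCAPED] += E
                    acc += E
                    alive = False
                    break
                # medium lookup
                in_ph = (ph_lo[0] <= x < ph_hi[0] and ph_lo[1] <= y < ph_hi[1]
                         and ph_lo[2] <= z < ph_hi[2])
                if in_ph:
                    medium = WATER
                elif _in_blade(x, y, z, blades):
                    medium = NICKEL
                else:
                    medium = VACUUM

                if medium == VACUUM:
                    if dz <= 1e-9:
                        sinks[ACC_ESCAPED] += E
                        acc += E
                        alive = False
                        break
                    # fly to the next z boundary
                    znext = world_zmax
                    for q in range(zb.shape[0]):
                        if zb[q] > z + 1e-9:
                            znext = zb[q]
                            break
                    t = (znext - z) / dz
                    zold = z
                    x += dx * t
                    y += dy * t
                    z = znext
                    if zold < plane_z <= z and n_rec < rec_E.shape[0]:
                        tc = (plane_z - zold) / dz
                        rec_E[n_rec] = E
                        rec_x[n_rec] = x - dx * (t - tc)
                        rec_y[n_rec] = y - dy * (t - tc)
                        rec_tag[n_rec] = tag
                        n_rec += 1
                    z += 1e-7  # nudge into the next region
                    continue

                # --- condensed-history step in matter ---
                if medium == WATER:
                    rho, za, x0m = rho_w, za_w, x0m_w
                    log_s = log_s_w
                    rtab = range_w
                    ds_cap = max_step_w
                else:
                    rho, za, x0m = rho_ni, za_ni, x0m_ni
                    log_s = log_s_ni
                    rtab = range_ni
                    ds_cap = max_step_ni
                if E < cutoff + 1e-12:
                    # below-cutoff: deposit locally
                    if medium == WATER:
                        if score_on:
                            _score_point(sum_e_pt, gox, goy, goz, gsx, gsy, gsz,
                                         gnx, gny, gnz, x, y, z, E)
                        sinks[ACC_PHANTOM] += E
                    else:
                        sinks[ACC_COLLIMATOR] += E
                    acc += E
                    alive = False
                    break

                # clip step at the medium's z faces / phantom box
                ds = ds_cap
                if medium == WATER:
                    for a in range(3):
                        if a == 0:
                            p, d, lo, hi = x, dx, ph_lo[0], ph_hi[0]
                        elif a == 1:
                            p, d, lo, hi = y, dy, ph_lo[1], ph_hi[1]
                        else:
                            p, d, lo, hi = z, dz, ph_lo[2], ph_hi[2]
                        if d > 0.0:
                            tc = (hi - p) / d
                        elif d < 0.0:
                            tc = (lo - p) / d
                        else:
                            continue
                        if tc < ds:
                            ds = tc
                else:
                    # nickel: clip at the slab z faces only
                    for b in range(nb):
                        if blades[b, 2] <= z <= blades[b, 3]:
                            if dz > 0.0:
                                tc = (blades[b, 3] - z) / dz
                            elif dz < 0.0:
                                tc = (blades[b, 2] - z) / dz
                            else:
                                tc = ds
                            if tc < ds:
                                ds = tc
                            break
                if ds < 1e-9:
                    ds = 1e-9

                # exact CSDA energy update via the range tables (no Euler bias)
                r_now = _interp(E, e_nodes, rtab)
                r_cut = _interp(cutoff, e_nodes, rtab)
                if r_now - r_cut <= ds:
                    # terminal step: deposit everything over the residual range
                    l_res = r_now - r_cut
                    if l_res > ds:
                        l_res = ds
                    if medium == WATER:
                        if score_on and l_res > 1e-7:
                            _score_segment(sum_e, sum_l, sum_e2l,
                                           gox, goy, goz, gsx, gsy, gsz,
                                           gnx, gny, gnz,
                                           x, y, z, x + dx * l_res,
                                           y + dy * l_res, z + dz * l_res, E, l_res)
                        elif score_on:
                            _score_point(sum_e_pt, gox, goy, goz, gsx, gsy, gsz,
                                         gnx, gny, gnz, x, y, z, E)
                        sinks[ACC_PHANTOM] += E
                    else:
                        sinks[ACC_COLLIMATOR] += E
                    acc += E
                    alive = False
                    break

                mean_loss = E - _interp(r_now - ds, rtab, e_nodes)
                eps = mean_loss
                if straggle_on:
                    eps += _bohr_sigma(E, za, rho, ds) * np.random.standard_normal()
                    if eps < 0.0:
                        eps = 0.0
                    elif eps > E:
                        eps = E
                xn = x + dx * ds
                yn = y + dy * ds
                zn = z + dz * ds
                if medium == WATER:
                    if score_on:
                        _score_segment(sum_e, sum_l, sum_e2l,
                                       gox, goy, goz, gsx, gsy, gsz,
                                       gnx, gny, gnz, x, y, z, xn, yn, zn,
                                       eps, ds)
                    sinks[ACC_PHANTOM] += eps
                else:
                    sinks[ACC_COLLIMATOR] += eps
                acc += eps
                E -= eps
                if z < plane_z <= zn and n_rec < rec_E.shape[0]:
                    rec_E[n_rec] = E
                    rec_x[n_rec] = xn
                    rec_y[n_rec] = yn
                    rec_tag[n_rec] = tag
                    n_rec += 1
                x, y, z = xn, yn, zn
                if medium == NICKEL and tag == 0:
                    tag = 1  # collimator scatter

                if scatter_on and E > cutoff:
                    th0 = _highland_theta0(E, rho * ds, x0m)
                    if th0 > 0.0:
                        # orthonormal frame around the direction
                        if abs(dz) < 0.99:
                            e1x, e1y, e1z = -dy, dx, 0.0
                        else:
                            e1x, e1y, e1z = 1.0, 0.0, 0.0
                        nrm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                        e1x /= nrm
                        e1y /= nrm
                        e1z /= nrm
                        e2x = dy * e1z - dz * e1y
                        e2y = dz * e1x - dx * e1z
                        e2z = dx * e1y - dy * e1x
                        a1 = th0 * np.random.standard_normal()
                        a2 = th0 * np.random.standard_normal()
                        dx += a1 * e1x + a2 * e2x
                        dy += a1 * e1y + a2 * e2y
                        dz += a1 * e1z + a2 * e2z
                        nrm = math.sqrt(dx * dx + dy * dy + dz * dz)
                        dx /= nrm
                        dy /= nrm
                        dz /= nrm

                if nuclear_on and medium == WATER and E > cutoff:
                    rate = nuc_rate
                    if E < 8.0:
                        rate = 0.0
                    elif E < 20.0:
                        rate = nuc_rate * (E - 8.0) / 12.0
                    if np.random.random() < rate * ds:
                        local = nuc_local_frac * E
                        if score_on:
                            _score_point(sum_e_pt, gox, goy, goz, gsx, gsy, gsz,
                                         gnx, gny, gnz, x, y, z, local)
                        sinks[ACC_PHANTOM] += local
                        acc += local
                        rest = E - local
                        if 0.5 * E > 5.0 and n_st < MAX_STACK:
                            es = 5.0 + (0.5 * E - 5.0) * np.random.random()
                            ct = 0.5 + 0.5 * np.random.random()
                            stn = math.sqrt(1.0 - ct * ct)
                            phi = 2.0 * math.pi * np.random.random()
                            st[n_st, 0] = x
                            st[n_st, 1] = y
                            st[n_st, 2] = z
                            st[n_st, 3] = stn * math.cos(phi)
                            st[n_st, 4] = stn * math.sin(phi)
                            st[n_st, 5] = ct
                            st[n_st, 6] = es
                            st[n_st, 7] = 2.0
                            n_st += 1
                            rest -= es
                        sinks[ACC_BINDING] += rest
                        acc += rest
                        alive = False
                        break
        hist_accounted[h] = acc
    return n_rec
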