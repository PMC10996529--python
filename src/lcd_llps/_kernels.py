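"""Numba kernels: neighbour lists, forces, Langevin (BAOAB) integration.

All kernels are single-threaded so that trajectories are bitwise
reproducible for a given seed.  The nonbonded work is split in two:

* MLJ (2 nm cutoff) uses a Verlet pair list built from a cell grid
  with a 0.3 nm skin, rebuilt when any bead has moved more than half
  the skin since the last build; the pair's sigma^2 and mean
  hydropathy are cached with the list so the hot loop is gather-light;
* screened electrostatics (3.5 nm cutoff) runs over the precomputed
  list of charged-bead pairs every step — only ~6% of beads carry
  charge, so this brute list is tiny.

Directly bonded (i, i+1) pairs are excluded from both nonbonded terms.
The thermostat (the O part of BAOAB) may be applied every k-th step
using the exactly integrated Ornstein–Uhlenbeck coefficients for a lag
of k steps; with the 0.01 ps time step and multi-ps damping times this
leaves the sampled ensemble unchanged while saving most of the
Gaussian draws.
"""

import numpy as np
from numba import njit

# 13 half-stencil neighbour-cell offsets (plus the self cell handled apart).
_OFFSETS = np.array([
    (1, 0, 0), (-1, 1, 0), (0, 1, 0), (1, 1, 0),
    (-1, -1, 1), (0, -1, 1), (1, -1, 1),
    (-1, 0, 1), (0, 0, 1), (1, 0, 1),
    (-1, 1, 1), (0, 1, 1), (1, 1, 1),
], dtype=np.int64)

_RMIN2_FACTOR = 1.2599210498948732   # 2^(1/3): r2 <= f*s2  <=>  r <= 2^(1/6) s


@njit(cache=True)
def _min_image(d, L):
    return d - L * np.rint(d / L)


@njit(cache=True)
def build_pairs(pos, box, chain_id, sig, lam, rlist, pi, pj, ps2, pl):
    """Fill the Verlet list (pairs within *rlist*); returns the count.

    Alongside the indices, caches s_ij^2 (squared arithmetic-mean
    diameter) and lambda_ij (arithmetic-mean hydropathy) per pair.
    Uses a cell grid when every box edge fits >= 3 cells of edge >=
    rlist, otherwise an O(N^2) sweep.  Bonded pairs are skipped.
    Returns -1 if capacity is exceeded.
    """
    n = pos.shape[0]
    cap = pi.shape[0]
    r2max = rlist * rlist
    bx = box[0]
    by = box[1]
    bz = box[2]
    ibx = 1.0 / bx
    iby = 1.0 / by
    ibz = 1.0 / bz
    ncx = int(bx / rlist)
    ncy = int(by / rlist)
    ncz = int(bz / rlist)
    count = 0
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n - 1):
            for j in range(i + 1, n):
                if chain_id[i] == chain_id[j] and j - i == 1:
                    continue
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                dx -= bx * np.rint(dx * ibx)
                dy -= by * np.rint(dy * iby)
                dz -= bz * np.rint(dz * ibz)
                if dx * dx + dy * dy + dz * dz <= r2max:
                    if count >= cap:
                        return -1
                    pi[count] = i
                    pj[count] = j
                    s = 0.5 * (sig[i] + sig[j])
                    ps2[count] = s * s
                    pl[count] = 0.5 * (lam[i] + lam[j])
                    count += 1
        return count

    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        wx = pos[i, 0] - bx * np.floor(pos[i, 0] * ibx)
        wy = pos[i, 1] - by * np.floor(pos[i, 1] * iby)
        wz = pos[i, 2] - bz * np.floor(pos[i, 2] * ibz)
        cx = min(max(int(wx * ibx * ncx), 0), ncx - 1)
        cy = min(max(int(wy * iby * ncy), 0), ncy - 1)
        cz = min(max(int(wz * ibz * ncz), 0), ncz - 1)
        c = (cz * ncy + cy) * ncx + cx
        nxt[i] = head[c]
        head[c] = i

    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                for k in range(14):
                    if k == 13:           # pairs within the cell itself
                        c2 = c
                    else:
                        ox = (cx + _OFFSETS[k, 0]) % ncx
                        oy = (cy + _OFFSETS[k, 1]) % ncy
                        oz = (cz + _OFFSETS[k, 2]) % ncz
                        c2 = (oz * ncy + oy) * ncx + ox
                    i = head[c]
                    while i >= 0:
                        j = head[c2] if k < 13 else nxt[i]
                        while j >= 0:
                            if not (chain_id[i] == chain_id[j] and abs(j - i) == 1):
                                dx = pos[j, 0] - pos[i, 0]
                                dy = pos[j, 1] - pos[i, 1]
                                dz = pos[j, 2] - pos[i, 2]
                                dx -= bx * np.rint(dx * ibx)
                                dy -= by * np.rint(dy * iby)
                                dz -= bz * np.rint(dz * ibz)
                                if dx * dx + dy * dy + dz * dz <= r2max:
                                    if count >= cap:
                                        return -1
                                    pi[count] = i
                                    pj[count] = j
                                    s = 0.5 * (sig[i] + sig[j])
                                    ps2[count] = s * s
                                    pl[count] = 0.5 * (lam[i] + lam[j])
                                    count += 1
                            j = nxt[j]
                        i = nxt[i]
    return count


@njit(cache=True)
def compute_forces_kernel(pos, box, forces,
                          bond_i, bond_j, bond_k, r0,
                          pi, pj, ps2, pl, npairs, lam_scale, eps, rc_m,
                          ci, cj, qq, kpref, kappa, rc_e,
                          sdx, sdy, sdz, sfr):
    """Total forces (bond + MLJ + Yukawa); returns the potential energy.

    sdx/sdy/sdz/sfr are caller-provided scratch arrays (pair-list
    capacity); the MLJ sum runs in three passes — gather separations,
    branchless arithmetic, scatter — so the middle pass vectorises.
    """
    forces[:] = 0.0
    pe = 0.0
    bx = box[0]
    by = box[1]
    bz = box[2]
    ibx = 1.0 / bx
    iby = 1.0 / by
    ibz = 1.0 / bz
    # bonds
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * bond_k * (r - r0) ** 2
        # clamp guards the pathological r=0 of a blown-up run (no exception;
        # the resulting inf is caught by the integrator's finite check)
        fmag = -bond_k * (r - r0) / max(r, 1e-12)
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
    # MLJ from the Verlet list, in three passes over the pair list.
    rc2 = rc_m * rc_m
    # pass 1: gather minimum-image separations (scalar; indexed loads)
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        sdx[p] = dx
        sdy[p] = dy
        sdz[p] = dz
        sfr[p] = dx * dx + dy * dy + dz * dz
    # pass 2: branchless force/energy arithmetic (select-only; vectorises)
    for p in range(npairs):
        r2 = sfr[p]
        s2 = ps2[p]
        l = pl[p] * lam_scale
        inside = 1.0 if r2 <= rc2 else 0.0
        inv_r2 = 1.0 / max(r2, 1e-24)
        sr2 = s2 * inv_r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        lj_e = 4.0 * eps * (sr12 - sr6)
        lj_f_over_r = 24.0 * eps * (2.0 * sr12 - sr6) * inv_r2   # (-dE/dr)/r
        core = r2 <= _RMIN2_FACTOR * s2                          # r <= 2^(1/6) s
        e = (lj_e + eps * (1.0 - l)) if core else l * lj_e
        fr = lj_f_over_r if core else l * lj_f_over_r
        pe += e * inside
        sfr[p] = fr * inside
    # pass 3: scatter, accumulating the i side in registers (the list
    # carries runs of equal i, so this breaks the forces[i] store chain)
    cur_i = -1
    fix = 0.0
    fiy = 0.0
    fiz = 0.0
    for p in range(npairs):
        fr = sfr[p]
        i = pi[p]
        if i != cur_i:
            if cur_i >= 0:
                forces[cur_i, 0] += fix
                forces[cur_i, 1] += fiy
                forces[cur_i, 2] += fiz
            cur_i = i
            fix = 0.0
            fiy = 0.0
            fiz = 0.0
        if fr == 0.0:
            continue
        j = pj[p]
        fx = fr * sdx[p]
        fy = fr * sdy[p]
        fz = fr * sdz[p]
        fix -= fx
        fiy -= fy
        fiz -= fz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
    if cur_i >= 0:
        forces[cur_i, 0] += fix
        forces[cur_i, 1] += fiy
        forces[cur_i, 2] += fiz
    # screened electrostatics over charged pairs
    re2 = rc_e * rc_e
    for p in range(ci.shape[0]):
        i = ci[p]
        j = cj[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > re2:
            continue
        r = np.sqrt(r2)
        inv_r = 1.0 / max(r, 1e-12)
        pref = kpref * qq[p]
        screen = np.exp(-kappa * r)
        pe += pref * screen * inv_r
        fr = pref * screen * (inv_r * inv_r + kappa * inv_r) * inv_r
        forces[i, 0] -= fr * dx
        forces[i, 1] -= fr * dy
        forces[i, 2] -= fr * dz
        forces[j, 0] += fr * dx
        forces[j, 1] += fr * dy
        forces[j, 2] += fr * dz
    return pe


@njit(cache=True)
def run_langevin(pos, vel, box, mass, sig, lam, chain_id,
                 bond_i, bond_j, ci, cj, qq,
                 dt, n_steps, damping_time, thermostat_interval, kT,
                 kpref, kappa, eps, lam_scale, rc_e, rc_m, bond_k, r0,
                 rlist, skin, seed, frame_stride, frames_out):
    """BAOAB Langevin integration; fills frames_out every frame_stride steps.

    damping_time <= 0 disables the thermostat (NVE velocity Verlet).
    The O step is applied on every thermostat_interval-th step with the
    OU coefficients integrated over that lag.  Returns the number of
    frames recorded, or -(step+1) if a coordinate became non-finite.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    cap = max(n * 220, 40000)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    ps2 = np.empty(cap)
    pl = np.empty(cap)
    sdx = np.empty(cap)
    sdy = np.empty(cap)
    sdz = np.empty(cap)
    sfr = np.empty(cap)
    kth = max(thermostat_interval, 1)
    if damping_time > 0.0:
        a = np.exp(-kth * dt / damping_time)
        noise_amp = np.sqrt(kT / mass * (1.0 - a * a))
    else:
        a = 1.0
        noise_amp = np.zeros(n)
    inv_mass = 1.0 / mass
    forces = np.empty((n, 3))
    ref = pos.copy()
    npairs = build_pairs(pos, box, chain_id, sig, lam, rlist, pi, pj, ps2, pl)
    while npairs < 0:
        cap *= 2
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        ps2 = np.empty(cap)
        pl = np.empty(cap)
        npairs = build_pairs(pos, box, chain_id, sig, lam, rlist, pi, pj, ps2, pl)
        sdx = np.empty(cap)
        sdy = np.empty(cap)
        sdz = np.empty(cap)
        sfr = np.empty(cap)
    compute_forces_kernel(pos, box, forces, bond_i, bond_j, bond_k, r0,
                          pi, pj, ps2, pl, npairs, lam_scale, eps, rc_m,
                          ci, cj, qq, kpref, kappa, rc_e, sdx, sdy, sdz, sfr)
    half_skin2 = (0.5 * skin) ** 2
    kframe = 0
    for step in range(n_steps):
        for i in range(n):
            c = 0.5 * dt * inv_mass[i]
            for d in range(3):
                vel[i, d] += c * forces[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        if damping_time > 0.0 and step % kth == 0:
            for i in range(n):
                amp = noise_amp[i]
                for d in range(3):
                    vel[i, d] = a * vel[i, d] + amp * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        # neighbour-list validity check (sumd2 also traps NaN/inf blow-up,
        # which would otherwise poison the cell binning)
        maxd2 = 0.0
        sumd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            sumd2 += d2
            if d2 > maxd2:
                maxd2 = d2
        if not np.isfinite(sumd2):
            return -(step + 1)
        if maxd2 > half_skin2:
            npairs = build_pairs(pos, box, chain_id, sig, lam, rlist,
                                 pi, pj, ps2, pl)
            while npairs < 0:
                cap *= 2
                pi = np.empty(cap, dtype=np.int64)
                pj = np.empty(cap, dtype=np.int64)
                ps2 = np.empty(cap)
                pl = np.empty(cap)
                sdx = np.empty(cap)
                sdy = np.empty(cap)
                sdz = np.empty(cap)
                sfr = np.empty(cap)
                npairs = build_pairs(pos, box, chain_id, sig, lam, rlist,
                                     pi, pj, ps2, pl)
            ref[:] = pos
        compute_forces_kernel(pos, box, forces, bond_i, bond_j, bond_k, r0,
                              pi, pj, ps2, pl, npairs, lam_scale, eps, rc_m,
                              ci, cj, qq, kpref, kappa, rc_e,
                              sdx, sdy, sdz, sfr)
        for i in range(n):
            c = 0.5 * dt * inv_mass[i]
            for d in range(3):
                vel[i, d] += c * forces[i, d]
        if not np.isfinite(pos[0, 0]):
            return -(step + 1)
        if frame_stride > 0 and (step + 1) % frame_stride == 0:
            if kframe < frames_out.shape[0]:
                frames_out[kframe] = pos
                kframe += 1
    # final sanity check over all coordinates
    for i in range(n):
        for d in range(3):
            if not np.isfinite(pos[i, d]):
                return -n_steps
    return kframe


@njit(cache=True)
def accumulate_pair_forces(pos, box, chain_id, resid, sig, lam, charge,
                           kpref, kappa, eps, lam_scale, rc_e, rc_m,
                           elec_map, hydro_map):
    """One frame of intermolecular pairwise signed radial forces.

    Accumulates each intermolecular bead pair's electrostatic and
    hydrophobic (lambda-weighted LJ) radial force into the L x L
    sequence-position maps (symmetrically) and returns the frame totals
    (each unordered pair counted once).  Positive = repulsive.
    """
    n = pos.shape[0]
    re2 = rc_e * rc_e
    rm2 = rc_m * rc_m
    rmax2 = max(re2, rm2)
    tot_e = 0.0
    tot_h = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j]:
                continue
            dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
            dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
            dz = _min_image(pos[j, 2] - pos[i, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rmax2:
                continue
            r = np.sqrt(r2)
            a = resid[i]
            b = resid[j]
            qq = charge[i] * charge[j]
            if qq != 0.0 and r2 <= re2:
                fe = kpref * qq * np.exp(-kappa * r) * (1.0 / r2 + kappa / r)
                tot_e += fe
                elec_map[a, b] += fe
                if a != b:          # diagonal cells accumulate once per pair
                    elec_map[b, a] += fe
            if r2 <= rm2:
                s = 0.5 * (sig[i] + sig[j])
                l = 0.5 * (lam[i] + lam[j]) * lam_scale
                sr6 = (s * s / r2) ** 3
                fh = l * 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
                tot_h += fh
                hydro_map[a, b] += fh
                if a != b:
                    hydro_map[b, a] += fh
    return tot_e, tot_h
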