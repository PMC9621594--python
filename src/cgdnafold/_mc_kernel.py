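"""Compiled Monte Carlo inner loop (numba).

The kernel mirrors the reference energy functions in ``forcefield`` and is
checked against them (full recompute vs incremental tally) in the test
suite.  Beads are stored flat, three per residue in P, C, N order, so bead
``b`` belongs to residue ``b // 3`` and has kind ``b % 3``.

Moves: pivot (rotate one contiguous chain segment about a random axis
through a backbone bead) and, for two-chain systems, rigid whole-chain
translations constrained by the reflecting box walls.  Pairing, stacking
and coaxial terms are recomputed globally each move (they are small);
excluded-volume and electrostatic sums are updated incrementally over the
moved/static boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed scalar parameter array
P_KBOND, P_KANG, P_KDIH, P_NHFAC = 0, 1, 2, 3
P_EPSEXC, P_EXCCAP = 4, 5
P_EPSBP, P_R0NN, P_D0X, P_ALPHAR, P_ALPHAD, P_WINDOW, P_DETECT = 6, 7, 8, 9, 10, 11, 12
P_SIGST, P_STCUT = 13, 14
P_ELPREF, P_LDEBYE = 15, 16
P_BOX, P_KT, P_PTRANS, P_COAXCUT = 17, 18, 19, 20
N_PRM = 21


@njit(cache=True)
def _dist(pos, i, j):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _bracket(r, sigma, cutoff):
    if r >= cutoff:
        return 0.0
    rr = r
    if rr < 0.05 * sigma:
        rr = 0.05 * sigma
    x = sigma / rr
    x10 = x**10
    v = 5.0 * x10 * x * x - 6.0 * x10
    if v > 1e3:
        v = 1e3
    return v


@njit(cache=True)
def _angle(pos, i, j, k):
    ux = pos[i, 0] - pos[j, 0]; uy = pos[i, 1] - pos[j, 1]; uz = pos[i, 2] - pos[j, 2]
    vx = pos[k, 0] - pos[j, 0]; vy = pos[k, 1] - pos[j, 1]; vz = pos[k, 2] - pos[j, 2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c)


@njit(cache=True)
def _dihedral(pos, i, j, k, l):
    b1x = pos[j, 0] - pos[i, 0]; b1y = pos[j, 1] - pos[i, 1]; b1z = pos[j, 2] - pos[i, 2]
    b2x = pos[k, 0] - pos[j, 0]; b2y = pos[k, 1] - pos[j, 1]; b2z = pos[k, 2] - pos[j, 2]
    b3x = pos[l, 0] - pos[k, 0]; b3y = pos[l, 1] - pos[k, 1]; b3z = pos[l, 2] - pos[k, 2]
    n1x = b1y * b2z - b1z * b2y; n1y = b1z * b2x - b1x * b2z; n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y; n2y = b2z * b3x - b2x * b3z; n2z = b2x * b3y - b2y * b3x
    nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    m1x = (n1y * b2z - n1z * b2y) / nb2
    m1y = (n1z * b2x - n1x * b2z) / nb2
    m1z = (n1x * b2y - n1y * b2x) / nb2
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    return np.arctan2(y, x)


@njit(cache=True)
def _term_factor(helical, lo, hi, nhfac):
    if helical[lo] != 0 and helical[hi] != 0:
        return 1.0
    return nhfac


@njit(cache=True)
def _bonded_chain(pos, bonds, angles, dihedrals, bond_res, angle_res, dih_res,
                  bond_r0, angle_t0, dih_p0, helical, prm,
                  b_lo, b_hi, a_lo, a_hi, d_lo, d_hi):
    """(U_b, U_a, U_d) for one chain's term slices."""
    ub = 0.0
    for t in range(b_lo, b_hi):
        i = bonds[t, 0]; j = bonds[t, 1]; ty = bonds[t, 2]
        f = _term_factor(helical, bond_res[t, 0], bond_res[t, 1], prm[P_NHFAC])
        d = _dist(pos, i, j) - bond_r0[ty]
        ub += prm[P_KBOND] * f * d * d
    ua = 0.0
    for t in range(a_lo, a_hi):
        th = _angle(pos, angles[t, 0], angles[t, 1], angles[t, 2])
        f = _term_factor(helical, angle_res[t, 0], angle_res[t, 1], prm[P_NHFAC])
        d = th - angle_t0[angles[t, 3]]
        ua += prm[P_KANG] * f * d * d
    ud = 0.0
    for t in range(d_lo, d_hi):
        ph = _dihedral(pos, dihedrals[t, 0], dihedrals[t, 1],
                       dihedrals[t, 2], dihedrals[t, 3])
        f = _term_factor(helical, dih_res[t, 0], dih_res[t, 1], prm[P_NHFAC])
        ud += prm[P_KDIH] * f * (1.0 - np.cos(ph - dih_p0[dihedrals[t, 4]]))
    return ub, ua, ud


@njit(cache=True, inline="always")
def _in_seg(b, lo, hi):
    return lo <= b < hi


@njit(cache=True)
def _bonded_cross(pos, bonds, angles, dihedrals, bond_res, angle_res, dih_res,
                  bond_r0, angle_t0, dih_p0, helical, prm,
                  b_lo, b_hi, a_lo, a_hi, d_lo, d_hi, lo, hi):
    """(U_b, U_a, U_d) over terms crossing the moved-segment boundary.

    A pivot move preserves geometry strictly inside or outside the moved
    range, so only terms with beads on both sides change.
    """
    ub = 0.0
    for t in range(b_lo, b_hi):
        i = bonds[t, 0]; j = bonds[t, 1]
        mi = _in_seg(i, lo, hi); mj = _in_seg(j, lo, hi)
        if mi == mj:
            continue
        f = _term_factor(helical, bond_res[t, 0], bond_res[t, 1], prm[P_NHFAC])
        d = _dist(pos, i, j) - bond_r0[bonds[t, 2]]
        ub += prm[P_KBOND] * f * d * d
    ua = 0.0
    for t in range(a_lo, a_hi):
        i = angles[t, 0]; j = angles[t, 1]; k = angles[t, 2]
        mi = _in_seg(i, lo, hi); mj = _in_seg(j, lo, hi); mk = _in_seg(k, lo, hi)
        if mi == mj and mj == mk:
            continue
        f = _term_factor(helical, angle_res[t, 0], angle_res[t, 1], prm[P_NHFAC])
        d = _angle(pos, i, j, k) - angle_t0[angles[t, 3]]
        ua += prm[P_KANG] * f * d * d
    ud = 0.0
    for t in range(d_lo, d_hi):
        i = dihedrals[t, 0]; j = dihedrals[t, 1]
        k = dihedrals[t, 2]; l = dihedrals[t, 3]
        mi = _in_seg(i, lo, hi); mj = _in_seg(j, lo, hi)
        mk = _in_seg(k, lo, hi); ml = _in_seg(l, lo, hi)
        if mi == mj and mj == mk and mk == ml:
            continue
        f = _term_factor(helical, dih_res[t, 0], dih_res[t, 1], prm[P_NHFAC])
        ph = _dihedral(pos, i, j, k, l)
        ud += prm[P_KDIH] * f * (1.0 - np.cos(ph - dih_p0[dihedrals[t, 4]]))
    return ub, ua, ud


@njit(cache=True)
def _exc_pair(r2, sig2, eps, cap):
    dd2 = r2
    if dd2 < 1e-12:
        dd2 = 1e-12
    x2 = sig2 / dd2
    x6 = x2 * x2 * x2
    e = eps * (x6 * x6 - 2.0 * x6 + 1.0)
    if e > cap:
        e = cap
    return e


@njit(cache=True)
def _el_pair(r2, prm):
    dd = np.sqrt(r2)
    if dd < 1e-6:
        dd = 1e-6
    e = prm[P_ELPREF] * np.exp(-dd / prm[P_LDEBYE]) / dd
    if e > prm[P_EXCCAP]:
        e = prm[P_EXCCAP]
    return e


@njit(cache=True)
def _pair_cross_energy(pos, strand_of_bead, res_of_bead, radsum2, prm,
                       lo, hi, n_beads):
    """Excluded-volume + electrostatic energy across the [lo,hi) boundary.

    Electrostatics (P beads only, every third bead) are truncated beyond
    10 Debye lengths.
    """
    e_exc = 0.0
    eps = prm[P_EPSEXC]
    cap = prm[P_EXCCAP]
    for m in range(lo, hi):
        rm = res_of_bead[m]
        sm = strand_of_bead[m]
        km = m - 3 * rm
        xm = pos[m, 0]; ym = pos[m, 1]; zm = pos[m, 2]
        for s in range(n_beads):
            if lo <= s < hi:
                continue
            dx = xm - pos[s, 0]
            dy = ym - pos[s, 1]
            dz = zm - pos[s, 2]
            r2 = dx * dx + dy * dy + dz * dz
            rs = res_of_bead[s]
            sig2 = radsum2[km, s - 3 * rs]
            if r2 >= sig2:
                continue
            if strand_of_bead[s] == sm and abs(rs - rm) <= 1:
                continue
            e_exc += _exc_pair(r2, sig2, eps, cap)
    e_el = 0.0
    cut = 10.0 * prm[P_LDEBYE]
    cut2 = cut * cut
    m0 = lo + ((3 - lo % 3) % 3)
    for m in range(m0, hi, 3):
        xm = pos[m, 0]; ym = pos[m, 1]; zm = pos[m, 2]
        for s in range(0, n_beads, 3):
            if lo <= s < hi:
                continue
            dx = xm - pos[s, 0]
            dy = ym - pos[s, 1]
            dz = zm - pos[s, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2:
                e_el += _el_pair(r2, prm)
    return e_exc, e_el


@njit(cache=True)
def _full_exc_el(pos, strand_of_bead, res_of_bead, radsum2, prm, n_beads):
    e_exc = 0.0
    eps = prm[P_EPSEXC]
    cap = prm[P_EXCCAP]
    for i in range(n_beads):
        ri = res_of_bead[i]
        si = strand_of_bead[i]
        ki = i - 3 * ri
        for j in range(i + 1, n_beads):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            rj = res_of_bead[j]
            sig2 = radsum2[ki, j - 3 * rj]
            if r2 >= sig2:
                continue
            if strand_of_bead[j] == si and abs(rj - ri) <= 1:
                continue
            e_exc += _exc_pair(r2, sig2, eps, cap)
    e_el = 0.0
    cut = 10.0 * prm[P_LDEBYE]
    cut2 = cut * cut
    for i in range(0, n_beads, 3):
        for j in range(i + 3, n_beads, 3):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2:
                e_el += _el_pair(r2, prm)
    return e_exc, e_el


@njit(cache=True)
def _pairstack(pos, base, strand_of_res, combos, gabs, prm, n_res,
               partner_out, cand_e):
    """Pairing + stacking + coaxial energies; fills partner_out (detected
    pairs only) and returns (u_bp, u_bs, u_cs, n_pairs)."""
    k = combos.shape[0]
    r0 = prm[P_R0NN]
    w = prm[P_WINDOW]
    lo2 = (r0 - w) * (r0 - w)
    hi2 = (r0 + w) * (r0 + w)
    n_neg = 0
    for c in range(k):
        i = combos[c, 0]
        j = combos[c, 1]
        ii = 3 * i + 2
        jj = 3 * j + 2
        dx = pos[ii, 0] - pos[jj, 0]
        dy = pos[ii, 1] - pos[jj, 1]
        dz = pos[ii, 2] - pos[jj, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < lo2 or r2 > hi2:
            cand_e[c] = 0.0
            continue
        r = np.sqrt(r2)
        d1 = _dist(pos, 3 * i + 1, 3 * j + 2) - prm[P_D0X]
        d2 = _dist(pos, 3 * i + 2, 3 * j + 1) - prm[P_D0X]
        dr = r - r0
        cand_e[c] = -prm[P_EPSBP] * np.exp(
            -prm[P_ALPHAR] * dr * dr - prm[P_ALPHAD] * (d1 * d1 + d2 * d2))
        n_neg += 1

    for r in range(n_res):
        partner_out[r] = -1
    u_bp = 0.0
    if n_neg > 0:
        # insertion sort of the (few) negative candidates by energy;
        # index order breaks exact ties lexicographically
        order = np.empty(n_neg, dtype=np.int64)
        m = 0
        for c in range(k):
            if cand_e[c] < 0.0:
                e = cand_e[c]
                p = m
                while p > 0 and cand_e[order[p - 1]] > e:
                    order[p] = order[p - 1]
                    p -= 1
                order[p] = c
                m += 1
        for oi in range(n_neg):
            c = order[oi]
            i = combos[c, 0]
            j = combos[c, 1]
            if partner_out[i] >= 0 or partner_out[j] >= 0:
                continue
            partner_out[i] = j
            partner_out[j] = i
            u_bp += cand_e[c]

    # stacking over neighbouring pairs
    u_bs = 0.0
    sig = prm[P_SIGST]
    cut = prm[P_STCUT]
    for r in range(n_res - 1):
        if strand_of_res[r] != strand_of_res[r + 1]:
            continue
        p = partner_out[r]
        q = partner_out[r + 1]
        if p < 0 or q < 0 or q != p - 1:
            continue
        if r >= q:
            continue
        g = gabs[base[r], base[r + 1]]
        b1 = _bracket(_dist(pos, 3 * r + 2, 3 * (r + 1) + 2), sig, cut)
        b2 = _bracket(_dist(pos, 3 * p + 2, 3 * q + 2), sig, cut)
        u_bs += 0.5 * g * (b1 + b2)

    # helices (runs of stacked pairs seen from the lower-index side)
    u_cs = 0.0
    n_hel = 0
    hel_start = np.empty(n_res, dtype=np.int64)
    hel_end = np.empty(n_res, dtype=np.int64)
    r = 0
    while r < n_res:
        p = partner_out[r]
        if p <= r:
            r += 1
            continue
        start = r
        while (r + 1 < n_res and strand_of_res[r + 1] == strand_of_res[r]
               and partner_out[r + 1] == partner_out[r] - 1
               and partner_out[r] - 1 > r + 1):
            r += 1
        hel_start[n_hel] = start
        hel_end[n_hel] = r
        n_hel += 1
        r += 1
    if n_hel >= 2:
        coax_cut = prm[P_COAXCUT]
        max_c = 4 * n_hel * n_hel
        cand_val = np.zeros(max_c)
        cand_ia = np.empty(max_c, dtype=np.int64)
        cand_ib = np.empty(max_c, dtype=np.int64)
        n_cand = 0
        for a in range(n_hel):
            for b in range(a + 1, n_hel):
                for ia in range(2):
                    ea = hel_start[a] if ia == 0 else hel_end[a]
                    if ia == 1 and ea == hel_start[a]:
                        continue          # singleton helix: one end only
                    for ib in range(2):
                        eb = hel_start[b] if ib == 0 else hel_end[b]
                        if ib == 1 and eb == hel_start[b]:
                            continue
                        i = ea; j = partner_out[ea]
                        k = eb; l = partner_out[eb]
                        best = 0.0
                        for reg in range(2):
                            if reg == 0:
                                c2 = k; c4 = l
                            else:
                                c2 = l; c4 = k
                            adj1 = (strand_of_res[i] == strand_of_res[c2]
                                    and abs(i - c2) == 1)
                            adj2 = (strand_of_res[j] == strand_of_res[c4]
                                    and abs(j - c4) == 1)
                            if adj1 and adj2:
                                continue
                            r1 = _dist(pos, 3 * i + 2, 3 * c2 + 2)
                            r2 = _dist(pos, 3 * j + 2, 3 * c4 + 2)
                            if r1 < coax_cut and r2 < coax_cut:
                                g = gabs[base[i], base[c2]]
                                e = 0.5 * g * (
                                    _bracket(r1, sig, cut) + _bracket(r2, sig, cut))
                                if e < best:
                                    best = e
                        if best < 0.0:
                            cand_val[n_cand] = best
                            cand_ia[n_cand] = 2 * a + ia
                            cand_ib[n_cand] = 2 * b + ib
                            n_cand += 1
        # greedy: best interfaces first, one per helix end
        used = np.zeros(2 * n_hel, dtype=np.uint8)
        for _it in range(n_cand):
            bi = -1
            bv = 0.0
            for c in range(n_cand):
                if cand_val[c] < bv and used[cand_ia[c]] == 0 and used[cand_ib[c]] == 0:
                    bv = cand_val[c]
                    bi = c
            if bi < 0:
                break
            used[cand_ia[bi]] = 1
            used[cand_ib[bi]] = 1
            u_cs += cand_val[bi]

    # detected pairs (below threshold) define the reported pair list
    n_pairs = 0
    for r in range(n_res):
        p = partner_out[r]
        if p > r:
            # recover the candidate energy of this matched pair
            keep = False
            for c in range(k):
                if combos[c, 0] == r and combos[c, 1] == p:
                    if cand_e[c] < prm[P_DETECT]:
                        keep = True
                    break
            if keep:
                n_pairs += 1
            else:
                partner_out[r] = -1
                partner_out[p] = -1
    return u_bp, u_bs, u_cs, n_pairs


@njit(cache=True)
def full_energy(pos, base, strand_of_res, strand_of_bead, res_of_bead,
                combos, gabs, radsum2, prm,
                bonds, angles, dihedrals, bond_res, angle_res, dih_res,
                bond_r0, angle_t0, dih_p0, helical, chain_slices):
    """All eight components from scratch; returns (U[8], partner, n_pairs)."""
    n_beads = pos.shape[0]
    n_res = base.shape[0]
    u = np.zeros(8)
    for c in range(chain_slices.shape[0]):
        ub, ua, ud = _bonded_chain(
            pos, bonds, angles, dihedrals, bond_res, angle_res, dih_res,
            bond_r0, angle_t0, dih_p0, helical, prm,
            chain_slices[c, 0], chain_slices[c, 1], chain_slices[c, 2],
            chain_slices[c, 3], chain_slices[c, 4], chain_slices[c, 5])
        u[0] += ub; u[1] += ua; u[2] += ud
    e_exc, e_el = _full_exc_el(pos, strand_of_bead, res_of_bead, radsum2,
                               prm, n_beads)
    u[3] = e_exc
    u[7] = e_el
    partner = np.empty(n_res, dtype=np.int16)
    cand_e = np.empty(combos.shape[0])
    u_bp, u_bs, u_cs, n_pairs = _pairstack(
        pos, base, strand_of_res, combos, gabs, prm, n_res, partner, cand_e)
    u[4] = u_bp; u[5] = u_bs; u[6] = u_cs
    return u, partner, n_pairs


@njit(cache=True)
def _rotate_segment(pos, lo, hi, pivot, axis, angle):
    c = np.cos(angle)
    s = np.sin(angle)
    ux, uy, uz = axis[0], axis[1], axis[2]
    for b in range(lo, hi):
        x = pos[b, 0] - pivot[0]
        y = pos[b, 1] - pivot[1]
        z = pos[b, 2] - pivot[2]
        dot = ux * x + uy * y + uz * z
        pos[b, 0] = pivot[0] + x * c + (uy * z - uz * y) * s + ux * dot * (1 - c)
        pos[b, 1] = pivot[1] + y * c + (uz * x - ux * z) * s + uy * dot * (1 - c)
        pos[b, 2] = pivot[2] + z * c + (ux * y - uy * x) * s + uz * dot * (1 - c)


@njit(cache=True)
def run_block(pos, base, strand_of_res, strand_of_bead, res_of_bead,
              strand_first_res, strand_n_res,
              combos, gabs, radsum2, prm,
              bonds, angles, dihedrals, bond_res, angle_res, dih_res,
              bond_r0, angle_t0, dih_p0, helical, chain_slices,
              sweeps, adapt_sweeps, thin, seed, amps,
              frame_e, frame_np, frame_partner,
              coords_out, coords_thin, record_coords):
    """Run ``sweeps`` MC sweeps at fixed conditions, recording every
    ``thin`` sweeps.  Returns (n_accept, n_attempt, U_final)."""
    np.random.seed(seed)
    n_beads = pos.shape[0]
    n_res = base.shape[0]
    n_chains = strand_first_res.shape[0]

    u, cur_partner, cur_npairs = full_energy(
        pos, base, strand_of_res, strand_of_bead, res_of_bead,
        combos, gabs, radsum2, prm,
        bonds, angles, dihedrals, bond_res, angle_res, dih_res,
        bond_r0, angle_t0, dih_p0, helical, chain_slices)
    tmp_partner = np.empty(n_res, dtype=np.int16)
    cand_e = np.empty(combos.shape[0])
    backup = np.empty((n_beads, 3))
    axis = np.empty(3)
    kt = prm[P_KT]
    box = prm[P_BOX]

    n_acc = 0
    n_att = 0
    win_acc = 0
    win_att = 0
    frame_idx = 0
    coord_idx = 0

    for sweep in range(sweeps):
        for _ in range(n_beads):
            do_trans = n_chains == 2 and np.random.random() < prm[P_PTRANS]
            chain = np.random.randint(0, n_chains)
            r_first = strand_first_res[chain]
            r_count = strand_n_res[chain]
            c_lo = 3 * r_first
            c_hi = 3 * (r_first + r_count)

            if do_trans:
                lo, hi = c_lo, c_hi
                dxv = amps[1] * (2.0 * np.random.random() - 1.0)
                dyv = amps[1] * (2.0 * np.random.random() - 1.0)
                dzv = amps[1] * (2.0 * np.random.random() - 1.0)
            else:
                res = r_first + np.random.randint(0, r_count)
                kind = np.random.randint(0, 2)     # P or C backbone bead
                piv = 3 * res + kind
                if np.random.random() < 0.5:
                    lo, hi = c_lo, piv              # head
                else:
                    lo, hi = piv + 1, c_hi          # tail
                if lo >= hi:
                    continue
                nrm = 0.0
                while nrm < 1e-12:
                    axis[0] = np.random.normal()
                    axis[1] = np.random.normal()
                    axis[2] = np.random.normal()
                    nrm = np.sqrt(axis[0]**2 + axis[1]**2 + axis[2]**2)
                axis[0] /= nrm; axis[1] /= nrm; axis[2] /= nrm
                angle = amps[0] * (2.0 * np.random.random() - 1.0)

            n_att += 1
            win_att += 1

            old_exc, old_el = _pair_cross_energy(
                pos, strand_of_bead, res_of_bead, radsum2, prm, lo, hi, n_beads)
            if do_trans:
                old_b = 0.0; old_a = 0.0; old_d = 0.0
            else:
                old_b, old_a, old_d = _bonded_cross(
                    pos, bonds, angles, dihedrals, bond_res, angle_res, dih_res,
                    bond_r0, angle_t0, dih_p0, helical, prm,
                    chain_slices[chain, 0], chain_slices[chain, 1],
                    chain_slices[chain, 2], chain_slices[chain, 3],
                    chain_slices[chain, 4], chain_slices[chain, 5], lo, hi)

            for b in range(lo, hi):
                backup[b, 0] = pos[b, 0]
                backup[b, 1] = pos[b, 1]
                backup[b, 2] = pos[b, 2]

            if do_trans:
                for b in range(lo, hi):
                    pos[b, 0] += dxv
                    pos[b, 1] += dyv
                    pos[b, 2] += dzv
            else:
                pivot = pos[piv]
                _rotate_segment(pos, lo, hi, pivot, axis, angle)

            # reflecting walls: reject anything leaving the box
            out = False
            if box > 0.0:
                for b in range(lo, hi):
                    if (pos[b, 0] < 0.0 or pos[b, 0] > box
                            or pos[b, 1] < 0.0 or pos[b, 1] > box
                            or pos[b, 2] < 0.0 or pos[b, 2] > box):
                        out = True
                        break
            if out:
                for b in range(lo, hi):
                    pos[b, 0] = backup[b, 0]
                    pos[b, 1] = backup[b, 1]
                    pos[b, 2] = backup[b, 2]
                continue

            new_exc, new_el = _pair_cross_energy(
                pos, strand_of_bead, res_of_bead, radsum2, prm, lo, hi, n_beads)
            if do_trans:
                new_b = 0.0; new_a = 0.0; new_d = 0.0
            else:
                new_b, new_a, new_d = _bonded_cross(
                    pos, bonds, angles, dihedrals, bond_res, angle_res, dih_res,
                    bond_r0, angle_t0, dih_p0, helical, prm,
                    chain_slices[chain, 0], chain_slices[chain, 1],
                    chain_slices[chain, 2], chain_slices[chain, 3],
                    chain_slices[chain, 4], chain_slices[chain, 5], lo, hi)
            u_bp, u_bs, u_cs, n_pairs = _pairstack(
                pos, base, strand_of_res, combos, gabs, prm, n_res,
                tmp_partner, cand_e)

            du = ((new_b - old_b) + (new_a - old_a) + (new_d - old_d)
                  + (new_exc - old_exc) + (new_el - old_el)
                  + (u_bp - u[4]) + (u_bs - u[5]) + (u_cs - u[6]))

            acc = False
            if du <= 0.0:
                acc = True
            elif np.random.random() < np.exp(-du / kt):
                acc = True
            if acc:
                u[0] += new_b - old_b
                u[1] += new_a - old_a
                u[2] += new_d - old_d
                u[3] += new_exc - old_exc
                u[7] += new_el - old_el
                u[4] = u_bp
                u[5] = u_bs
                u[6] = u_cs
                for r in range(n_res):
                    cur_partner[r] = tmp_partner[r]
                cur_npairs = n_pairs
                n_acc += 1
                win_acc += 1
            else:
                for b in range(lo, hi):
                    pos[b, 0] = backup[b, 0]
                    pos[b, 1] = backup[b, 1]
                    pos[b, 2] = backup[b, 2]

            # amplitude adaptation toward 30-50% acceptance during burn-in
            if sweep < adapt_sweeps and win_att >= 200:
                rate = win_acc / win_att
                idx = 1 if do_trans else 0
                if rate < 0.30:
                    amps[idx] *= 0.85
                elif rate > 0.50:
                    amps[idx] *= 1.15
                if amps[0] > np.pi:
                    amps[0] = np.pi
                if amps[0] < 1e-3:
                    amps[0] = 1e-3
                if box > 0.0 and amps[1] > 0.25 * box:
                    amps[1] = 0.25 * box
                if amps[1] < 1e-2:
                    amps[1] = 1e-2
                win_acc = 0
                win_att = 0

        if sweep % thin == 0 and frame_idx < frame_e.shape[0]:
            for c8 in range(8):
                frame_e[frame_idx, c8] = u[c8]
            frame_np[frame_idx] = cur_npairs
            for r in range(n_res):
                frame_partner[frame_idx, r] = cur_partner[r]
            frame_idx += 1
        if record_coords and sweep % coords_thin == 0 and coord_idx < coords_out.shape[0]:
            for b in range(n_beads):
                coords_out[coord_idx, b, 0] = pos[b, 0]
                coords_out[coord_idx, b, 1] = pos[b, 1]
                coords_out[coord_idx, b, 2] = pos[b, 2]
            coord_idx += 1

    return n_acc, n_att, u, frame_idx, coord_idx
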