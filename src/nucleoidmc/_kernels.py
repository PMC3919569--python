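"""Numba kernels for the Metropolis Monte-Carlo engine.

The move set preserves bond lengths exactly:

* crankshaft — rigid rotation of a contiguous block of vertices about the
  axis through its two anchoring vertices.  When the block interior contains
  a junction vertex shared with another chain, the whole pendant chain is
  co-rotated rigidly (the rotation is an isometry fixing the anchors, so
  every bond is preserved).
* end rotation — rigid rotation of a terminal block of a free-ended linear
  chain about a random axis through its single anchor.
* junction reflection — a degree-3 junction vertex is reflected through the
  plane of its three neighbors (the only other solution of the three bond
  constraints); gives local mobility to replication-fork vertices.
* component translation (optional) — rigid translation of a whole connected
  component; used for phantom-chain and single-tethered-vertex tests.

Overlap detection uses a linked-cell grid over segment midpoints with cell
size >= segment length + hard-core diameter, so all candidate pairs are in
the 27 neighboring cells.  Because every move is an isometry of the moved
set, moved-moved segment pairs need no re-check; only moved-static pairs
and pairs involving a partially moved (anchor) segment are tested.

All randomness comes from numpy's global MT19937 stream, seeded once per
run via :func:`seed_rng`; runs are bit-reproducible per seed.
"""

import numpy as np
from numba import njit

__all__ = ["seed_rng", "build_grid", "run_moves"]


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=False)
def _segdist2(p1x, p1y, p1z, q1x, q1y, q1z, p2x, p2y, p2z, q2x, q2y, q2z):
    """Squared minimum distance between segments p1-q1 and p2-q2."""
    d1x = q1x - p1x
    d1y = q1y - p1y
    d1z = q1z - p1z
    d2x = q2x - p2x
    d2y = q2y - p2y
    d2z = q2z - p2z
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    eps = 1e-14
    s = 0.0
    t = 0.0
    if a <= eps and e <= eps:
        return rx * rx + ry * ry + rz * rz
    if a <= eps:
        t = f / e
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= eps:
            s = -c / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > eps:
                s = (b * f - c * e) / denom
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = -c / a
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
            elif t > 1.0:
                t = 1.0
                s = (b - c) / a
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
    cx = rx + s * d1x - t * d2x
    cy = ry + s * d1y - t * d2y
    cz = rz + s * d1z - t * d2z
    return cx * cx + cy * cy + cz * cz


@njit(cache=True)
def build_grid(pos, segs, glo, inv_cell, gdim, head, nxt, seg_mid, seg_cell):
    """(Re)build the linked-cell grid of segment midpoints.

    Returns the number of segments falling outside the grid box (must be 0
    for a usable grid).
    """
    head[:] = -1
    S = segs.shape[0]
    nx, ny, nz = gdim[0], gdim[1], gdim[2]
    bad = 0
    for s in range(S):
        a = segs[s, 0]
        b = segs[s, 1]
        mx = 0.5 * (pos[a, 0] + pos[b, 0])
        my = 0.5 * (pos[a, 1] + pos[b, 1])
        mz = 0.5 * (pos[a, 2] + pos[b, 2])
        seg_mid[s, 0] = mx
        seg_mid[s, 1] = my
        seg_mid[s, 2] = mz
        ix = int(np.floor((mx - glo[0]) * inv_cell))
        iy = int(np.floor((my - glo[1]) * inv_cell))
        iz = int(np.floor((mz - glo[2]) * inv_cell))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            bad += 1
            seg_cell[s] = -1
            continue
        cell = ix + nx * (iy + ny * iz)
        seg_cell[s] = cell
        nxt[s] = head[cell]
        head[cell] = s
    return bad


@njit(cache=True)
def _is_excluded(excl_ptr, excl_idx, s, t):
    lo = excl_ptr[s]
    hi = excl_ptr[s + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = excl_idx[mid]
        if v == t:
            return True
        elif v < t:
            lo = mid + 1
        else:
            hi = mid
    return False



@njit(cache=True)
def _sphere_term(dn2, do2, r2max, rmd, kk, wall_k):
    """Energy delta of one member against its sphere; False = hard reject.

    Hard wall with piston semantics when wall_k == 0, harmonic wall (soft,
    annealing) when wall_k > 0; plus the condensation bias kk toward the
    center."""
    d = 0.0
    if dn2 > r2max:
        if wall_k > 0.0:
            en = np.sqrt(dn2) - rmd
            eo = np.sqrt(do2) - rmd
            if eo < 0.0:
                eo = 0.0
            d += 0.5 * wall_k * (en * en - eo * eo)
        elif dn2 > do2:
            return 0.0, False
    elif wall_k > 0.0 and do2 > r2max:
        eo = np.sqrt(do2) - rmd
        d -= 0.5 * wall_k * eo * eo
    d += 0.5 * kk * (dn2 - do2)
    return d, True


@njit(cache=True)
def run_moves(
    n_moves,
    # geometry / state
    pos,
    segs,
    seg_chain,
    seg_pos,
    chain_ptr,
    chain_verts,
    chain_circ,
    # bending
    joint_tri,
    joint_kappa,
    jv_ptr,
    jv_idx,
    # constraints
    vert_md,
    md_ptr,
    md_verts,
    md_center,
    md_k,
    md_r,
    md_wall_k,
    md_is_com,
    md_sum,
    md_ub,
    vert_pin,
    pin_tgt,
    pin_k,
    pin_long,
    # topology helpers
    vs_ptr,
    vs_idx,
    excl_ptr,
    excl_idx,
    is_junc,
    free_end,
    pend_junc,
    pend_chain,
    pend_ptr,
    pend_idx,
    refl_junc,
    refl_nb,
    comp_ptr,
    comp_verts,
    # flags / params
    bend_on,
    sa_on,
    conf_on,
    conf_r,
    conf_half,
    conf_wall_k,
    hard_d2,
    max_block,
    amp,
    p_reflect,
    p_trans,
    trans_amp,
    # grid
    glo,
    inv_cell,
    gdim,
    head,
    nxt,
    seg_mid,
    seg_cell,
    # scratch
    in_moved,
    moved_buf,
    npos_buf,
    idx_of,
    seg_mark,
    aff_buf,
    aff_lvl,
    md_cnt,
    md_touch,
    md_cmoved,
    md_pend_ub,
):
    S = segs.shape[0]
    nx, ny, nz = gdim[0], gdim[1], gdim[2]
    n_accept = 0
    n_overflow = 0
    ncomp = comp_ptr.shape[0] - 1
    nrefl = refl_junc.shape[0]
    conf_r2 = conf_r * conf_r

    ba = np.empty(4, dtype=np.int64)  # bend-anchor vertex list

    for _step in range(n_moves):
        u = np.random.random()
        m = 0  # moved vertex count
        nb = 0  # bend anchors
        ok = True

        if u < p_reflect and nrefl > 0:
            # --- junction reflection -----------------------------------
            r = int(np.random.random() * nrefl)
            if r >= nrefl:
                r = nrefl - 1
            jv = refl_junc[r]
            n1 = refl_nb[r, 0]
            n2 = refl_nb[r, 1]
            n3 = refl_nb[r, 2]
            ax = pos[n2, 0] - pos[n1, 0]
            ay = pos[n2, 1] - pos[n1, 1]
            az = pos[n2, 2] - pos[n1, 2]
            bx = pos[n3, 0] - pos[n1, 0]
            by = pos[n3, 1] - pos[n1, 1]
            bz = pos[n3, 2] - pos[n1, 2]
            nxv = ay * bz - az * by
            nyv = az * bx - ax * bz
            nzv = ax * by - ay * bx
            nn = np.sqrt(nxv * nxv + nyv * nyv + nzv * nzv)
            if nn < 1e-9:
                continue
            nxv /= nn
            nyv /= nn
            nzv /= nn
            dx = pos[jv, 0] - pos[n1, 0]
            dy = pos[jv, 1] - pos[n1, 1]
            dz = pos[jv, 2] - pos[n1, 2]
            h = dx * nxv + dy * nyv + dz * nzv
            moved_buf[0] = jv
            in_moved[jv] = True
            idx_of[jv] = 0
            npos_buf[0, 0] = pos[jv, 0] - 2.0 * h * nxv
            npos_buf[0, 1] = pos[jv, 1] - 2.0 * h * nyv
            npos_buf[0, 2] = pos[jv, 2] - 2.0 * h * nzv
            m = 1
            ba[0] = n1
            ba[1] = n2
            ba[2] = n3
            ba[3] = jv
            nb = 4
        elif u < p_reflect + p_trans:
            # --- rigid translation of a connected component -------------
            ci = int(np.random.random() * ncomp)
            if ci >= ncomp:
                ci = ncomp - 1
            tx = trans_amp * (2.0 * np.random.random() - 1.0)
            ty = trans_amp * (2.0 * np.random.random() - 1.0)
            tz = trans_amp * (2.0 * np.random.random() - 1.0)
            for k in range(comp_ptr[ci], comp_ptr[ci + 1]):
                v = comp_verts[k]
                moved_buf[m] = v
                in_moved[v] = True
                idx_of[v] = m
                npos_buf[m, 0] = pos[v, 0] + tx
                npos_buf[m, 1] = pos[v, 1] + ty
                npos_buf[m, 2] = pos[v, 2] + tz
                m += 1
            nb = 0
        else:
            # --- crankshaft / end rotation ------------------------------
            if S == 0:
                continue
            s0 = int(np.random.random() * S)
            if s0 >= S:
                s0 = S - 1
            c = seg_chain[s0]
            i = seg_pos[s0]
            base = chain_ptr[c]
            n = chain_ptr[c + 1] - base
            circ = chain_circ[c]
            blk = 1 + int(np.random.random() * max_block)
            if blk > max_block:
                blk = max_block
            end_rot = False
            step = 1
            if circ:
                a1p = i
                if blk > n - 2:
                    blk = n - 2
                a2p = (i + blk + 1) % n
            else:
                # pick a direction so both chain ends are mobile
                if np.random.random() < 0.5:
                    a1p = i
                    step = 1
                    last = n - 1
                else:
                    a1p = i + 1
                    step = -1
                    last = 0
                room = (last - a1p) * step  # vertices beyond the anchor
                if room < 2:
                    endv = chain_verts[base + last]
                    if free_end[endv] and room >= 1:
                        end_rot = True
                        blk = room
                    else:
                        continue
                elif blk + 1 > room:
                    endv = chain_verts[base + last]
                    if free_end[endv]:
                        end_rot = True
                        blk = room
                    else:
                        blk = room - 1
                if end_rot:
                    a2p = a1p
                else:
                    a2p = a1p + (blk + 1) * step
            g1 = chain_verts[base + a1p]
            g2 = chain_verts[base + a2p]
            # axis
            p0x = pos[g1, 0]
            p0y = pos[g1, 1]
            p0z = pos[g1, 2]
            if end_rot:
                axx = np.random.normal()
                axy = np.random.normal()
                axz = np.random.normal()
            else:
                axx = pos[g2, 0] - p0x
                axy = pos[g2, 1] - p0y
                axz = pos[g2, 2] - p0z
            al = np.sqrt(axx * axx + axy * axy + axz * axz)
            if al < 1e-9:
                continue
            axx /= al
            axy /= al
            axz /= al
            theta = amp * (2.0 * np.random.random() - 1.0)
            ct = np.cos(theta)
            st = np.sin(theta)
            omc = 1.0 - ct
            # rotation matrix (Rodrigues)
            r00 = ct + axx * axx * omc
            r01 = axx * axy * omc - axz * st
            r02 = axx * axz * omc + axy * st
            r10 = axy * axx * omc + axz * st
            r11 = ct + axy * axy * omc
            r12 = axy * axz * omc - axx * st
            r20 = axz * axx * omc - axy * st
            r21 = axz * axy * omc + axx * st
            r22 = ct + axz * axz * omc

            for k in range(1, blk + 1):
                if circ:
                    pp = (a1p + k) % n
                else:
                    pp = a1p + k * step
                v = chain_verts[base + pp]
                if in_moved[v]:
                    continue
                moved_buf[m] = v
                in_moved[v] = True
                m += 1
                if is_junc[v]:
                    # co-rotate pendant chains hanging off this junction;
                    # junctions with no valid pendant set cannot be moved
                    # by a block move
                    found = False
                    if circ:
                        for q in range(pend_junc.shape[0]):
                            if pend_junc[q] == v and pend_chain[q] == c:
                                found = True
                                for kk in range(pend_ptr[q], pend_ptr[q + 1]):
                                    w = pend_idx[kk]
                                    if not in_moved[w]:
                                        moved_buf[m] = w
                                        in_moved[w] = True
                                        m += 1
                    if not found:
                        ok = False
                        break
            for j in range(m if ok else 0):
                v = moved_buf[j]
                idx_of[v] = j
                xx = pos[v, 0] - p0x
                yy = pos[v, 1] - p0y
                zz = pos[v, 2] - p0z
                npos_buf[j, 0] = p0x + r00 * xx + r01 * yy + r02 * zz
                npos_buf[j, 1] = p0y + r10 * xx + r11 * yy + r12 * zz
                npos_buf[j, 2] = p0z + r20 * xx + r21 * yy + r22 * zz
            ba[0] = g1
            nb = 1
            if not end_rot:
                ba[1] = g2
                nb = 2

        if m == 0:
            continue

        # --- hard constraint: confinement ------------------------------
        # piston rule: a vertex already outside (during annealing) may
        # move, but never farther out; identical to the plain hard wall
        # whenever the current state is feasible.  With conf_wall_k > 0
        # the walls are soft (harmonic on the excess; annealing only).
        dE = 0.0
        if ok and conf_on:
            for j in range(m):
                v = moved_buf[j]
                x = abs(npos_buf[j, 0])
                y = npos_buf[j, 1]
                z = npos_buf[j, 2]
                r2n = y * y + z * z
                if conf_wall_k > 0.0:
                    rn = np.sqrt(r2n)
                    ro = np.sqrt(
                        pos[v, 1] * pos[v, 1] + pos[v, 2] * pos[v, 2]
                    )
                    en = rn - conf_r
                    eo = ro - conf_r
                    if en > 0.0 or eo > 0.0:
                        if en < 0.0:
                            en = 0.0
                        if eo < 0.0:
                            eo = 0.0
                        dE += 0.5 * conf_wall_k * (en * en - eo * eo)
                    en = x - conf_half
                    eo = abs(pos[v, 0]) - conf_half
                    if en > 0.0 or eo > 0.0:
                        if en < 0.0:
                            en = 0.0
                        if eo < 0.0:
                            eo = 0.0
                        dE += 0.5 * conf_wall_k * (en * en - eo * eo)
                else:
                    if r2n > conf_r2:
                        r2o = pos[v, 1] * pos[v, 1] + pos[v, 2] * pos[v, 2]
                        if r2n > r2o:
                            ok = False
                            break
                    if x > conf_half:
                        if x > abs(pos[v, 0]):
                            ok = False
                            break

        # --- macrodomain spheres + harmonic bias ------------------------
        nt = 0
        n_mds = md_ptr.shape[0] - 1
        if ok and n_mds > 0:
            for j in range(m):
                v = moved_buf[j]
                mdid = vert_md[v]
                if mdid >= 0:
                    if md_cnt[mdid] == 0:
                        md_touch[nt] = mdid
                        nt += 1
                    md_cnt[mdid] += 1
            # centers may be shared between MDs (e.g. the terminus junction
            # centers both Ter copies) and need not be members themselves
            for mdid in range(n_mds):
                if not md_is_com[mdid] and in_moved[md_center[mdid]]:
                    md_cmoved[mdid] = True
                    if md_cnt[mdid] == 0:
                        md_touch[nt] = mdid
                        nt += 1
                        md_cnt[mdid] = -1  # touched marker without members
            for q in range(nt):
                mdid = md_touch[q]
                size = md_ptr[mdid + 1] - md_ptr[mdid]
                kk = md_k[mdid]
                rmd = md_r[mdid]
                r2max = rmd * rmd + 1e-9
                if md_is_com[mdid]:
                    # center-of-mass center: moves with the moved members.
                    # Harmonic term via running sums (O(moved)); hard wall
                    # checks only moved members plus a drift-tracked upper
                    # bound on the unmoved members' extent, with a full
                    # rescan when the bound approaches the wall.
                    if md_cnt[mdid] == size:
                        continue  # rigid
                    dsx = 0.0
                    dsy = 0.0
                    dsz = 0.0
                    ds2 = 0.0
                    for j in range(m):
                        w = moved_buf[j]
                        if vert_md[w] == mdid:
                            jw = idx_of[w]
                            nx_ = npos_buf[jw, 0]
                            ny_ = npos_buf[jw, 1]
                            nz_ = npos_buf[jw, 2]
                            ox_ = pos[w, 0]
                            oy_ = pos[w, 1]
                            oz_ = pos[w, 2]
                            dsx += nx_ - ox_
                            dsy += ny_ - oy_
                            dsz += nz_ - oz_
                            ds2 += (
                                nx_ * nx_ + ny_ * ny_ + nz_ * nz_
                                - ox_ * ox_ - oy_ * oy_ - oz_ * oz_
                            )
                    cxo = md_sum[mdid, 0] / size
                    cyo = md_sum[mdid, 1] / size
                    czo = md_sum[mdid, 2] / size
                    cxn = cxo + dsx / size
                    cyn = cyo + dsy / size
                    czn = czo + dsz / size
                    delta_c = np.sqrt(
                        (cxn - cxo) ** 2 + (cyn - cyo) ** 2 + (czn - czo) ** 2
                    )
                    # sum over members of |w - c|^2 = sum |w|^2 - size |c|^2
                    c2n = cxn * cxn + cyn * cyn + czn * czn
                    c2o = cxo * cxo + cyo * cyo + czo * czo
                    dE += 0.5 * kk * (ds2 - size * (c2n - c2o))
                    if md_wall_k > 0.0:
                        # soft wall (annealing): full member scan
                        for kmem in range(md_ptr[mdid], md_ptr[mdid + 1]):
                            w = md_verts[kmem]
                            if in_moved[w]:
                                jw = idx_of[w]
                                wxn = npos_buf[jw, 0]
                                wyn = npos_buf[jw, 1]
                                wzn = npos_buf[jw, 2]
                            else:
                                wxn = pos[w, 0]
                                wyn = pos[w, 1]
                                wzn = pos[w, 2]
                            dn2 = (
                                (wxn - cxn) ** 2
                                + (wyn - cyn) ** 2
                                + (wzn - czn) ** 2
                            )
                            do2 = (
                                (pos[w, 0] - cxo) ** 2
                                + (pos[w, 1] - cyo) ** 2
                                + (pos[w, 2] - czo) ** 2
                            )
                            if dn2 > r2max:
                                en = np.sqrt(dn2) - rmd
                                eo = np.sqrt(do2) - rmd
                                if eo < 0.0:
                                    eo = 0.0
                                dE += 0.5 * md_wall_k * (en * en - eo * eo)
                            elif do2 > r2max:
                                eo = np.sqrt(do2) - rmd
                                dE -= 0.5 * md_wall_k * eo * eo
                        md_pend_ub[mdid] = 1e17  # force rescan next chunk
                    else:
                        mx2 = 0.0
                        for j in range(m):
                            w = moved_buf[j]
                            if vert_md[w] != mdid:
                                continue
                            jw = idx_of[w]
                            dn2 = (
                                (npos_buf[jw, 0] - cxn) ** 2
                                + (npos_buf[jw, 1] - cyn) ** 2
                                + (npos_buf[jw, 2] - czn) ** 2
                            )
                            if dn2 > r2max:
                                do2 = (
                                    (pos[w, 0] - cxo) ** 2
                                    + (pos[w, 1] - cyo) ** 2
                                    + (pos[w, 2] - czo) ** 2
                                )
                                if dn2 > do2:
                                    ok = False  # piston rule
                                    break
                            if dn2 > mx2:
                                mx2 = dn2
                        if ok and md_ub[mdid] + delta_c > rmd:
                            # unmoved members may now breach: full rescan
                            for kmem in range(md_ptr[mdid], md_ptr[mdid + 1]):
                                w = md_verts[kmem]
                                if in_moved[w]:
                                    continue
                                dn2 = (
                                    (pos[w, 0] - cxn) ** 2
                                    + (pos[w, 1] - cyn) ** 2
                                    + (pos[w, 2] - czn) ** 2
                                )
                                if dn2 > r2max:
                                    do2 = (
                                        (pos[w, 0] - cxo) ** 2
                                        + (pos[w, 1] - cyo) ** 2
                                        + (pos[w, 2] - czo) ** 2
                                    )
                                    if dn2 > do2:
                                        ok = False  # piston rule
                                        break
                                if dn2 > mx2:
                                    mx2 = dn2
                            md_pend_ub[mdid] = np.sqrt(mx2)
                        else:
                            mxm = np.sqrt(mx2)
                            ub = md_ub[mdid] + delta_c
                            md_pend_ub[mdid] = ub if ub > mxm else mxm
                    if not ok:
                        break
                elif md_cmoved[mdid]:
                    if md_cnt[mdid] == size:
                        continue  # rigid: distances to center preserved
                    cv = md_center[mdid]
                    jc = idx_of[cv]
                    cxn = npos_buf[jc, 0]
                    cyn = npos_buf[jc, 1]
                    czn = npos_buf[jc, 2]
                    cxo = pos[cv, 0]
                    cyo = pos[cv, 1]
                    czo = pos[cv, 2]
                    for kmem in range(md_ptr[mdid], md_ptr[mdid + 1]):
                        w = md_verts[kmem]
                        if in_moved[w]:
                            jw = idx_of[w]
                            wxn = npos_buf[jw, 0]
                            wyn = npos_buf[jw, 1]
                            wzn = npos_buf[jw, 2]
                        else:
                            wxn = pos[w, 0]
                            wyn = pos[w, 1]
                            wzn = pos[w, 2]
                        dxn = wxn - cxn
                        dyn = wyn - cyn
                        dzn = wzn - czn
                        dn2 = dxn * dxn + dyn * dyn + dzn * dzn
                        dxo = pos[w, 0] - cxo
                        dyo = pos[w, 1] - cyo
                        dzo = pos[w, 2] - czo
                        do2 = dxo * dxo + dyo * dyo + dzo * dzo
                        d, keep = _sphere_term(dn2, do2, r2max, rmd, kk, md_wall_k)
                        if not keep:
                            ok = False
                            break
                        dE += d
                    if not ok:
                        break
                else:
                    cv = md_center[mdid]
                    cxo = pos[cv, 0]
                    cyo = pos[cv, 1]
                    czo = pos[cv, 2]
                    for j in range(m):
                        w = moved_buf[j]
                        if vert_md[w] != mdid:
                            continue
                        dxn = npos_buf[j, 0] - cxo
                        dyn = npos_buf[j, 1] - cyo
                        dzn = npos_buf[j, 2] - czo
                        dn2 = dxn * dxn + dyn * dyn + dzn * dzn
                        dxo = pos[w, 0] - cxo
                        dyo = pos[w, 1] - cyo
                        dzo = pos[w, 2] - czo
                        do2 = dxo * dxo + dyo * dyo + dzo * dzo
                        d, keep = _sphere_term(dn2, do2, r2max, rmd, kk, md_wall_k)
                        if not keep:
                            ok = False
                            break
                        dE += d
                    if not ok:
                        break

        # --- pins -------------------------------------------------------
        if ok and pin_k.shape[0] > 0:
            for j in range(m):
                v = moved_buf[j]
                pid = vert_pin[v]
                if pid < 0:
                    continue
                if pin_long[pid]:
                    dn = npos_buf[j, 0] - pin_tgt[pid, 0]
                    do = pos[v, 0] - pin_tgt[pid, 0]
                    dE += 0.5 * pin_k[pid] * (dn * dn - do * do)
                else:
                    dn2 = 0.0
                    do2 = 0.0
                    for ax in range(3):
                        dn = npos_buf[j, ax] - pin_tgt[pid, ax]
                        do = pos[v, ax] - pin_tgt[pid, ax]
                        dn2 += dn * dn
                        do2 += do * do
                    dE += 0.5 * pin_k[pid] * (dn2 - do2)

        # --- bending at affected joints ---------------------------------
        if ok and bend_on:
            for q in range(nb):
                a = ba[q]
                for t in range(jv_ptr[a], jv_ptr[a + 1]):
                    jt = jv_idx[t]
                    uu = joint_tri[jt, 0]
                    vv = joint_tri[jt, 1]
                    ww = joint_tri[jt, 2]
                    # old angle
                    u1x = pos[vv, 0] - pos[uu, 0]
                    u1y = pos[vv, 1] - pos[uu, 1]
                    u1z = pos[vv, 2] - pos[uu, 2]
                    v1x = pos[ww, 0] - pos[vv, 0]
                    v1y = pos[ww, 1] - pos[vv, 1]
                    v1z = pos[ww, 2] - pos[vv, 2]
                    co = (u1x * v1x + u1y * v1y + u1z * v1z) / (
                        np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
                        * np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
                    )
                    # new angle (mixed coordinates)
                    if in_moved[uu]:
                        ju = idx_of[uu]
                        pux, puy, puz = npos_buf[ju, 0], npos_buf[ju, 1], npos_buf[ju, 2]
                    else:
                        pux, puy, puz = pos[uu, 0], pos[uu, 1], pos[uu, 2]
                    if in_moved[vv]:
                        jv2 = idx_of[vv]
                        pvx, pvy, pvz = npos_buf[jv2, 0], npos_buf[jv2, 1], npos_buf[jv2, 2]
                    else:
                        pvx, pvy, pvz = pos[vv, 0], pos[vv, 1], pos[vv, 2]
                    if in_moved[ww]:
                        jw = idx_of[ww]
                        pwx, pwy, pwz = npos_buf[jw, 0], npos_buf[jw, 1], npos_buf[jw, 2]
                    else:
                        pwx, pwy, pwz = pos[ww, 0], pos[ww, 1], pos[ww, 2]
                    u2x = pvx - pux
                    u2y = pvy - puy
                    u2z = pvz - puz
                    v2x = pwx - pvx
                    v2y = pwy - pvy
                    v2z = pwz - pvz
                    cn = (u2x * v2x + u2y * v2y + u2z * v2z) / (
                        np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
                        * np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
                    )
                    dE += joint_kappa[jt] * (co - cn)

        # --- Metropolis on the energy before the expensive overlap test --
        if ok and dE > 0.0:
            if np.random.random() > np.exp(-dE):
                ok = False

        # --- self-avoidance ---------------------------------------------
        na = 0
        if ok and sa_on:
            for j in range(m):
                v = moved_buf[j]
                for t in range(vs_ptr[v], vs_ptr[v + 1]):
                    s2 = vs_idx[t]
                    if seg_mark[s2] == 0:
                        seg_mark[s2] = 1
                        aff_buf[na] = s2
                        na += 1
            # levels and moved-static checks via the grid
            for jj in range(na):
                if not ok:
                    break
                s2 = aff_buf[jj]
                e0 = segs[s2, 0]
                e1 = segs[s2, 1]
                lvl = 0
                if in_moved[e0]:
                    lvl += 1
                    j0 = idx_of[e0]
                    a0x, a0y, a0z = npos_buf[j0, 0], npos_buf[j0, 1], npos_buf[j0, 2]
                else:
                    a0x, a0y, a0z = pos[e0, 0], pos[e0, 1], pos[e0, 2]
                if in_moved[e1]:
                    lvl += 1
                    j1 = idx_of[e1]
                    a1x, a1y, a1z = npos_buf[j1, 0], npos_buf[j1, 1], npos_buf[j1, 2]
                else:
                    a1x, a1y, a1z = pos[e1, 0], pos[e1, 1], pos[e1, 2]
                aff_lvl[jj] = lvl
                mx = 0.5 * (a0x + a1x)
                my = 0.5 * (a0y + a1y)
                mz = 0.5 * (a0z + a1z)
                ix = int(np.floor((mx - glo[0]) * inv_cell))
                iy = int(np.floor((my - glo[1]) * inv_cell))
                iz = int(np.floor((mz - glo[2]) * inv_cell))
                if (
                    ix < 1
                    or ix >= nx - 1
                    or iy < 1
                    or iy >= ny - 1
                    or iz < 1
                    or iz >= nz - 1
                ):
                    n_overflow += 1
                    ok = False
                    break
                for ddz in range(-1, 2):
                    if not ok:
                        break
                    for ddy in range(-1, 2):
                        if not ok:
                            break
                        cbase = ix - 1 + nx * (iy + ddy + ny * (iz + ddz))
                        for ddx in range(3):
                            tseg = head[cbase + ddx]
                            while tseg >= 0:
                                if seg_mark[tseg] == 0 and not _is_excluded(
                                    excl_ptr, excl_idx, s2, tseg
                                ):
                                    t0 = segs[tseg, 0]
                                    t1 = segs[tseg, 1]
                                    d2 = _segdist2(
                                        a0x,
                                        a0y,
                                        a0z,
                                        a1x,
                                        a1y,
                                        a1z,
                                        pos[t0, 0],
                                        pos[t0, 1],
                                        pos[t0, 2],
                                        pos[t1, 0],
                                        pos[t1, 1],
                                        pos[t1, 2],
                                    )
                                    if d2 < hard_d2:
                                        ok = False
                                        break
                                tseg = nxt[tseg]
                            if not ok:
                                break
            # affected-affected pairs: only pairs involving a partially
            # moved (anchor) segment can change internal distances
            if ok:
                for jj in range(na):
                    if aff_lvl[jj] != 1:
                        continue
                    s2 = aff_buf[jj]
                    e0 = segs[s2, 0]
                    e1 = segs[s2, 1]
                    if in_moved[e0]:
                        j0 = idx_of[e0]
                        a0x, a0y, a0z = npos_buf[j0, 0], npos_buf[j0, 1], npos_buf[j0, 2]
                    else:
                        a0x, a0y, a0z = pos[e0, 0], pos[e0, 1], pos[e0, 2]
                    if in_moved[e1]:
                        j1 = idx_of[e1]
                        a1x, a1y, a1z = npos_buf[j1, 0], npos_buf[j1, 1], npos_buf[j1, 2]
                    else:
                        a1x, a1y, a1z = pos[e1, 0], pos[e1, 1], pos[e1, 2]
                    for kk in range(na):
                        if kk == jj:
                            continue
                        tseg = aff_buf[kk]
                        if _is_excluded(excl_ptr, excl_idx, s2, tseg):
                            continue
                        t0 = segs[tseg, 0]
                        t1 = segs[tseg, 1]
                        if in_moved[t0]:
                            j0 = idx_of[t0]
                            b0x, b0y, b0z = npos_buf[j0, 0], npos_buf[j0, 1], npos_buf[j0, 2]
                        else:
                            b0x, b0y, b0z = pos[t0, 0], pos[t0, 1], pos[t0, 2]
                        if in_moved[t1]:
                            j1 = idx_of[t1]
                            b1x, b1y, b1z = npos_buf[j1, 0], npos_buf[j1, 1], npos_buf[j1, 2]
                        else:
                            b1x, b1y, b1z = pos[t1, 0], pos[t1, 1], pos[t1, 2]
                        d2 = _segdist2(
                            a0x, a0y, a0z, a1x, a1y, a1z,
                            b0x, b0y, b0z, b1x, b1y, b1z,
                        )
                        if d2 < hard_d2:
                            ok = False
                            break
                    if not ok:
                        break

        # --- commit ------------------------------------------------------
        if ok:
            n_accept += 1
            for q in range(nt):
                mdid = md_touch[q]
                if md_is_com[mdid] and md_cnt[mdid] != (
                    md_ptr[mdid + 1] - md_ptr[mdid]
                ):
                    md_ub[mdid] = md_pend_ub[mdid]
            for j in range(m):
                v = moved_buf[j]
                mdid = vert_md[v]
                if mdid >= 0 and md_is_com[mdid]:
                    md_sum[mdid, 0] += npos_buf[j, 0] - pos[v, 0]
                    md_sum[mdid, 1] += npos_buf[j, 1] - pos[v, 1]
                    md_sum[mdid, 2] += npos_buf[j, 2] - pos[v, 2]
                pos[v, 0] = npos_buf[j, 0]
                pos[v, 1] = npos_buf[j, 1]
                pos[v, 2] = npos_buf[j, 2]
            if sa_on:
                for jj in range(na):
                    s2 = aff_buf[jj]
                    old_cell = seg_cell[s2]
                    # unlink
                    t = head[old_cell]
                    if t == s2:
                        head[old_cell] = nxt[s2]
                    else:
                        while nxt[t] != s2:
                            t = nxt[t]
                        nxt[t] = nxt[s2]
                    e0 = segs[s2, 0]
                    e1 = segs[s2, 1]
                    mx = 0.5 * (pos[e0, 0] + pos[e1, 0])
                    my = 0.5 * (pos[e0, 1] + pos[e1, 1])
                    mz = 0.5 * (pos[e0, 2] + pos[e1, 2])
                    seg_mid[s2, 0] = mx
                    seg_mid[s2, 1] = my
                    seg_mid[s2, 2] = mz
                    ix = int(np.floor((mx - glo[0]) * inv_cell))
                    iy = int(np.floor((my - glo[1]) * inv_cell))
                    iz = int(np.floor((mz - glo[2]) * inv_cell))
                    cell = ix + nx * (iy + ny * iz)
                    seg_cell[s2] = cell
                    nxt[s2] = head[cell]
                    head[cell] = s2

        # --- reset scratch ----------------------------------------------
        for j in range(m):
            in_moved[moved_buf[j]] = False
        for jj in range(na):
            seg_mark[aff_buf[jj]] = 0
        for q in range(nt):
            md_cnt[md_touch[q]] = 0
            md_cmoved[md_touch[q]] = False

    return n_accept, n_overflow
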