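"""Compiled inner loops: crankshaft Monte Carlo, projection diagrams, writhe.

Everything here operates on plain float64/int arrays so numba can compile it;
the public modules wrap these kernels with validated, documented interfaces.
Conventions used throughout:

* a ring of N beads is a (N, 3) array of bead centers with cyclic adjacency;
* a projection diagram is a pair of event arrays (crossing id, over flag)
  listing the 2c passages through c crossings in order along the curve,
  plus a per-crossing sign array (right-hand rule);
* crossing signs follow ``sign(cross2d(tangent_over, tangent_under))`` in the
  projection plane.  A global mirror of this convention would relabel every
  knot by its mirror image, which the Alexander-based classifier does not
  distinguish, so only internal consistency matters.
"""

import numpy as np
from numba import njit

GEOM_TOL = 1e-9  # degeneracy tolerance, units of the bead-center spacing


# --------------------------------------------------------------------------
# basic geometry
# --------------------------------------------------------------------------

@njit(cache=True)
def rg_of(P):
    N = P.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(N):
        cx += P[i, 0]
        cy += P[i, 1]
        cz += P[i, 2]
    cx /= N
    cy /= N
    cz /= N
    s = 0.0
    for i in range(N):
        dx = P[i, 0] - cx
        dy = P[i, 1] - cy
        dz = P[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
    return np.sqrt(s / N)


@njit(cache=True)
def full_overlap(P, D):
    """Strict overlap test: any non-adjacent center pair closer than D."""
    if D <= 0.0:
        return False
    N = P.shape[0]
    D2 = D * D
    for i in range(N):
        for j in range(i + 2, N):
            if i == 0 and j == N - 1:
                continue
            dx = P[i, 0] - P[j, 0]
            dy = P[i, 1] - P[j, 1]
            dz = P[i, 2] - P[j, 2]
            if dx * dx + dy * dy + dz * dz < D2:
                return True
    return False


@njit(cache=True)
def renormalize_ring(P, spacing):
    """Re-project bond lengths to exactly ``spacing``.

    Each bond is rescaled sequentially, then the (tiny) closure error is
    distributed linearly along the ring.  Returns a new array.
    """
    N = P.shape[0]
    Q = np.empty_like(P)
    Q[0] = P[0]
    for i in range(N - 1):
        vx = P[i + 1, 0] - P[i, 0]
        vy = P[i + 1, 1] - P[i, 1]
        vz = P[i + 1, 2] - P[i, 2]
        nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
        f = spacing / nrm
        Q[i + 1, 0] = Q[i, 0] + vx * f
        Q[i + 1, 1] = Q[i, 1] + vy * f
        Q[i + 1, 2] = Q[i, 2] + vz * f
    vx = P[0, 0] - P[N - 1, 0]
    vy = P[0, 1] - P[N - 1, 1]
    vz = P[0, 2] - P[N - 1, 2]
    nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
    f = spacing / nrm
    ex = Q[N - 1, 0] + vx * f - Q[0, 0]
    ey = Q[N - 1, 1] + vy * f - Q[0, 1]
    ez = Q[N - 1, 2] + vz * f - Q[0, 2]
    for i in range(1, N):
        g = i / N
        Q[i, 0] -= ex * g
        Q[i, 1] -= ey * g
        Q[i, 2] -= ez * g
    return Q


# --------------------------------------------------------------------------
# crankshaft Monte Carlo
# --------------------------------------------------------------------------

@njit(cache=True)
def mc_run(P, D, spacing, n_sweeps, record_every, rand_i, rand_k, rand_ang,
           out_frames, out_rg, renorm_every, n_acc_in, n_since_in):
    """Run ``n_sweeps`` sweeps (N proposals each) of crankshaft Metropolis.

    Moves are accepted iff no bead overlap is created (hard-sphere, zero/
    infinite energy).  Every ``record_every`` sweeps the current conformation
    and its Rg are stored (``record_every == 0`` disables recording).  Bond
    lengths are re-projected every ``renorm_every`` accepted moves; the
    re-projection is reverted in the (measure-zero) case it creates overlap.

    Returns (n_accepted, n_since_renorm, n_recorded).
    """
    N = P.shape[0]
    D2 = D * D
    n_rec = 0
    n_acc = n_acc_in
    n_since = n_since_in
    idx = 0
    moved = np.empty((N, 3))
    for sweep in range(n_sweeps):
        for _m in range(N):
            i = rand_i[idx]
            k = rand_k[idx]
            ang = rand_ang[idx]
            idx += 1
            j = (i + k) % N
            ax = P[j, 0] - P[i, 0]
            ay = P[j, 1] - P[i, 1]
            az = P[j, 2] - P[i, 2]
            an = np.sqrt(ax * ax + ay * ay + az * az)
            if an < 1e-12:
                continue
            ax /= an
            ay /= an
            az /= an
            ca = np.cos(ang)
            sa = np.sin(ang)
            omc = 1.0 - ca
            nmv = k - 1
            for m2 in range(nmv):
                b = (i + 1 + m2) % N
                vx = P[b, 0] - P[i, 0]
                vy = P[b, 1] - P[i, 1]
                vz = P[b, 2] - P[i, 2]
                dot = ax * vx + ay * vy + az * vz
                cxv = ay * vz - az * vy
                cyv = az * vx - ax * vz
                czv = ax * vy - ay * vx
                moved[m2, 0] = P[i, 0] + vx * ca + cxv * sa + ax * dot * omc
                moved[m2, 1] = P[i, 1] + vy * ca + cyv * sa + ay * dot * omc
                moved[m2, 2] = P[i, 2] + vz * ca + czv * sa + az * dot * omc
            ok = True
            if D2 > 0.0:
                n_un = N - k - 1
                for m2 in range(nmv):
                    mx = moved[m2, 0]
                    my = moved[m2, 1]
                    mz = moved[m2, 2]
                    for q in range(n_un):
                        u = (j + 1 + q) % N
                        dx = mx - P[u, 0]
                        dy = my - P[u, 1]
                        dz = mz - P[u, 2]
                        if dx * dx + dy * dy + dz * dz < D2:
                            ok = False
                            break
                    if not ok:
                        break
            if ok:
                for m2 in range(nmv):
                    b = (i + 1 + m2) % N
                    P[b, 0] = moved[m2, 0]
                    P[b, 1] = moved[m2, 1]
                    P[b, 2] = moved[m2, 2]
                n_acc += 1
                n_since += 1
                if n_since >= renorm_every:
                    Q = renormalize_ring(P, spacing)
                    if not full_overlap(Q, D):
                        P[:] = Q
                    n_since = 0
        if record_every > 0 and (sweep + 1) % record_every == 0:
            if n_rec < out_frames.shape[0]:
                out_frames[n_rec] = P
                out_rg[n_rec] = rg_of(P)
                n_rec += 1
    return n_acc, n_since, n_rec


# --------------------------------------------------------------------------
# projection diagrams
# --------------------------------------------------------------------------

@njit(cache=True)
def project_crossings(P, dx, dy, dz, tol, pos, over_first, sign):
    """Orthogonal projection of the closed ring along unit direction d.

    Fills per-crossing arrays:
      pos[c, 0:2] -- positions along the curve (segment index + fraction) of
                     the lower-index and higher-index strand visits;
      over_first[c] -- 1 if the lower-index strand passes over;
      sign[c]     -- crossing sign by the right-hand rule.
    Returns (status, n_crossings); status 1 flags a degenerate projection
    (segment parallel to d, vertex/tangential intersection, or coincident
    depths) for which the caller must redraw the direction.
    """
    N = P.shape[0]
    # orthonormal basis (e1, e2) of the projection plane
    if abs(dx) <= abs(dy) and abs(dx) <= abs(dz):
        hx, hy, hz = 1.0, 0.0, 0.0
    elif abs(dy) <= abs(dz):
        hx, hy, hz = 0.0, 1.0, 0.0
    else:
        hx, hy, hz = 0.0, 0.0, 1.0
    hd = hx * dx + hy * dy + hz * dz
    e1x = hx - hd * dx
    e1y = hy - hd * dy
    e1z = hz - hd * dz
    e1n = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= e1n
    e1y /= e1n
    e1z /= e1n
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x

    x = np.empty(N)
    y = np.empty(N)
    z = np.empty(N)
    for i in range(N):
        x[i] = P[i, 0] * e1x + P[i, 1] * e1y + P[i, 2] * e1z
        y[i] = P[i, 0] * e2x + P[i, 1] * e2y + P[i, 2] * e2z
        z[i] = P[i, 0] * dx + P[i, 1] * dy + P[i, 2] * dz
    # a segment (nearly) parallel to d projects to a point: degenerate
    for i in range(N):
        i2 = i + 1 if i < N - 1 else 0
        sx = x[i2] - x[i]
        sy = y[i2] - y[i]
        if np.sqrt(sx * sx + sy * sy) < tol:
            return 1, 0

    c = 0
    for i in range(N):
        i2 = i + 1 if i < N - 1 else 0
        axx = x[i2] - x[i]
        axy = y[i2] - y[i]
        for j in range(i + 2, N):
            if i == 0 and j == N - 1:
                continue
            j2 = j + 1 if j < N - 1 else 0
            bxx = x[j2] - x[j]
            bxy = y[j2] - y[j]
            den = axx * bxy - axy * bxx
            rx = x[j] - x[i]
            ry = y[j] - y[i]
            la2 = axx * axx + axy * axy
            lb2 = bxx * bxx + bxy * bxy
            scale = np.sqrt(la2 * lb2)
            if abs(den) < 1e-13 * scale:
                # parallel in projection: degenerate only if lines nearly
                # coincide (tangential contact possible)
                perp = rx * axy - ry * axx
                if abs(perp) / np.sqrt(la2) < tol:
                    return 1, 0
                continue
            s = (rx * bxy - ry * bxx) / den
            u = (rx * axy - ry * axx) / den
            inside_s = (s > tol) and (s < 1.0 - tol)
            inside_u = (u > tol) and (u < 1.0 - tol)
            if inside_s and inside_u:
                za = z[i] * (1.0 - s) + z[i2] * s
                zb = z[j] * (1.0 - u) + z[j2] * u
                if abs(za - zb) < tol:
                    return 1, 0
                pos[c, 0] = i + s
                pos[c, 1] = j + u
                if za > zb:
                    over_first[c] = 1
                    sign[c] = 1 if den > 0.0 else -1
                else:
                    over_first[c] = 0
                    sign[c] = 1 if -den > 0.0 else -1
                c += 1
            else:
                near_s = (s >= -tol) and (s <= 1.0 + tol)
                near_u = (u >= -tol) and (u <= 1.0 + tol)
                if near_s and near_u:
                    # intersection at (or hair-close to) a vertex
                    return 1, 0
    return 0, c


@njit(cache=True)
def sort_events(pos, c, over_first, tol, ev_cross, ev_over):
    """Order the 2c crossing passages along the curve.

    Returns the number of events, or -1 if two passages are closer than tol
    along the curve (ordering ambiguity; caller redraws the direction).
    """
    n_ev = 2 * c
    evpos = np.empty(n_ev)
    for k in range(c):
        evpos[2 * k] = pos[k, 0]
        evpos[2 * k + 1] = pos[k, 1]
    order = np.argsort(evpos)
    for m in range(n_ev - 1):
        if evpos[order[m + 1]] - evpos[order[m]] < tol:
            return -1
    for m in range(n_ev):
        e = order[m]
        cid = e // 2
        ev_cross[m] = cid
        if e % 2 == 0:
            ev_over[m] = over_first[cid]
        else:
            ev_over[m] = 1 - over_first[cid]
    return n_ev


@njit(cache=True)
def _compact4(ev_cross, ev_over, n_ev, r1, r2, r3, r4):
    w = 0
    for m in range(n_ev):
        if m == r1 or m == r2 or m == r3 or m == r4:
            continue
        ev_cross[w] = ev_cross[m]
        ev_over[w] = ev_over[m]
        w += 1
    return w


@njit(cache=True)
def reduce_events(ev_cross, ev_over, n_ev):
    """Iteratively remove Reidemeister-I kinks and R-II cancellable pairs.

    Works on the first ``n_ev`` entries in place; returns the new count.
    A kink is a crossing whose two passages are consecutive along the curve;
    an R-II pair is two crossings whose passages are consecutive on both
    strands with one strand passing over at both (the two connecting arcs
    then carry no other crossings, so the pair is always removable).
    """
    changed = True
    while changed and n_ev > 0:
        changed = False
        # R1
        for a in range(n_ev):
            b = a + 1 if a < n_ev - 1 else 0
            if ev_cross[a] == ev_cross[b]:
                n_ev = _compact4(ev_cross, ev_over, n_ev, a, b, -1, -1)
                changed = True
                break
        if changed:
            continue
        # R2
        for a in range(n_ev):
            b = a + 1 if a < n_ev - 1 else 0
            if ev_cross[a] == ev_cross[b] or ev_over[a] != ev_over[b]:
                continue
            ca = ev_cross[a]
            cb = ev_cross[b]
            pa = -1
            pb = -1
            for m in range(n_ev):
                if m != a and ev_cross[m] == ca:
                    pa = m
                if m != b and ev_cross[m] == cb:
                    pb = m
            nxt = pa + 1 if pa < n_ev - 1 else 0
            prv = pa - 1 if pa > 0 else n_ev - 1
            if pb == nxt or pb == prv:
                n_ev = _compact4(ev_cross, ev_over, n_ev, a, b, pa, pb)
                changed = True
                break
    return n_ev


# --------------------------------------------------------------------------
# Alexander determinant (float evaluation; exact path lives in _alexander.py)
# --------------------------------------------------------------------------

@njit(cache=True)
def _det_inplace(A):
    n = A.shape[0]
    if n == 0:
        return 1.0
    det = 1.0
    for k in range(n):
        p = k
        mx = abs(A[k, k])
        for i in range(k + 1, n):
            if abs(A[i, k]) > mx:
                mx = abs(A[i, k])
                p = i
        if mx == 0.0:
            return 0.0
        if p != k:
            for j in range(n):
                tmp = A[k, j]
                A[k, j] = A[p, j]
                A[p, j] = tmp
            det = -det
        det *= A[k, k]
        piv = A[k, k]
        for i in range(k + 1, n):
            f = A[i, k] / piv
            for j in range(k + 1, n):
                A[i, j] -= f * A[k, j]
            A[i, k] = 0.0
    return det


@njit(cache=True)
def alexander_det(ev_cross, ev_over, sign, n_ev, orig_c, t):
    """det of the Alexander presentation minor at parameter value ``t``.

    Rows come from the Wirtinger relations of the diagram, arcs delimited by
    underpasses; the last row and column are deleted.  The result equals
    +- t^a * Delta(t) for an unknown integer a, so only |value| at t = -1 is
    an invariant here (|(-1)^a| = 1); other t require the exact
    polynomial route.
    """
    n = n_ev // 2
    if n < 3:
        return 1.0
    row_of = np.full(orig_c, -1, np.int64)
    r = 0
    for m in range(n_ev):
        if ev_over[m] == 0:
            row_of[ev_cross[m]] = r
            r += 1
    pref = np.empty(n_ev, np.int64)
    cnum = 0
    for m in range(n_ev):
        pref[m] = cnum
        if ev_over[m] == 0:
            cnum += 1
    M = np.zeros((n, n))
    for m in range(n_ev):
        cid = ev_cross[m]
        rr = row_of[cid]
        if ev_over[m] == 0:
            ain = pref[m] % n
            aout = (pref[m] + 1) % n
            if sign[cid] > 0:
                M[rr, ain] += t
                M[rr, aout] += -1.0
            else:
                M[rr, ain] += 1.0
                M[rr, aout] += -t
        else:
            arc = pref[m] % n
            if sign[cid] > 0:
                M[rr, arc] += 1.0 - t
            else:
                M[rr, arc] += t - 1.0
    A = M[: n - 1, : n - 1].copy()
    return _det_inplace(A)


# --------------------------------------------------------------------------
# batch classification screen
# --------------------------------------------------------------------------

@njit(cache=True)
def diagram_once(P, d, tol, pos, over_first, sign, ev_cross, ev_over):
    """One projection attempt: crossings + ordered events (no reduction).

    Returns (status, n_crossings); status != 0 means degenerate.
    """
    st, c = project_crossings(P, d[0], d[1], d[2], tol, pos, over_first, sign)
    if st != 0:
        return 1, 0
    n_ev = sort_events(pos, c, over_first, tol, ev_cross, ev_over)
    if n_ev < 0:
        return 1, 0
    return 0, c


@njit(cache=True)
def screen_batch(coords, dirs, pool, max_redraws, tol,
                 out_d1, out_status, out_nred, out_redraws):
    """Classify a batch of conformations up to the unknot/nontrivial screen.

    For each conformation: draw its projection direction (redrawing from the
    shared ``pool`` on degeneracy), reduce the diagram, and evaluate the
    Alexander determinant |Delta(-1)| by float LU.  Status codes:
      0  resolved by the screen (out_d1 == 1 means unknot);
      1  nontrivial -- caller must run the exact signature path;
      2  redraw budget exhausted.
    """
    n = coords.shape[0]
    N = coords.shape[1]
    maxc = N * (N - 1) // 2
    pos = np.empty((maxc, 2))
    over_first = np.empty(maxc, np.uint8)
    sgn = np.empty(maxc, np.int8)
    ev_cross = np.empty(2 * maxc, np.int64)
    ev_over = np.empty(2 * maxc, np.uint8)
    psize = pool.shape[0]
    for q in range(n):
        P = coords[q]
        got = False
        used = 0
        c = 0
        n_ev = 0
        for r in range(max_redraws):
            if r == 0:
                ddx, ddy, ddz = dirs[q, 0], dirs[q, 1], dirs[q, 2]
            else:
                pi = (q + 131 * r) % psize
                ddx, ddy, ddz = pool[pi, 0], pool[pi, 1], pool[pi, 2]
            st, c = project_crossings(P, ddx, ddy, ddz, tol, pos, over_first, sgn)
            if st != 0:
                continue
            n_ev = sort_events(pos, c, over_first, tol, ev_cross, ev_over)
            if n_ev < 0:
                continue
            used = r
            got = True
            break
        if not got:
            out_status[q] = 2
            out_d1[q] = -1
            out_nred[q] = -1
            out_redraws[q] = max_redraws
            continue
        n_ev = reduce_events(ev_cross, ev_over, n_ev)
        out_redraws[q] = used
        nred = n_ev // 2
        out_nred[q] = nred
        if nred < 3:
            out_d1[q] = 1
            out_status[q] = 0
            continue
        dv = abs(alexander_det(ev_cross, ev_over, sgn, n_ev, c, -1.0))
        if dv > 1e12:
            out_d1[q] = -1
            out_status[q] = 1
            continue
        d1 = int(round(dv))
        out_d1[q] = d1
        out_status[q] = 0 if d1 == 1 else 1


# --------------------------------------------------------------------------
# writhe
# --------------------------------------------------------------------------

@njit(cache=True)
def _pair_omega(p1x, p1y, p1z, p2x, p2y, p2z,
                p3x, p3y, p3z, p4x, p4y, p4z):
    """Signed solid-angle contribution of one segment pair, over 2*pi.

    Returns (value, omega, ok): the signed contribution, the unsigned solid
    angle (2*pi signals an intersecting pair), and ok = False when an
    endpoint is collinear with the other segment (a spherical-quadrilateral
    vertex degenerates); the caller may retry with a perturbed endpoint.
    """
    r13x = p3x - p1x
    r13y = p3y - p1y
    r13z = p3z - p1z
    r14x = p4x - p1x
    r14y = p4y - p1y
    r14z = p4z - p1z
    r23x = p3x - p2x
    r23y = p3y - p2y
    r23z = p3z - p2z
    r24x = p4x - p2x
    r24y = p4y - p2y
    r24z = p4z - p2z
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x
    m1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    m2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    m3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    m4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if m1 < 1e-12 or m2 < 1e-12 or m3 < 1e-12 or m4 < 1e-12:
        return 0.0, 0.0, False
    a1 = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
    a2 = (n2x * n3x + n2y * n3y + n2z * n3z) / (m2 * m3)
    a3 = (n3x * n4x + n3y * n4y + n3z * n4z) / (m3 * m4)
    a4 = (n4x * n1x + n4y * n1y + n4z * n1z) / (m4 * m1)
    a1 = min(1.0, max(-1.0, a1))
    a2 = min(1.0, max(-1.0, a2))
    a3 = min(1.0, max(-1.0, a3))
    a4 = min(1.0, max(-1.0, a4))
    omega = np.arcsin(a1) + np.arcsin(a2) + np.arcsin(a3) + np.arcsin(a4)
    # sign from (r34 x r12) . r13
    r34x = p4x - p3x
    r34y = p4y - p3y
    r34z = p4z - p3z
    r12x = p2x - p1x
    r12y = p2y - p1y
    r12z = p2z - p1z
    cx = r34y * r12z - r34z * r12y
    cy = r34z * r12x - r34x * r12z
    cz = r34x * r12y - r34y * r12x
    dot = cx * r13x + cy * r13y + cz * r13z
    if dot > 0.0:
        return omega / (2.0 * np.pi), omega, True
    elif dot < 0.0:
        return -omega / (2.0 * np.pi), omega, True
    return 0.0, omega, True


@njit(cache=True)
def writhe_exact_one(P):
    """Closed-form Gauss double integral over non-adjacent segment pairs.

    Each pair contributes the signed solid angle of the quadrilateral spanned
    by the four endpoints (Klenin & Langowski method 1a).  Collinear
    degeneracies are resolved by a tiny deterministic endpoint perturbation
    (contribution error ~1e-7 of one pair, only on a measure-zero set).
    Returns (writhe, status); status 1 flags an intersecting segment pair
    for which the integral is undefined.
    """
    N = P.shape[0]
    wr = 0.0
    status = 0
    for i in range(N):
        i2 = i + 1 if i < N - 1 else 0
        for j in range(i + 2, N):
            if i == 0 and j == N - 1:
                continue
            j2 = j + 1 if j < N - 1 else 0
            v, om, ok = _pair_omega(P[i, 0], P[i, 1], P[i, 2],
                                    P[i2, 0], P[i2, 1], P[i2, 2],
                                    P[j, 0], P[j, 1], P[j, 2],
                                    P[j2, 0], P[j2, 1], P[j2, 2])
            if not ok:
                # collinear degeneracy: perturb both endpoints of the first
                # segment by a fixed tiny vector and retry
                e = 1e-9
                v, om, ok = _pair_omega(P[i, 0] + e, P[i, 1] + 1.3 * e,
                                        P[i, 2] + 0.7 * e,
                                        P[i2, 0] + e, P[i2, 1] + 1.3 * e,
                                        P[i2, 2] + 0.7 * e,
                                        P[j, 0], P[j, 1], P[j, 2],
                                        P[j2, 0], P[j2, 1], P[j2, 2])
                if not ok:
                    status = 1
                    continue
            if om > 2.0 * np.pi - 1e-6:
                # the full solid angle: the two segments intersect
                status = 1
                continue
            wr += v
    return wr, status


@njit(cache=True)
def writhe_exact_batch(coords, out):
    status = 0
    for q in range(coords.shape[0]):
        w, st = writhe_exact_one(coords[q])
        out[q] = w
        if st != 0:
            status = 1
    return status


@njit(cache=True)
def writhe_projection_dirs(P, dirs, tol, out_vals, out_ok):
    """Signed crossing sum of the projection along each direction."""
    N = P.shape[0]
    maxc = N * (N - 1) // 2
    pos = np.empty((maxc, 2))
    over_first = np.empty(maxc, np.uint8)
    sgn = np.empty(maxc, np.int8)
    for m in range(dirs.shape[0]):
        st, c = project_crossings(P, dirs[m, 0], dirs[m, 1], dirs[m, 2],
                                  tol, pos, over_first, sgn)
        if st != 0:
            out_ok[m] = 0
            out_vals[m] = 0.0
            continue
        s = 0.0
        for k in range(c):
            s += sgn[k]
        out_vals[m] = s
        out_ok[m] = 1
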