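"""Exact Alexander polynomial of a crossing diagram, in integer arithmetic.

The Wirtinger presentation of a diagram with n crossings gives an n x n
matrix over Z[t] whose (n-1) minor determinant equals +-t^a * Delta(t) for
an unknown shift a.  Evaluating the determinant at a single t therefore only
yields an invariant at t = -1.  To obtain |Delta| at other arguments we
reconstruct the full determinant polynomial exactly -- integer Bareiss
determinants at deg+1 integer points followed by exact Lagrange
interpolation -- strip the t^a unit, and check the Alexander symmetry
Delta(t) = t^deg Delta(1/t) plus |Delta(1)| = 1 as internal consistency
guards.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def bareiss_det(M):
    """Exact determinant of a square integer matrix (list of lists)."""
    n = len(M)
    if n == 0:
        return 1
    A = [row[:] for row in M]
    sign = 1
    denom = 1
    for k in range(n - 1):
        if A[k][k] == 0:
            p = -1
            for i in range(k + 1, n):
                if A[i][k] != 0:
                    p = i
                    break
            if p < 0:
                return 0
            A[k], A[p] = A[p], A[k]
            sign = -sign
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                A[i][j] = (A[i][j] * A[k][k] - A[i][k] * A[k][j]) // denom
        denom = A[k][k]
    return sign * A[n - 1][n - 1]


def _interp_integer_poly(ts, vs):
    """Integer coefficients (ascending) of the poly through (ts, vs)."""
    n = len(ts)
    coeffs = [Fraction(0)] * n
    for k in range(n):
        # Lagrange basis polynomial for node k
        num = [Fraction(1)]
        den = Fraction(1)
        for m in range(n):
            if m == k:
                continue
            # multiply num by (t - ts[m])
            new = [Fraction(0)] * (len(num) + 1)
            for d, c in enumerate(num):
                new[d] += c * (-ts[m])
                new[d + 1] += c
            num = new
            den *= ts[k] - ts[m]
        w = Fraction(vs[k]) / den
        for d, c in enumerate(num):
            coeffs[d] += w * c
    out = []
    for c in coeffs:
        if c.denominator != 1:
            return None
        out.append(int(c))
    return out


def wirtinger_matrices(ev_cross, ev_over, sign, orig_c):
    """Constant and t-linear parts (C0, C1) of the Wirtinger Alexander matrix.

    Arcs are delimited by underpasses; rows follow the Fox-derivative
    relations (positive crossing: over arc 1-t, incoming under arc t,
    outgoing under arc -1; negative crossing scaled by t).
    """
    n_ev = len(ev_cross)
    n = n_ev // 2
    row_of = [-1] * orig_c
    r = 0
    for m in range(n_ev):
        if ev_over[m] == 0:
            row_of[ev_cross[m]] = r
            r += 1
    pref = [0] * n_ev
    cnum = 0
    for m in range(n_ev):
        pref[m] = cnum
        if ev_over[m] == 0:
            cnum += 1
    C0 = [[0] * n for _ in range(n)]
    C1 = [[0] * n for _ in range(n)]
    for m in range(n_ev):
        cid = ev_cross[m]
        rr = row_of[cid]
        if ev_over[m] == 0:
            ain = pref[m] % n
            aout = (pref[m] + 1) % n
            if sign[cid] > 0:
                C1[rr][ain] += 1
                C0[rr][aout] += -1
            else:
                C0[rr][ain] += 1
                C1[rr][aout] += -1
        else:
            arc = pref[m] % n
            if sign[cid] > 0:
                C0[rr][arc] += 1
                C1[rr][arc] += -1
            else:
                C0[rr][arc] += -1
                C1[rr][arc] += 1
    return C0, C1


def exact_signature(ev_cross, ev_over, sign, orig_c):
    """(|Delta(-1)|, |Delta(-2)|) of a reduced diagram, or None on failure.

    None signals an internally inconsistent determinant (failed symmetry or
    |Delta(1)| != 1); callers should treat it as an unresolvable diagram.
    """
    n = len(ev_cross) // 2
    if n < 3:
        return (1, 1)
    C0, C1 = wirtinger_matrices(ev_cross, ev_over, sign, orig_c)
    size = n - 1
    # determinant polynomial has degree <= size; sample size+1 points
    ts = []
    v = 1
    while len(ts) < size + 1:
        ts.append(v)
        if len(ts) < size + 1:
            ts.append(-v)
        v += 1
    vs = []
    for tv in ts:
        M = [[C0[i][j] + C1[i][j] * tv for j in range(size)]
             for i in range(size)]
        vs.append(bareiss_det(M))
    coeffs = _interp_integer_poly(ts, vs)
    if coeffs is None:
        return None
    # strip the t^a unit factor
    lo = 0
    while lo < len(coeffs) and coeffs[lo] == 0:
        lo += 1
    if lo == len(coeffs):
        return None  # determinant identically zero: not a knot diagram
    poly = coeffs[lo:]
    while poly and poly[-1] == 0:
        poly.pop()
    # Alexander symmetry and Delta(1) = +-1
    if poly != poly[::-1]:
        return None
    if abs(sum(poly)) != 1:
        return None
    d1 = abs(sum(c * (-1) ** k for k, c in enumerate(poly)))
    d2 = abs(sum(c * (-2) ** k for k, c in enumerate(poly)))
    return (d1, d2)
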