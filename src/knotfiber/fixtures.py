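"""Closed polygonal curves of known knot type, for tests and calibration.

Torus knots and the figure-eight come from their standard parametric curves;
twist and composite knots are built as polygonal braid closures from braid
words taken from the standard knot tables.  Every shipped word was verified
against the reduced-Burau Alexander polynomial before being frozen here.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

from .errors import InvalidParametersError

__all__ = ["make_fixture", "braid_closure_curve", "FIXTURE_KNOTS"]

#: fixture kind -> expected knot label
FIXTURE_KNOTS: Dict[str, str] = {
    "planar": "0_1",
    "torus_2_3": "3_1",
    "torus_2_5": "5_1",
    "torus_2_7": "7_1",
    "figure_eight": "4_1",
    "5_2": "5_2",
    "6_1": "6_1",
    "granny": "3_1#3_1",
}

# braid words on s strands (generator i = sigma_i, negative = inverse)
_BRAID_WORDS: Dict[str, Tuple[Tuple[int, ...], int]] = {
    "5_2": ((1, 1, 1, 2, -1, 2), 3),
    "6_1": ((1, 1, 2, -1, -3, 2, -3), 4),
    "granny": ((1, 1, 1, 2, 2, 2), 3),
}

_MIN_VERTICES = {
    "planar": 3,
    "torus_2_3": 24,
    "torus_2_5": 40,
    "torus_2_7": 56,
    "figure_eight": 40,
}


def _torus_curve(q: int, n: int) -> np.ndarray:
    """(2, q) torus knot on the standard torus (major radius 2, minor 1)."""
    t = 2.0 * math.pi * np.arange(n) / n
    r = 2.0 + np.cos(q * t)
    return np.column_stack([r * np.cos(2 * t), r * np.sin(2 * t),
                            np.sin(q * t)])


def _figure_eight_curve(n: int) -> np.ndarray:
    t = 2.0 * math.pi * np.arange(n) / n
    r = 2.0 + np.cos(2 * t)
    return np.column_stack([r * np.cos(3 * t), r * np.sin(3 * t),
                            np.sin(4 * t)])


def braid_closure_curve(word, n_strands: int) -> np.ndarray:
    """Polygonal closure of a braid word.

    Strands run down parallel vertical lines; each braid letter swaps two
    adjacent strands through a midpoint displaced out of the braid plane,
    the sign of the displacement encoding which strand passes in front.
    The closure returns each endpoint to its column around the outside of
    the braid at a distinct offset.  The result is a closed polygon whose
    knot type is the braid closure (the word's permutation must be a single
    cycle).
    """
    word = list(word)
    s = n_strands
    # permutation check: closure must be a single component
    perm = list(range(s))
    for g in word:
        i = abs(g) - 1
        if not (1 <= abs(g) <= s - 1):
            raise InvalidParametersError(f"generator {g} outside braid group B_{s}")
        perm[i], perm[i + 1] = perm[i + 1], perm[i]
    seen = {0}
    j = perm[0]
    while j != 0:
        seen.add(j)
        j = perm[j]
    if len(seen) != s:
        raise InvalidParametersError("braid closure is a link, not a knot")

    m = len(word)
    h = 0.4  # out-of-plane displacement at a crossing
    # paths[k] = vertex list of the strand starting at column k (top)
    paths: List[List[Tuple[float, float, float]]] = [
        [(float(k), 0.0, 0.0)] for k in range(s)]
    col_of = list(range(s))        # strand index occupying each column
    for step, g in enumerate(word):
        i = abs(g) - 1
        z_mid = -(step + 0.5)
        z_end = -(step + 1.0)
        sa, sb = col_of[i], col_of[i + 1]
        ya = h if g > 0 else -h    # strand moving right passes in front iff g>0
        paths[sa].append((i + 0.5, ya, z_mid))
        paths[sa].append((i + 1.0, 0.0, z_end))
        paths[sb].append((i + 0.5, -ya, z_mid))
        paths[sb].append((i + 0.0, 0.0, z_end))
        col_of[i], col_of[i + 1] = sb, sa
        for c in range(s):
            if c != i and c != i + 1:
                paths[col_of[c]].append((float(c), 0.0, z_end))
    # closure: the strand ending at the bottom of column c is joined to the
    # strand starting at the top of column c by one arc routed around the
    # outside of the braid in the plane x = c, at a column-specific offset
    # y = 2 + 0.7 c so closure arcs never meet each other or the braid body.
    z_bot = -float(m)
    curve: List[Tuple[float, float, float]] = []
    k = 0
    while True:
        curve.extend(paths[k])              # ends at (end_col, 0, z_bot)
        end_col = col_of.index(k)
        y_out = 2.0 + 0.7 * end_col
        curve.append((float(end_col), y_out, z_bot - 1.0))
        curve.append((float(end_col), y_out, 1.0))
        if end_col == 0:
            break                           # ring closes back to (0, 0, 0)
        k = end_col                         # descend into that column's start
    arr = np.array(curve, dtype=float)
    # drop consecutive duplicates
    keep = [0]
    for i in range(1, len(arr)):
        if np.linalg.norm(arr[i] - arr[keep[-1]]) > 1e-12:
            keep.append(i)
    if np.linalg.norm(arr[keep[-1]] - arr[keep[0]]) < 1e-12:
        keep.pop()
    arr = arr[keep]
    # the construction reuses exact straight lines (strands share columns),
    # which makes every projection degenerate; a deterministic jitter far
    # below the strand separation (0.4) breaks the coincidences without
    # changing the knot type
    jitter = np.random.default_rng(20190605).uniform(-0.02, 0.02, arr.shape)
    return arr + jitter


def make_fixture(kind: str, n_vertices: int = 60) -> np.ndarray:
    """Closed polygonal curve of the named knot type.

    Parametric kinds honour ``n_vertices``; braid-closure kinds use their
    fixed construction.  Raises if ``n_vertices`` is too small to preserve
    the knot type.
    """
    if kind == "planar":
        if n_vertices < 3:
            raise InvalidParametersError("planar polygon needs >= 3 vertices")
        t = 2.0 * math.pi * np.arange(n_vertices) / n_vertices
        return np.column_stack([np.cos(t), np.sin(t), np.zeros(n_vertices)])
    if kind in ("torus_2_3", "torus_2_5", "torus_2_7", "figure_eight"):
        if n_vertices < _MIN_VERTICES[kind]:
            raise InvalidParametersError(
                f"{kind} needs >= {_MIN_VERTICES[kind]} vertices")
        if kind == "figure_eight":
            return _figure_eight_curve(n_vertices)
        q = int(kind.rsplit("_", 1)[1])
        return _torus_curve(q, n_vertices)
    if kind in _BRAID_WORDS:
        word, s = _BRAID_WORDS[kind]
        return braid_closure_curve(word, s)
    raise InvalidParametersError(
        f"unknown fixture kind {kind!r}; options: {sorted(FIXTURE_KNOTS)}")
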