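"""Knot-type identification of closed polygonal curves.

A conformation is projected along a generic random direction to a planar
crossing diagram (redrawing the direction on any degeneracy), the diagram is
simplified by Reidemeister I/II reduction, and the knot is identified by the
pair of Alexander determinants (|Delta(-1)|, |Delta(-2)|) looked up in a
table of prime knots through 8 crossings plus the trefoil-factor composites
3_1#3_1 and 3_1#4_1.  The pair separates every entry of the shipped table;
chirality is not distinguished (the Alexander polynomial cannot see it).
Signatures outside the table are labelled "unresolved" and count as knotted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from ._alexander import exact_signature
from ._kernels import GEOM_TOL
from .errors import ClassificationError, DegenerateProjectionError
from .ring_model import Ensemble, _as_coords

__all__ = [
    "CrossingDiagram",
    "KnotType",
    "InvariantSignature",
    "ALEXANDER_COEFFS",
    "SIGNATURE_TABLE",
    "project_diagram",
    "reduce_diagram",
    "alexander_signature",
    "classify",
    "classify_batch",
    "classify_ensemble",
]

DEFAULT_MAX_REDRAWS = 32
_POOL_SIZE = 8192

# Alexander polynomial coefficients (ascending, symmetric) of prime knots
# through 8 crossings and the shipped composites.  8_20 and 8_21 are omitted:
# their Alexander polynomials coincide identically with 3_1#3_1 and 3_1#4_1,
# so the signature maps those determinant pairs to the composite labels.
ALEXANDER_COEFFS = {
    "3_1": [1, -1, 1],
    "4_1": [1, -3, 1],
    "5_1": [1, -1, 1, -1, 1],
    "5_2": [2, -3, 2],
    "6_1": [2, -5, 2],
    "6_2": [1, -3, 3, -3, 1],
    "6_3": [1, -3, 5, -3, 1],
    "7_1": [1, -1, 1, -1, 1, -1, 1],
    "7_2": [3, -5, 3],
    "7_3": [2, -3, 3, -3, 2],
    "7_4": [4, -7, 4],
    "7_5": [2, -4, 5, -4, 2],
    "7_6": [1, -5, 7, -5, 1],
    "7_7": [1, -5, 9, -5, 1],
    "8_1": [3, -7, 3],
    "8_2": [1, -3, 3, -3, 3, -3, 1],
    "8_3": [4, -9, 4],
    "8_4": [2, -5, 5, -5, 2],
    "8_5": [1, -3, 4, -5, 4, -3, 1],
    "8_6": [2, -6, 7, -6, 2],
    "8_7": [1, -3, 5, -5, 5, -3, 1],
    "8_8": [2, -6, 9, -6, 2],
    "8_9": [1, -3, 5, -7, 5, -3, 1],
    "8_10": [1, -3, 6, -7, 6, -3, 1],
    "8_11": [2, -7, 9, -7, 2],
    "8_12": [1, -7, 13, -7, 1],
    "8_13": [2, -7, 11, -7, 2],
    "8_14": [2, -8, 11, -8, 2],
    "8_15": [3, -8, 11, -8, 3],
    "8_16": [1, -4, 8, -9, 8, -4, 1],
    "8_17": [1, -4, 8, -11, 8, -4, 1],
    "8_18": [1, -5, 10, -13, 10, -5, 1],
    "8_19": [1, -1, 0, 1, 0, -1, 1],
    "3_1#3_1": [1, -2, 3, -2, 1],
    "3_1#4_1": [1, -4, 5, -4, 1],
}


def _crossing_number(label: str) -> int:
    if label == "0_1":
        return 0
    return sum(int(f.split("_")[0]) for f in label.split("#"))


def _eval(coeffs, t):
    return sum(c * t ** k for k, c in enumerate(coeffs))


def _build_signature_table():
    table = {(1, 1): "0_1"}
    for label, coeffs in ALEXANDER_COEFFS.items():
        key = (abs(_eval(coeffs, -1)), abs(_eval(coeffs, -2)))
        if key in table:
            raise RuntimeError(f"signature collision in table: {key}")
        table[key] = label
    return table


#: (|Delta(-1)|, |Delta(-2)|) -> knot label
SIGNATURE_TABLE = _build_signature_table()


@dataclass(frozen=True)
class InvariantSignature:
    """Knot determinant |Delta(-1)| and the companion value |Delta(-2)|."""

    d1: int
    d2: int

    def as_tuple(self) -> Tuple[int, int]:
        return (self.d1, self.d2)


@dataclass(frozen=True)
class KnotType:
    """Knot identity: table label, minimal crossing number, signature."""

    label: str
    crossing_number: int
    signature: Optional[InvariantSignature] = None
    n_redraws: int = 0

    @property
    def is_knotted(self) -> bool:
        return self.label != "0_1"


@dataclass(frozen=True)
class CrossingDiagram:
    """Planar crossing diagram read off one projection of a closed curve.

    ``events`` lists the 2c passages in order along the oriented curve as
    (crossing id, over flag); ``signs`` holds the right-hand-rule sign of
    each crossing, indexed by crossing id.  Crossing ids of a reduced
    diagram keep their original numbering.
    """

    events: Tuple[Tuple[int, int], ...]
    signs: Tuple[int, ...]

    @property
    def crossing_count(self) -> int:
        return len(self.events) // 2

    def dt_code(self) -> Tuple[int, ...]:
        """Dowker-Thistlethwaite code.

        Passages are numbered 1..2c along the curve; the code lists, for
        each odd label in order, the even label paired with it at the same
        crossing, negated when the even passage is an overpass.
        """
        first_visit = {}
        pairs = []
        for idx, (cid, over) in enumerate(self.events):
            lab = idx + 1
            if cid in first_visit:
                pairs.append((first_visit[cid], (lab, over)))
            else:
                first_visit[cid] = (lab, over)
        code = []
        for (la, ova), (lb, ovb) in pairs:
            odd, even = ((la, lb) if la % 2 == 1 else (lb, la))
            even_over = ovb if even == lb else ova
            code.append((odd, -even if even_over else even))
        code.sort()
        return tuple(e for _, e in code)


def _scratch(n_vertices: int):
    maxc = n_vertices * (n_vertices - 1) // 2
    return (np.empty((maxc, 2)), np.empty(maxc, np.uint8),
            np.empty(maxc, np.int8), np.empty(2 * maxc, np.int64),
            np.empty(2 * maxc, np.uint8))


def project_diagram(conf, direction) -> CrossingDiagram:
    """Extract the crossing diagram of the projection along ``direction``.

    Raises DegenerateProjectionError for non-generic directions (segment
    parallel to the direction, vertex or tangential intersection, equal
    depths, or two crossings closer than the tolerance along the curve);
    the caller should redraw the direction.
    """
    P = _as_coords(conf)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pos, over_first, sgn, ev_cross, ev_over = _scratch(P.shape[0])
    st, c = _kernels.diagram_once(P, d, GEOM_TOL, pos, over_first, sgn,
                                  ev_cross, ev_over)
    if st != 0:
        raise DegenerateProjectionError(
            "degenerate projection; redraw the direction")
    events = tuple((int(ev_cross[m]), int(ev_over[m])) for m in range(2 * c))
    signs = tuple(int(sgn[k]) for k in range(c))
    return CrossingDiagram(events=events, signs=signs)


def reduce_diagram(diag: CrossingDiagram) -> CrossingDiagram:
    """Remove R-I kinks and cancellable R-II pairs until a fixed point."""
    n_ev = len(diag.events)
    ev_cross = np.array([e[0] for e in diag.events], dtype=np.int64)
    ev_over = np.array([e[1] for e in diag.events], dtype=np.uint8)
    if n_ev == 0:
        return diag
    n_ev = int(_kernels.reduce_events(ev_cross, ev_over, n_ev))
    events = tuple((int(ev_cross[m]), int(ev_over[m])) for m in range(n_ev))
    return CrossingDiagram(events=events, signs=diag.signs)


def alexander_signature(diag: CrossingDiagram) -> InvariantSignature:
    """Integer-exact (|Delta(-1)|, |Delta(-2)|) of the diagram's knot."""
    if len(diag.events) == 0:
        return InvariantSignature(1, 1)
    ev_cross = [e[0] for e in diag.events]
    ev_over = [e[1] for e in diag.events]
    orig_c = max(ev_cross) + 1
    sig = exact_signature(ev_cross, ev_over, list(diag.signs), orig_c)
    if sig is None:
        raise ClassificationError("inconsistent Alexander determinant")
    return InvariantSignature(*sig)


def _lookup(sig: Tuple[int, int], n_redraws: int) -> KnotType:
    label = SIGNATURE_TABLE.get(sig)
    if label is None:
        return KnotType(label="unresolved", crossing_number=-1,
                        signature=InvariantSignature(*sig),
                        n_redraws=n_redraws)
    return KnotType(label=label, crossing_number=_crossing_number(label),
                    signature=InvariantSignature(*sig), n_redraws=n_redraws)


def classify(conf, max_redraws: int = DEFAULT_MAX_REDRAWS,
             seed: int = 0) -> KnotType:
    """Knot type of one closed polygonal curve.

    Draws uniformly random projection directions (redrawing on degeneracy up
    to ``max_redraws``), reduces the diagram, computes the exact invariant
    signature and looks it up.  Deterministic given ``seed``.
    """
    P = _as_coords(conf)
    rng = np.random.default_rng(seed)
    for attempt in range(max_redraws):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        try:
            diag = project_diagram(P, d)
        except DegenerateProjectionError:
            continue
        red = reduce_diagram(diag)
        if red.crossing_count < 3:
            return KnotType(label="0_1", crossing_number=0,
                            signature=InvariantSignature(1, 1),
                            n_redraws=attempt)
        try:
            sig = alexander_signature(red)
        except ClassificationError:
            continue
        return _lookup(sig.as_tuple(), attempt)
    raise ClassificationError(
        f"no generic projection found in {max_redraws} attempts")


def _direction_pool(rng: np.random.Generator, size: int) -> np.ndarray:
    d = rng.standard_normal((size, 3))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def classify_batch(coords: np.ndarray, seed: int = 0,
                   max_redraws: int = DEFAULT_MAX_REDRAWS):
    """Classify an (n, N, 3) batch of ring conformations.

    Fast path: a compiled screen reduces each conformation's diagram and
    evaluates |Delta(-1)| in floating point; conformations with |Delta(-1)|
    = 1 are unknots.  Every nontrivial (or numerically overflowing) case is
    re-derived through the exact integer signature path.  Returns
    (labels, d1, d2, n_redraws) arrays.
    """
    coords = np.ascontiguousarray(np.asarray(coords, dtype=float))
    n, N = coords.shape[0], coords.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dirs = _direction_pool(rng, n)
    pool = _direction_pool(rng, _POOL_SIZE)
    d1_arr = np.empty(n, np.int64)
    status = np.empty(n, np.int64)
    nred = np.empty(n, np.int64)
    redraws = np.empty(n, np.int64)
    _kernels.screen_batch(coords, dirs, pool, max_redraws, GEOM_TOL,
                          d1_arr, status, nred, redraws)

    labels = np.empty(n, dtype=object)
    d1_out = np.zeros(n, np.int64)
    d2_out = np.zeros(n, np.int64)
    labels[:] = "0_1"
    d1_out[status == 0] = 1
    d2_out[status == 0] = 1

    pos, over_first, sgn, ev_cross, ev_over = _scratch(N)
    for q in np.nonzero(status != 0)[0]:
        if status[q] == 2:
            raise ClassificationError(
                f"conformation {q}: no generic projection in {max_redraws} draws")
        kt = None
        for attempt in range(max_redraws):
            pi = (int(q) + 131 * (redraws[q] + attempt)) % _POOL_SIZE
            d = dirs[q] if (redraws[q] + attempt) == 0 else pool[pi]
            st, c = _kernels.diagram_once(coords[q], d, GEOM_TOL, pos,
                                          over_first, sgn, ev_cross, ev_over)
            if st != 0:
                continue
            n_ev = int(_kernels.reduce_events(ev_cross, ev_over, 2 * c))
            if n_ev < 6:
                kt = KnotType("0_1", 0, InvariantSignature(1, 1), attempt)
                break
            sig = exact_signature([int(v) for v in ev_cross[:n_ev]],
                                  [int(v) for v in ev_over[:n_ev]],
                                  [int(v) for v in sgn[:c]], c)
            if sig is None:
                continue
            kt = _lookup(sig, attempt)
            break
        if kt is None:
            raise ClassificationError(
                f"conformation {q}: no consistent diagram in {max_redraws} draws")
        labels[q] = kt.label
        if kt.signature is not None:
            d1_out[q] = kt.signature.d1
            d2_out[q] = kt.signature.d2
    return labels, d1_out, d2_out, redraws


def classify_ensemble(ensemble: Ensemble, seed: int = 0,
                      max_redraws: int = DEFAULT_MAX_REDRAWS) -> Ensemble:
    """Annotate an Ensemble in place with knot labels and signatures."""
    labels, d1, d2, _ = classify_batch(ensemble.coords, seed=seed,
                                       max_redraws=max_redraws)
    ensemble.knot_labels = labels
    ensemble.knot_d1 = d1
    ensemble.knot_d2 = d2
    return ensemble
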