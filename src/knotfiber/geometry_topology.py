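"""Writhe of closed polygonal curves.

Two routes are provided: the projection-averaging estimator (mean signed
crossing number over uniformly random viewing directions) and the exact
closed-form Gauss double integral over segment pairs.  The exact method is
noise-free and cheap at small N, so it is the default for ensemble
annotation; the projection method mirrors how writhe is defined and serves
as the stochastic cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import GEOM_TOL
from .errors import UndefinedWritheError
from .ring_model import Ensemble, _as_coords

__all__ = ["WritheEstimate", "writhe_projection", "writhe_exact",
           "annotate_writhe"]

DEFAULT_N_PROJECTIONS = 300


@dataclass(frozen=True)
class WritheEstimate:
    """Projection-average writhe with its Monte Carlo standard error."""

    value: float
    n_projections: int
    standard_error: float

    @property
    def abs_value(self) -> float:
        return abs(self.value)


def writhe_projection(conf, n_projections: int = DEFAULT_N_PROJECTIONS,
                      seed: int = 0) -> WritheEstimate:
    """Mean signed crossing sum over uniformly random projection directions.

    Degenerate directions are redrawn (the estimator stays unbiased: the
    degenerate set has measure zero).  Reproducible from ``seed``.
    """
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    P = _as_coords(conf)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_projections)
    got = 0
    while got < n_projections:
        want = n_projections - got
        d = rng.standard_normal((want, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        out = np.empty(want)
        ok = np.empty(want, np.uint8)
        _kernels.writhe_projection_dirs(P, d, GEOM_TOL, out, ok)
        good = ok == 1
        n_good = int(good.sum())
        vals[got:got + n_good] = out[good]
        got += n_good
    se = float(vals.std(ddof=1) / np.sqrt(n_projections)) \
        if n_projections > 1 else float("inf")
    return WritheEstimate(value=float(vals.mean()),
                          n_projections=n_projections, standard_error=se)


def writhe_exact(conf) -> float:
    """Exact writhe: Gauss-integral contribution summed over segment pairs.

    Deterministic and scale invariant; raises UndefinedWritheError if two
    non-adjacent segments intersect (the integral diverges there).
    """
    P = _as_coords(conf)
    wr, status = _kernels.writhe_exact_one(P)
    if status != 0:
        raise UndefinedWritheError(
            "intersecting (or degenerately coplanar) segment pair")
    return float(wr)


def annotate_writhe(ensemble: Ensemble) -> Ensemble:
    """Annotate an Ensemble in place with exact per-conformation writhe."""
    out = np.empty(ensemble.n)
    status = _kernels.writhe_exact_batch(ensemble.coords, out)
    if status != 0:
        raise UndefinedWritheError(
            "ensemble contains a conformation with intersecting segments")
    ensemble.writhe = out
    return ensemble
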