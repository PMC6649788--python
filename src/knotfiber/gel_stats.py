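"""Synthetic gel-quantification tables and the knotting-probability
estimators used on them.

Two-dimensional gels of nicked minichromosome DNA resolve the unknotted
circle from knotted circles band-by-band (one band per irreducible crossing
number), while a separate native gel yields the fraction of molecules that
are positively supercoiled.  This module generates count tables with exactly
that statistical structure -- each molecule is (+)S with probability f_S,
knotted with the conditional probability of its supercoiling state, and
assigned a knot class from a fixed spectrum -- and implements the
estimators: total P_kn, the conditional P_kn inside the (+)S fraction, and
per-class fold enhancements between two conditions.

The conditional estimator inverts the total-probability decomposition

    P_total = basal * (1 - f_S) + P_cond * f_S,

attributing basal knotting to the non-supercoiled fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .compaction_analysis import KnotProbability
from .errors import InvalidParametersError, UndefinedConditionalError

__all__ = [
    "GelSimParams",
    "GelKnotTable",
    "FoldChange",
    "simulate_gel_table",
    "pkn_from_table",
    "conditional_pkn",
    "enhancement_between",
]

KN_CLASSES = (3, 4, 5, 6, 7, 8)


def _default_f_s(times):
    """Saturating accumulation of (+)S molecules after topo II loss."""
    return tuple(float(1.0 - np.exp(-t / 35.0)) for t in times)


def _default_spectrum():
    # trefoil-dominated, geometrically decreasing with crossing number
    w = np.array([0.4 ** (k - 3) for k in KN_CLASSES])
    return tuple(w / w.sum())


@dataclass(frozen=True)
class GelSimParams:
    """Generating parameters of the synthetic gel time course.

    ``basal_pkn`` is the knotting probability of torsionally relaxed
    chromatin, ``conditional_pkn`` that of positively supercoiled chromatin;
    ``f_s`` gives the (+)S molecule fraction at each sampled time point
    (minutes after inducing topoisomerase II inactivation).
    """

    basal_pkn: float = 0.02
    conditional_pkn: float = 0.5
    times_min: Tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
    f_s: Optional[Tuple[float, ...]] = None
    spectrum: Tuple[float, ...] = field(default_factory=_default_spectrum)
    n_molecules: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.basal_pkn <= 1.0 and
                0.0 <= self.conditional_pkn <= 1.0):
            raise InvalidParametersError("probabilities must lie in [0, 1]")
        if self.n_molecules <= 0:
            raise InvalidParametersError("n_molecules must be positive")
        fs = self.f_s if self.f_s is not None else _default_f_s(self.times_min)
        fs = tuple(float(f) for f in fs)
        if len(fs) != len(self.times_min):
            raise InvalidParametersError("f_s must match times_min in length")
        if any(f < 0 or f > 1 for f in fs):
            raise InvalidParametersError("f_s values must lie in [0, 1]")
        object.__setattr__(self, "f_s", fs)
        w = np.asarray(self.spectrum, dtype=float)
        if len(w) != len(KN_CLASSES) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise InvalidParametersError(
                "spectrum must be 6 non-negative weights summing to 1")
        object.__setattr__(self, "spectrum", tuple(float(x) for x in w))


@dataclass(frozen=True)
class GelKnotTable:
    """Band counts of one gel lane plus the measured (+)S fraction."""

    condition: str
    replicate: int
    n_nicked_unknotted: int
    knotted_by_class: Dict[int, int]       # Kn# 3..8 -> count
    f_positive_supercoiled: float

    @property
    def n_knotted(self) -> int:
        return sum(self.knotted_by_class.values())

    @property
    def n_total(self) -> int:
        return self.n_nicked_unknotted + self.n_knotted

    def class_probability(self, kn_class: int) -> float:
        if self.n_total == 0:
            raise InvalidParametersError("empty table")
        return self.knotted_by_class.get(kn_class, 0) / self.n_total


def simulate_gel_table(params: GelSimParams,
                       replicate: int = 0) -> List[GelKnotTable]:
    """One synthetic time course of gel count tables.

    Per time point: each of ``n_molecules`` is (+)S with probability
    f_S(t); a molecule is knotted with ``conditional_pkn`` if (+)S, else
    ``basal_pkn``; knot classes follow the multinomial ``spectrum``.
    Reproducible from ``params.seed`` and ``replicate``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(params.seed).spawn(replicate + 1)[replicate])
    out = []
    n = params.n_molecules
    for t, fs in zip(params.times_min, params.f_s):
        n_s = rng.binomial(n, fs)
        n_knot = (rng.binomial(n_s, params.conditional_pkn)
                  + rng.binomial(n - n_s, params.basal_pkn))
        class_counts = rng.multinomial(n_knot, params.spectrum)
        out.append(GelKnotTable(
            condition=f"{t:g}min", replicate=replicate,
            n_nicked_unknotted=int(n - n_knot),
            knotted_by_class={k: int(c) for k, c
                              in zip(KN_CLASSES, class_counts)},
            f_positive_supercoiled=float(n_s / n)))
    return out


def pkn_from_table(table: GelKnotTable) -> KnotProbability:
    """Total knotted fraction of the nicked circles, with Wilson CI."""
    if table.n_total == 0:
        raise InvalidParametersError("empty gel table")
    return KnotProbability.from_counts(table.n_knotted, table.n_total)


def conditional_pkn(table: GelKnotTable, basal_pkn: float) -> float:
    """Knotting probability inside the (+)S molecule fraction.

    P_cond = (P_total - basal * (1 - f_S)) / f_S, clipped to [0, 1]; with
    basal ~ 0 this is the knotted excess divided by the (+)S fraction.
    """
    f = table.f_positive_supercoiled
    if f <= 0:
        raise UndefinedConditionalError(
            "conditional P_kn undefined with zero (+)S fraction")
    p_total = table.n_knotted / table.n_total
    return float(np.clip((p_total - basal_pkn * (1.0 - f)) / f, 0.0, 1.0))


@dataclass(frozen=True)
class FoldChange:
    """Per-class probability ratio; lower-bound flag when the baseline
    count was zero and a continuity correction (0.5 counts) was applied."""

    value: float
    is_lower_bound: bool = False


def enhancement_between(table_a: GelKnotTable, table_b: GelKnotTable,
                        kn_class: int) -> FoldChange:
    """Fold change of one knot class from condition a to condition b."""
    if table_a.n_total == 0 or table_b.n_total == 0:
        raise InvalidParametersError("empty gel table")
    ca = table_a.knotted_by_class.get(kn_class, 0)
    pb = table_b.class_probability(kn_class)
    if ca == 0:
        pa = 0.5 / table_a.n_total
        return FoldChange(value=float(pb / pa), is_lower_bound=True)
    pa = ca / table_a.n_total
    return FoldChange(value=float(pb / pa), is_lower_bound=False)
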