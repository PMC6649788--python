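"""Knot probability, D/L calibration and gyration-radius conditioning.

This is the analysis stage of the pipeline: given annotated ring ensembles
it computes the knotting probability P_kn, calibrates the bead-diameter /
linker-length ratio against a target P_kn, and quantifies how conditioning
on chain compaction (keeping only conformations whose radius of gyration
falls below a cutoff fraction of the ensemble RMS value Rg0) enriches knots
overall and per knot class, and how compaction correlates with writhe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    ExtrapolationError,
    InvalidParametersError,
    NonMonotoneTableError,
)
from .geometry_topology import annotate_writhe
from .knot_id import classify_ensemble
from .ring_model import Ensemble, ModelParams, sample_ensemble

__all__ = [
    "KnotProbability",
    "knot_probability",
    "pkn_vs_ratio",
    "calibrate_dl",
    "compaction_profile",
    "cutoff_at_conditional_pkn",
    "writhe_rg_table",
    "knot_spectrum",
]

#: default knot-class groupings reported by the compaction profile
PROFILE_CLASSES = ("3_1", "4_1", "5_1+5_2")


@dataclass(frozen=True)
class KnotProbability:
    """Fraction of knotted chains with a Wilson 95% interval."""

    p: float
    n_total: int
    n_knotted: int
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, n_knotted: int, n_total: int) -> "KnotProbability":
        if n_total <= 0:
            raise InvalidParametersError("empty sample")
        lo, hi = proportion_confint(n_knotted, n_total, alpha=0.05,
                                    method="wilson")
        return cls(p=n_knotted / n_total, n_total=int(n_total),
                   n_knotted=int(n_knotted), ci_low=float(lo),
                   ci_high=float(hi))


def _require_labels(ensemble: Ensemble) -> np.ndarray:
    if ensemble.knot_labels is None:
        raise InvalidParametersError(
            "ensemble has no knot annotations; run classify_ensemble first")
    return ensemble.knot_labels


def knot_probability(ensemble: Ensemble) -> KnotProbability:
    """P_kn = fraction of conformations with any nontrivial knot type.

    "unresolved" labels (nontrivial signature outside the shipped table)
    count as knotted: the probability is defined irrespective of knot
    complexity.
    """
    labels = _require_labels(ensemble)
    if ensemble.n == 0:
        raise InvalidParametersError("empty ensemble")
    n_knot = int(np.sum(labels != "0_1"))
    return KnotProbability.from_counts(n_knot, ensemble.n)


def pkn_vs_ratio(ratios, n_samples: int, seed: int,
                 n_beads: int = 25) -> pd.DataFrame:
    """Knot probability of N-bead rings across a grid of D/L ratios.

    One independent ensemble (sub-seeded from ``seed``) is generated and
    classified per ratio; the table is sorted by D/L.
    """
    ratios = sorted(float(r) for r in ratios)
    ss = np.random.SeedSequence(seed)
    rows = []
    for r, child in zip(ratios, ss.spawn(max(len(ratios), 1))):
        sample_seed, classify_seed = child.generate_state(2) >> np.uint32(1)
        params = ModelParams.from_ratio(n_beads=n_beads, dl_ratio=r)
        ens = sample_ensemble(params, n_samples, seed=int(sample_seed))
        classify_ensemble(ens, seed=int(classify_seed))
        kp = knot_probability(ens)
        rows.append({"dl_ratio": r, "p": kp.p, "n_total": kp.n_total,
                     "n_knotted": kp.n_knotted, "ci_low": kp.ci_low,
                     "ci_high": kp.ci_high})
    return pd.DataFrame(rows, columns=["dl_ratio", "p", "n_total",
                                       "n_knotted", "ci_low", "ci_high"])


def calibrate_dl(target_pkn: float, table: pd.DataFrame) -> float:
    """D/L ratio at which P_kn equals ``target_pkn``.

    Interpolates linearly in (D/L, log P_kn), which is close to straight for
    this model; requires the tabulated P_kn to be monotone (non-increasing
    in D/L within one binomial SE) and the target to lie inside the
    tabulated range.
    """
    t = table.sort_values("dl_ratio").reset_index(drop=True)
    p = t["p"].to_numpy(dtype=float)
    dl = t["dl_ratio"].to_numpy(dtype=float)
    if len(p) < 2:
        raise InvalidParametersError("need at least two grid points")
    se = np.sqrt(np.maximum(p * (1 - p), 1e-300) / t["n_total"].to_numpy())
    for i in range(len(p) - 1):
        if p[i + 1] > p[i] + (se[i] + se[i + 1]):
            raise NonMonotoneTableError(
                f"P_kn increases from D/L={dl[i]} to {dl[i + 1]} beyond SE")
    # exact grid hit
    for i in range(len(p)):
        if p[i] == target_pkn:
            return float(dl[i])
    if not (min(p) <= target_pkn <= max(p)):
        raise ExtrapolationError(
            f"target {target_pkn} outside tabulated P_kn range "
            f"[{min(p):.4g}, {max(p):.4g}]")
    for i in range(len(p) - 1):
        hi, lo = p[i], p[i + 1]   # p decreasing with D/L
        if lo <= target_pkn <= hi:
            if lo <= 0:
                raise ExtrapolationError(
                    "bracketing grid point has zero counts; enlarge the run")
            f = ((math.log(target_pkn) - math.log(hi))
                 / (math.log(lo) - math.log(hi)))
            return float(dl[i] + f * (dl[i + 1] - dl[i]))
    raise ExtrapolationError("target not bracketed by the table")


def _class_mask(labels: np.ndarray, cls: str) -> np.ndarray:
    if cls == "5_1+5_2":
        return (labels == "5_1") | (labels == "5_2")
    return labels == cls


def compaction_profile(ensemble: Ensemble, cutoffs,
                       min_kept: int = 200) -> pd.DataFrame:
    """Conditional knotting statistics under Rg cutoffs.

    For each cutoff (a fraction of the ensemble RMS gyration radius Rg0),
    conformations with Rg <= cutoff * Rg0 are kept and the conditional
    P_kn, per-class probabilities (3_1, 4_1, 5_1+5_2 and per crossing
    number 3..8) and their enhancements over the unconstrained ensemble are
    tabulated.  Rows keeping fewer than ``min_kept`` conformations are
    flagged and should be excluded from headline numbers.
    """
    labels = _require_labels(ensemble)
    rg0 = ensemble.rms_rg
    rel = ensemble.rg / rg0
    n = ensemble.n
    base_knot = labels != "0_1"

    base_class_p = {c: max(_class_mask(labels, c).mean(), 0.0)
                    for c in PROFILE_CLASSES}
    kn_of = _crossing_numbers(labels)
    base_kn_p = {k: float(np.mean(kn_of == k)) for k in range(3, 9)}

    rows = []
    for cut in cutoffs:
        cut = float(cut)
        kept = rel <= cut if np.isfinite(cut) else np.ones(n, dtype=bool)
        n_kept = int(kept.sum())
        row = {"max_rg_rel": cut, "n_kept": n_kept,
               "flagged": n_kept < min_kept}
        if n_kept > 0:
            kp = KnotProbability.from_counts(int(base_knot[kept].sum()),
                                             n_kept)
            row.update(pkn=kp.p, pkn_ci_low=kp.ci_low, pkn_ci_high=kp.ci_high)
            for c in PROFILE_CLASSES:
                pc = float(_class_mask(labels[kept], c).mean())
                key = c.replace("+", "_")
                row[f"p_{key}"] = pc
                row[f"enh_{key}"] = (pc / base_class_p[c]
                                     if base_class_p[c] > 0 else np.nan)
            for k in range(3, 9):
                pk = float(np.mean(kn_of[kept] == k))
                row[f"p_kn{k}"] = pk
                row[f"enh_kn{k}"] = (pk / base_kn_p[k]
                                     if base_kn_p[k] > 0 else np.nan)
        else:
            row.update(pkn=np.nan, pkn_ci_low=np.nan, pkn_ci_high=np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("max_rg_rel", ascending=False).reset_index(drop=True)


def cutoff_at_conditional_pkn(ensemble: Ensemble, target: float = 0.5,
                              cutoffs=None, min_kept: int = 1) -> float:
    """Relative Rg cutoff at which the conditional P_kn reaches ``target``.

    Scans cutoffs downward (default 1.0 to 0.45 in steps of 0.025) and
    linearly interpolates between the grid points bracketing the first
    crossing.  If the target is never reached before the kept count drops
    below ``min_kept``, the crossing is extrapolated from an inverse-
    variance-weighted logistic fit (logit P_kn linear in the cutoff) over
    the innermost few points that keep at least 30 conformations, where the
    local trend is steepest.  Returns NaN if no estimate is possible.
    """
    labels = _require_labels(ensemble)
    knotted = labels != "0_1"
    rel = ensemble.rg / ensemble.rms_rg
    if cutoffs is None:
        cutoffs = np.arange(1.0, 0.449, -0.025)
    prev_cut = prev_p = None
    pts = []
    for cut in cutoffs:
        kept = rel <= cut
        n = int(kept.sum())
        if n < min_kept:
            break
        p = float(knotted[kept].mean())
        pts.append((float(cut), p, n))
        if p >= target:
            if prev_p is None:
                return float(cut)
            f = (target - prev_p) / (p - prev_p) if p > prev_p else 1.0
            return float(prev_cut + f * (cut - prev_cut))
        prev_cut, prev_p = float(cut), p
    good = [(c, p, n) for c, p, n in pts if n >= 30][-6:]
    if len(good) < 3:
        return float("nan")
    c = np.array([g[0] for g in good])
    p = np.clip(np.array([g[1] for g in good]), 1e-6, 1 - 1e-6)
    n = np.array([g[2] for g in good], dtype=float)
    w = np.sqrt(n * p * (1 - p))
    b, a = np.polyfit(c, np.log(p / (1 - p)), 1, w=w)
    if b >= 0:
        return float("nan")
    t = math.log(target / (1 - target))
    return float((t - a) / b)


def _crossing_numbers(labels: np.ndarray) -> np.ndarray:
    """Minimal crossing number per label; -1 for unresolved, 0 for unknots."""
    out = np.zeros(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab == "0_1":
            out[i] = 0
        elif lab == "unresolved":
            out[i] = -1
        else:
            out[i] = sum(int(f.split("_")[0]) for f in lab.split("#"))
    return out


def knot_spectrum(ensemble: Ensemble) -> pd.DataFrame:
    """Probability of each knot population by crossing number (3..8).

    Unresolved conformations are excluded from the spectrum (their class is
    unknown) but still count toward the overall P_kn, so the spectrum sums
    to P_kn minus the unresolved fraction.
    """
    labels = _require_labels(ensemble)
    kn_of = _crossing_numbers(labels)
    n = ensemble.n
    rows = [{"kn": k, "probability": float(np.mean(kn_of == k)),
             "count": int(np.sum(kn_of == k))} for k in range(3, 9)]
    df = pd.DataFrame(rows)
    df.attrs["unresolved_fraction"] = float(np.mean(kn_of == -1))
    return df


def writhe_rg_table(ensemble: Ensemble, bin_width: float = 1.0) -> pd.DataFrame:
    """Mean relative gyration radius Rg/Rg0 per |writhe| bin.

    Bins run from 0 in steps of ``bin_width``; empty bins are reported with
    count 0 and no mean.
    """
    if ensemble.writhe is None:
        raise InvalidParametersError(
            "ensemble has no writhe annotations; run annotate_writhe first")
    if bin_width <= 0:
        raise InvalidParametersError("bin_width must be > 0")
    aw = np.abs(ensemble.writhe)
    rel = ensemble.rg / ensemble.rms_rg
    n_bins = int(math.floor(aw.max() / bin_width)) + 1
    idx = np.minimum((aw / bin_width).astype(np.int64), n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        cnt = int(m.sum())
        rows.append({"wr_lo": b * bin_width, "wr_hi": (b + 1) * bin_width,
                     "n": cnt,
                     "mean_rg_rel": float(rel[m].mean()) if cnt else np.nan})
    return pd.DataFrame(rows)
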