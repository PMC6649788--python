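"""Equilibrium ensembles of excluded-volume bead rings by crankshaft Monte Carlo.

The model is a closed ring of ``N`` spherical beads of diameter ``D`` whose
centers are joined by straight, infinitely thin segments; the free part of a
segment, of length ``L``, represents a DNA linker between nucleosomes.  The
only energy term is hard-sphere exclusion between non-adjacent beads, so
Metropolis acceptance reduces to an overlap test.  Crankshaft moves rotate a
sub-arc rigidly about the axis through its two pivot beads; segments may pass
through each other, so the sampled ensemble is torsionally relaxed and
unrestricted in topology, and knotting statistics are read off a posteriori.

All lengths are expressed in units of the bead-center spacing ``D + L``
(default normalization ``D + L = 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .errors import (
    DegenerateAxisError,
    InvalidParametersError,
    SamplingFailureError,
    UndefinedAutocorrelationError,
)

__all__ = [
    "ModelParams",
    "RingConformation",
    "Ensemble",
    "MCState",
    "build_initial",
    "crankshaft",
    "has_overlap",
    "radius_of_gyration",
    "autocorrelation_time",
    "sample_ensemble",
]

#: sweeps of the pilot run used to estimate the Rg autocorrelation time
PILOT_SWEEPS = 10_000
#: accepted moves between bond-length re-projections
RENORM_EVERY = 10_000
#: sweeps per kernel call (fixed so the random stream is chunk-independent)
CHUNK_SWEEPS = 20_000


@dataclass(frozen=True)
class ModelParams:
    """Geometry and size of the bead-ring model.

    Parameters
    ----------
    n_beads : int
        Number of beads (nucleosomes) in the ring; at least 4.
    bead_diameter : float
        Bead diameter ``D`` (excluded-volume range), >= 0.
    linker_length : float
        Linker length ``L`` > 0; consecutive bead centers sit at ``D + L``.
    """

    n_beads: int = 25
    bead_diameter: float = 0.47 / 1.47
    linker_length: float = 1.0 / 1.47

    def __post_init__(self):
        if self.n_beads < 4:
            raise InvalidParametersError("n_beads must be >= 4")
        if self.bead_diameter < 0:
            raise InvalidParametersError("bead_diameter must be >= 0")
        if self.linker_length <= 0:
            raise InvalidParametersError("linker_length must be > 0")

    @classmethod
    def from_ratio(cls, n_beads: int = 25, dl_ratio: float = 0.47,
                   spacing: float = 1.0) -> "ModelParams":
        """Build params from the ``D/L`` ratio at a given center spacing."""
        if dl_ratio < 0:
            raise InvalidParametersError("dl_ratio must be >= 0")
        L = spacing / (1.0 + dl_ratio)
        D = spacing - L
        return cls(n_beads=n_beads, bead_diameter=D, linker_length=L)

    @property
    def dl_ratio(self) -> float:
        return self.bead_diameter / self.linker_length

    @property
    def center_spacing(self) -> float:
        return self.bead_diameter + self.linker_length


@dataclass(frozen=True)
class RingConformation:
    """Ordered bead centers of one closed ring (cyclic adjacency)."""

    coords: np.ndarray  # (N, 3) float64

    def __post_init__(self):
        c = np.ascontiguousarray(np.asarray(self.coords, dtype=float))
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 4:
            raise InvalidParametersError("coords must be (N>=4, 3)")
        object.__setattr__(self, "coords", c)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.roll(self.coords, -1, axis=0) - self.coords,
                              axis=1)

    def validate(self, params: ModelParams, rtol: float = 1e-9) -> None:
        """Raise if bond lengths or excluded volume are violated."""
        spacing = params.center_spacing
        lens = self.segment_lengths()
        if np.any(np.abs(lens - spacing) > rtol * spacing):
            raise InvalidParametersError(
                f"segment length deviates from D+L by more than rtol={rtol}")
        if has_overlap(self, params.bead_diameter):
            raise InvalidParametersError("non-adjacent beads overlap")


@dataclass
class MCState:
    """Internal sampler state; never holds a rejected proposal."""

    coords: np.ndarray
    step: int = 0
    n_accepted: int = 0
    n_since_renorm: int = 0
    rg_series: list = field(default_factory=list)


@dataclass
class Ensemble:
    """Decorrelated ring conformations with per-conformation annotations."""

    params: ModelParams
    coords: np.ndarray             # (n, N, 3)
    rg: np.ndarray                 # (n,)
    seed: int
    burn_in_sweeps: int
    decorrelation_sweeps: int
    acceptance_rate: float
    tau_int_sweeps: float
    knot_labels: Optional[np.ndarray] = None   # array of str, len n
    knot_d1: Optional[np.ndarray] = None
    knot_d2: Optional[np.ndarray] = None
    writhe: Optional[np.ndarray] = None        # signed, exact method

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def rms_rg(self) -> float:
        """Ensemble RMS radius of gyration Rg0 = sqrt(<Rg^2>)."""
        return float(np.sqrt(np.mean(self.rg ** 2)))

    def conformation(self, i: int) -> RingConformation:
        return RingConformation(self.coords[i])


def _as_coords(conf) -> np.ndarray:
    c = getattr(conf, "coords", conf)
    return np.ascontiguousarray(np.asarray(c, dtype=float))


def build_initial(params: ModelParams) -> RingConformation:
    """Regular planar N-gon with side ``D + L`` (the unknotted start)."""
    N = params.n_beads
    spacing = params.center_spacing
    R = spacing / (2.0 * math.sin(math.pi / N))
    # shortest non-adjacent chord is between next-nearest vertices
    min_chord = 2.0 * R * math.sin(2.0 * math.pi / N)
    if min_chord < params.bead_diameter:
        raise InvalidParametersError(
            "regular polygon start violates excluded volume "
            f"(next-nearest chord {min_chord:.4g} < D {params.bead_diameter:.4g})")
    theta = 2.0 * math.pi * np.arange(N) / N
    coords = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                              np.zeros(N)])
    return RingConformation(coords)


def crankshaft(conf, i: int, j: int, angle: float) -> RingConformation:
    """Rigidly rotate the beads strictly between i and j (forward from i)
    by ``angle`` about the axis through centers i and j."""
    P = _as_coords(conf)
    N = P.shape[0]
    i %= N
    j %= N
    if i == j:
        raise InvalidParametersError("pivot indices must differ")
    arc = (j - i) % N - 1
    if arc < 1 or arc > N - 3:
        raise InvalidParametersError(
            f"arc between pivots must contain 1..N-3 beads, got {arc}")
    axis = P[j] - P[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise DegenerateAxisError("pivot centers coincide; axis undefined")
    a = axis / norm
    idx = [(i + 1 + m) % N for m in range(arc)]
    v = P[idx] - P[i]
    ca, sa = math.cos(angle), math.sin(angle)
    rot = (v * ca + np.cross(np.broadcast_to(a, v.shape), v) * sa
           + np.outer(v @ a, a) * (1.0 - ca))
    Q = P.copy()
    Q[idx] = P[i] + rot
    return RingConformation(Q)


def has_overlap(conf, bead_diameter: float) -> bool:
    """True iff any non-adjacent center pair is strictly closer than D.

    Distance exactly D counts as contact, not overlap.
    """
    P = _as_coords(conf)
    return bool(_kernels.full_overlap(P, float(bead_diameter)))


def radius_of_gyration(conf) -> float:
    """RMS distance of bead centers from their centroid."""
    P = _as_coords(conf)
    return float(_kernels.rg_of(P))


def autocorrelation_time(series) -> float:
    """Integrated autocorrelation time with a self-consistent window.

    tau_int = 1 + 2 * sum_{k<=W} rho(k), where W is the smallest lag with
    W >= 5 * tau_int(W) (Sokal's windowing).  Clamped below at 1 (white
    noise limit).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 100:
        raise InvalidParametersError("series must be 1-D with length >= 100")
    x = x - x.mean()
    var = np.dot(x, x) / x.size
    if var <= 0 or not np.isfinite(var):
        raise UndefinedAutocorrelationError("constant series")
    n = x.size
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    for w in range(1, n // 2):
        tau = 1.0 + 2.0 * np.sum(rho[1:w + 1])
        if w >= 5.0 * tau:
            break
    return float(max(tau, 1.0))


def _draw_move_randoms(rng: np.random.Generator, n_moves: int, N: int):
    ri = rng.integers(0, N, size=n_moves).astype(np.int64)
    rk = rng.integers(2, N - 1, size=n_moves).astype(np.int64)  # k in [2, N-2]
    ra = rng.uniform(-math.pi, math.pi, size=n_moves)
    return ri, rk, ra


def sample_ensemble(params: ModelParams, n_samples: int, seed: int,
                    burn_in="auto", decorrelation="auto",
                    pilot_sweeps: int = PILOT_SWEEPS) -> Ensemble:
    """Sample ``n_samples`` decorrelated ring conformations.

    Proposals are crankshaft moves with a uniformly random pivot pair
    (ordered, arc length 2..N-2) and rotation angle uniform on (-pi, pi],
    accepted iff no bead overlap results.  With ``burn_in="auto"`` a pilot
    run estimates the integrated autocorrelation time ``tau`` of Rg in
    sweeps (1 sweep = N proposals); burn-in is then ``ceil(200 * tau)``
    sweeps and the storage interval ``ceil(2 * tau)`` sweeps.  The run is
    bitwise reproducible from ``(params, seed)``.
    """
    if n_samples < 1:
        raise InvalidParametersError("n_samples must be >= 1")
    N = params.n_beads
    D = params.bead_diameter
    spacing = params.center_spacing
    ss = np.random.SeedSequence(seed)
    pilot_ss, main_ss = ss.spawn(2)

    conf0 = build_initial(params)

    # --- pilot: estimate tau_int of Rg and probe for jamming ---
    P = conf0.coords.copy()
    rng = np.random.default_rng(pilot_ss)
    pilot_rg = np.empty(pilot_sweeps)
    pilot_frames = np.empty((pilot_sweeps, N, 3))
    n_acc = 0
    n_since = 0
    done = 0
    while done < pilot_sweeps:
        chunk = min(CHUNK_SWEEPS, pilot_sweeps - done)
        ri, rk, ra = _draw_move_randoms(rng, chunk * N, N)
        n_acc, n_since, n_rec = _kernels.mc_run(
            P, D, spacing, chunk, 1, ri, rk, ra,
            pilot_frames[done:done + chunk], pilot_rg[done:done + chunk],
            RENORM_EVERY, n_acc, n_since)
        done += chunk
    if n_acc == 0:
        raise SamplingFailureError(
            f"no accepted move in {pilot_sweeps} pilot sweeps (jammed parameters)")
    tau = autocorrelation_time(pilot_rg[pilot_sweeps // 5:])

    if burn_in == "auto":
        burn_in_sweeps = int(math.ceil(200.0 * tau))
    else:
        burn_in_sweeps = int(burn_in)
    if decorrelation == "auto":
        decor = max(1, int(math.ceil(2.0 * tau)))
    else:
        decor = max(1, int(decorrelation))

    # --- main run: burn in from the initial polygon, then collect ---
    P = conf0.coords.copy()
    rng = np.random.default_rng(main_ss)
    empty_f = np.empty((0, N, 3))
    empty_r = np.empty(0)
    n_acc = 0
    n_since = 0
    n_moves_total = 0
    done = 0
    while done < burn_in_sweeps:
        chunk = min(CHUNK_SWEEPS, burn_in_sweeps - done)
        ri, rk, ra = _draw_move_randoms(rng, chunk * N, N)
        n_acc, n_since, _ = _kernels.mc_run(
            P, D, spacing, chunk, 0, ri, rk, ra, empty_f, empty_r,
            RENORM_EVERY, n_acc, n_since)
        done += chunk
        n_moves_total += chunk * N

    out_coords = np.empty((n_samples, N, 3))
    out_rg = np.empty(n_samples)
    collected = 0
    while collected < n_samples:
        want = n_samples - collected
        chunk = min(CHUNK_SWEEPS, want * decor)
        # chunk must be a multiple of decor so records align
        chunk = max(decor, (chunk // decor) * decor)
        ri, rk, ra = _draw_move_randoms(rng, chunk * N, N)
        n_acc, n_since, n_rec = _kernels.mc_run(
            P, D, spacing, chunk, decor, ri, rk, ra,
            out_coords[collected:], out_rg[collected:],
            RENORM_EVERY, n_acc, n_since)
        collected += n_rec
        n_moves_total += chunk * N

    acc_rate = n_acc / n_moves_total if n_moves_total else 0.0
    return Ensemble(params=params, coords=out_coords, rg=out_rg, seed=seed,
                    burn_in_sweeps=burn_in_sweeps, decorrelation_sweeps=decor,
                    acceptance_rate=float(acc_rate), tau_int_sweeps=float(tau))
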