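"""Independent oracles used by the test suite.

The random equilateral closed polygon sampler here is a direct (non-MCMC)
construction: the configuration space fibers over the moment polytope of
the chord lengths d_i = |v_0 v_{i+1}| with uniform dihedral angles, so
sampling the d_i uniformly from the polytope (rejection from a sequential
proposal) and the angles uniformly yields exact draws from the standard
measure on closed equilateral n-gons.  It shares no code with the crankshaft
sampler it is used to check.
"""

import numpy as np


def _sample_diagonals(n, rng):
    while True:
        d = np.empty(n - 2)
        d[0] = 1.0
        w = 1.0
        for i in range(1, n - 2):
            lo = max(d[i - 1] - 1.0, 1.0 - d[i - 1], 0.0)
            hi = d[i - 1] + 1.0
            d[i] = rng.uniform(lo, hi)
            w *= (hi - lo) / 2.0
        if abs(d[n - 3] - 1.0) > 1.0:
            continue
        if rng.uniform() < w:
            return d


def _polygon_from_diagonals(d, n, rng):
    V = np.zeros((n, 3))
    V[1] = (1.0, 0.0, 0.0)
    for i in range(2, n):
        r_prev = np.linalg.norm(V[i - 1])
        r_new = d[i - 1] if i - 1 <= n - 3 else 1.0
        a = V[i - 1] / r_prev
        ca = (r_prev ** 2 + r_new ** 2 - 1.0) / (2.0 * r_prev * r_new)
        ca = min(1.0, max(-1.0, ca))
        sa = np.sqrt(max(0.0, 1.0 - ca * ca))
        h = (np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9
             else np.array([0.0, 1.0, 0.0]))
        e1 = np.cross(a, h)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        V[i] = r_new * (ca * a + sa * (np.cos(phi) * e1 + np.sin(phi) * e2))
    return V


def random_equilateral_polygons(n, count, seed):
    """(count, n, 3) exact samples of closed equilateral n-gons."""
    rng = np.random.default_rng(seed)
    out = np.empty((count, n, 3))
    for k in range(count):
        out[k] = _polygon_from_diagonals(_sample_diagonals(n, rng), n, rng)
    return out
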