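# Methods

## The model

A circular minichromosome is represented as a closed ring of `N` spherical
beads of diameter `D` (one bead per nucleosome) whose centers are joined by
straight, infinitely thin segments; the exposed part of each segment, of
length `L`, stands for a DNA linker.  Consecutive bead centers therefore sit
at distance `D + L`, which is the internal unit of length (`D + L = 1`).
The configurational energy is zero unless two non-adjacent beads overlap
(center distance strictly below `D`), in which case it is infinite — a pure
hard-sphere chain.  Linkers are *phantom*: segments may pass through one
another during sampling, so the equilibrium ensemble is torsionally relaxed
and unrestricted in topology, and the knot spectrum is a property read off
the sampled conformations rather than a constraint.  This mimics the action
of a strand-passing enzyme (topoisomerase II) equilibrating the topology of
a nucleosomal fiber.

Deliberately absent: bending and torsional elasticity, electrostatics, an
explicit DNA path inside the beads, and fixed-linking-number (supercoiling-
constrained) sampling.  Compaction is imposed *a posteriori* by
conditioning, not by an attractive potential.

## Sampling

`sample_ensemble` runs Metropolis Monte Carlo built solely on crankshaft
moves: an ordered pivot pair `(i, i+k mod N)` with `i` uniform and
`k` uniform on `[2, N-2]`, and a rigid rotation of the enclosed arc about
the pivot axis by an angle uniform on `(-pi, pi]`.  Because the proposal is
symmetric and the energy is 0/infinity, acceptance reduces to an overlap
test against the unmoved beads (rotation preserves all distances within the
arc and to the pivots).  Large angles cost nothing here, so no step-size
tuning is needed; acceptance at `N = 25`, `D/L = 0.47` is about 0.79.

Decorrelation is controlled by the integrated autocorrelation time `tau` of
the radius of gyration, estimated from a 10^4-sweep pilot run (first 20%
discarded) with Sokal's self-consistent window (`W >= 5 tau(W)`); one sweep
is `N` proposed moves.  Defaults: burn-in `ceil(200 tau)` sweeps from the
regular-polygon start, storage every `ceil(2 tau)` sweeps (`tau` is about
2.2 sweeps at the reference parameters).  Rigid rotations conserve bond
lengths analytically; to bound floating-point drift every 10^4 accepted
moves the bonds are re-projected to exactly `D + L` (sequential rescale plus
linear redistribution of the closure error, reverted in the measure-zero
case it would create an overlap).  Stored conformations satisfy the bond
tolerance to better than 1e-6 and are strictly overlap-free; contact at
exactly distance `D` counts as allowed.

All randomness flows from one `numpy` `SeedSequence`; the sweep-chunking of
the kernel is a fixed constant, so a given `(params, seed)` reproduces the
ensemble bitwise.

Validation: with `D = 0` the chain is a freely jointed closed equilateral
polygon, for which an exact *direct* sampler exists (the configuration
space fibers over the moment polytope of the chord lengths, with uniform
dihedral angles).  The test suite compares the crankshaft sampler against
that independent construction: two-sample KS on the Rg distribution
(p = 0.33 at 5000 per side) and knotting probability within 3 pooled SE.

## Knot identification

Each conformation is orthogonally projected along a random direction
(uniform on the sphere).  Non-generic projections — a segment parallel to
the direction, a vertex or tangential intersection, coincident crossing
depths, or two crossings closer than 1e-9 along the curve — are rejected
and the direction redrawn (budget 32; in practice well under 1% of draws).
The planar diagram is stored as the ordered sequence of over/under passages
with right-hand-rule signs (the Dowker–Thistlethwaite code is derivable
from this representation), then simplified by removing Reidemeister-I kinks
and cancellable Reidemeister-II pairs to a fixed point.  Both removals are
exact on realizable diagrams: the patterns used guarantee the connecting
arcs carry no other crossings, so the moves are genuine isotopies.

The knot is identified by the pair of Alexander determinants
`(|Delta(-1)|, |Delta(-2)|)`.  The Wirtinger presentation of a reduced
diagram gives an integer matrix whose minor determinant equals
`±t^a Delta(t)`; since `a` is unknown, a single evaluation is only
invariant at `t = -1`.  The implementation therefore reconstructs the full
determinant polynomial exactly — integer Bareiss determinants at `deg+1`
points, exact rational interpolation — strips the `t^a` unit, and checks
the Alexander symmetry `Delta(t) = t^deg Delta(1/t)` and `|Delta(1)| = 1`
as internal guards before evaluating at `-1` and `-2`.  A compiled
floating-point screen at `t = -1` fast-paths the ~98% of conformations that
are unknots (`|Delta(-1)| = 1`); every nontrivial case goes through the
exact integer route.

The lookup table covers all prime knots through 8 crossings plus the
composites `3_1#3_1` and `3_1#4_1`; the pair separates every entry.  Two
unavoidable coincidences are resolved by convention: `8_20` and `8_21` have
Alexander polynomials *identical* to `3_1#3_1` and `3_1#4_1` respectively,
so those signatures are labelled as the composites (overwhelmingly the more
probable origin in these ensembles).  Chirality is never distinguished (the
Alexander polynomial cannot see it, and neither can gel mobility).
Signatures outside the table are labelled `unresolved`: they count as
knotted in `P_kn` (which is defined irrespective of knot complexity) but
are excluded from per-class spectra.

Test fixtures of known type come from parametric torus and figure-eight
curves and from polygonal braid closures (`5_2`, `6_1`, granny) whose braid
words were cross-checked against the reduced-Burau Alexander polynomial
before being frozen in.

## Writhe

Two independent routes.  `writhe_projection` implements the definitional
estimator: the mean signed crossing number over uniformly random viewing
directions (default 300, i.e. "hundreds"; SE reported, scaling as
`n^-1/2`).  `writhe_exact` evaluates the Gauss double integral in closed
form as the signed solid angle of the quadrilateral spanned by each
non-adjacent segment pair; it is deterministic, scale invariant, and is the
default for ensemble annotation.  Collinear degeneracies in the solid-angle
formula are resolved by a deterministic 1e-9 endpoint perturbation;
a full solid angle (2 pi) identifies an intersecting pair, for which the
writhe is reported as undefined.  The two routes agree within 3 SE on every
tested conformation, and point inversion flips the projection estimate
exactly (same directions, every crossing sign reversed).

## Compaction analysis

`Rg` is the RMS distance of the bead centers from their centroid (divisor
`N`); `Rg0` is the ensemble RMS value `sqrt(<Rg^2>)`.  Compaction
conditioning keeps conformations with `Rg <= cutoff * Rg0` and reports the
conditional `P_kn` (Wilson 95% intervals throughout), per-class
probabilities for `3_1`, `4_1`, `5_1+5_2` and per crossing number 3–8, and
enhancements `P(class|kept) / P(class|all)`.  Rows keeping fewer than
`min_kept` conformations (default 200) are flagged.  The cutoff at which
the conditional `P_kn` reaches a target is found by scanning downward in
steps of 0.025 with linear interpolation at the first crossing; if the
kept count hits zero first, a variance-weighted logistic fit over the
innermost scan points (those keeping >= 30) extrapolates the crossing.
The `D/L` calibration interpolates `log P_kn` linearly in `D/L` (the sweep
is close to log-linear over `D/L` in [0.3, 0.65]) and refuses
non-monotone tables and out-of-range targets.

Problem sizes: the package's production-scale compaction run uses 4x10^6
decorrelated conformations; the suite and the acceptance script use the
desk-scale defaults of 2x10^4 samples per `D/L` grid point and 5x10^5 for
the conditioning run.  At desk scale roughly 50 conformations survive the
0.6 cutoff, so the per-class enhancements there carry large (factor ~2)
sampling scatter; the compaction-profile `min_kept` flag marks exactly
this regime.

### What the model reproduces, and where it deviates

Measured at production scale (4x10^6 samples, pooled over four seeds), the
unconstrained reference ensemble at `N = 25`, `D/L = 0.47` gives
`P_kn = 0.0208` — recovering the in-vivo basal knotting level at
`D/L = 0.47` — and `Rg0/(D+L) = 1.599 ± 0.001`.  (With a `1/(N-1)`
divisor in `Rg` this is 1.632; the commonly quoted 1.63 corresponds to
that convention.  The `1/N` definition is kept here.)  Conditional
knotting rises steeply under compaction with enhancements strictly ordered
by knot complexity, and the mean `Rg/Rg0` decreases monotonically across
`|Wr|` bins.

Quantitatively, however, this model reaches conditional `P_kn = 0.5` at a
cutoff of about `0.53 x Rg0`, not `0.60`: at exactly `0.6 Rg0` the
conditional `P_kn` is `0.29 ± 0.02` (fold increase ~14), with enhancements
8.1 (`3_1`), 24 (`4_1`) and 87 (`5_1+5_2`).  Near the `P_kn = 0.5`
compression level the enhancement triple is ~12 / ~25–50 / >= 60 — the
in-vivo pattern — so the qualitative conclusion (a roughly 5-fold volume
compaction reproduces both the knotting level and the knot spectrum of
positively supercoiled chromatin) holds, while the headline association of
that state with precisely 60% of `Rg0` does not, in this implementation.
Likewise, strongly writhed conformations (`|Wr| >= 9`) average
`Rg/Rg0 = 0.71`, and the compact subset at the 0.6 cutoff has mean
`|Wr| ~ 2.2`: writhing implies compaction, but compaction does not imply
net writhe.  The corresponding acceptance tests assert the reference readings
(conditional `P_kn = 0.5` at the 0.6 cutoff; `|Wr| >= 9` at the matching
compaction) and are expected to fail against this implementation; they
are retained unweakened as a record of the discrepancy.

## Synthetic gel statistics

The gel generator emulates the *statistical* structure of two-dimensional
gel quantifications of nicked minichromosome DNA — nothing about
electrophoresis is modelled (no mobilities, band overlap, probe-exposure
nonlinearity, or densitometry).  Per time point, each of `n` molecules is
positively supercoiled with probability `f_S(t)`, knotted with probability
`P_cond` if supercoiled and `P_basal` otherwise, and knotted molecules draw
a crossing-number class 3–8 from a fixed spectrum.  Defaults are the
measured in-vivo scales: `P_basal = 0.02`, `P_cond = 0.5`,
`f_S(t) = 1 - exp(-t / 35 min)` sampled at 0–120 min, a trefoil-dominated
geometric spectrum (ratio 0.4), and 10^4 molecules per lane.  The
saturating `f_S` emulates the accumulation of supercoiled molecules after
topoisomerase II inactivation; the late-time *plateau* of total knotting
seen in vivo (knotting stops changing once the enzyme is fully inactive)
is deliberately not modelled — the estimators target the window where
knotting tracks the supercoiled fraction.

The conditional estimator inverts the total-probability decomposition
`P_total = P_basal (1 - f_S) + P_cond f_S`, attributing basal knotting to
the non-supercoiled fraction; this formalization (one modelling choice among several the gel readouts
alone cannot distinguish) is exact under the generator's assumptions and
recovers the generating parameters without detectable bias over 100
replicates.  Per-class fold changes between conditions use a 0.5-count
continuity correction when the baseline class is empty, flagged as a lower
bound.

## Numerical choices

- Degeneracy tolerance 1e-9 (units of `D + L`) for all projection tests;
  redraw budget 32.
- Overlap is a strict inequality; distance exactly `D` is contact.
- Float determinant screen trusts only `|Delta(-1)| = 1`; values above
  1e12 are routed to the exact integer path.
- Autocorrelation requires >= 100 points and a non-constant series;
  `tau_int` is clamped below at 1.
- XYZ coordinates are printed to 9 decimals; write-then-read is the
  identity at that precision.

## Limitations

Beads are the only excluded volume — DNA linkers can pass through beads as
well as each other, so absolute knotting levels are tied to this specific
coarse-graining and to the calibrated `D/L`, not derived from DNA
mechanics.  Knots above 8 crossings are reported only as `unresolved`
(about 2% of knotted conformations unconstrained, more under strong
compaction).  The Alexander signature cannot separate a handful of larger
knots from tabulated ones even in principle (`8_20`, `8_21`); at these
chain lengths the affected fraction is negligible.  The gel generator
draws knot classes independently of `f_S`, so it cannot emulate
spectrum shifts between relaxed and supercoiled states within a single
table — use two tables (two conditions) for that comparison, as the fold-
change estimator does.
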