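# knotfiber

Monte Carlo modelling and knot analysis of coarse-grained nucleosomal
fiber rings.

Topoisomerase II, by passing one DNA duplex through another, leaves a small
steady-state population of knotted DNA circles inside chromatin: in yeast
circular minichromosomes of ~25 nucleosomes the knotting probability is
about 0.02, and it rises more than an order of magnitude when positive
supercoiling compacts the fiber.  `knotfiber` is for polymer physicists and
chromatin biologists who want to reproduce and extend the conformational-
statistics side of that story: it samples equilibrium ensembles of
beads-on-a-string minichromosome rings, classifies the knot type of every
conformation, computes writhe, and quantifies how conditioning on chain
compaction enriches knots overall and class by class.  A companion module
generates synthetic gel-quantification count tables and implements the
estimators used on real two-dimensional gels.

## The model and the statistics it produces

A minichromosome is a closed ring of `N` spherical beads (nucleosomes) of
diameter `D`, centers joined by straight infinitely thin segments; the free
part of a segment, of length `L`, is a DNA linker, so consecutive centers
sit at `D + L` (= 1 internally).  The only interaction is hard-sphere
exclusion between non-adjacent beads, and linkers are phantom, so the
crankshaft Metropolis sampler explores a torsionally relaxed,
topology-unrestricted ensemble — the equilibrium a strand-passing enzyme
would establish.

Per conformation the package computes:

- **knot type** — by generic projection to a crossing diagram,
  Reidemeister I/II reduction, and integer-exact Alexander determinants
  `(|Δ(-1)|, |Δ(-2)|)` looked up against all prime knots through 8
  crossings plus the composites `3_1#3_1` and `3_1#4_1`;
- **writhe** `Wr` — exact Gauss-integral evaluation over segment pairs,
  cross-checked by the definitional projection average;
- **radius of gyration** `Rg`, with the ensemble RMS value `Rg0` as the
  compaction reference.

From these: the knotting probability `P_kn` (with Wilson intervals), the
`P_kn(D/L)` calibration curve and its interpolation to a target `P_kn`,
conditional knot statistics under cutoffs `Rg <= c * Rg0`, per-class
enhancements, and the mean `Rg/Rg0` per `|Wr|` bin.

## Worked example

```python
import knotfiber as kf

params = kf.ModelParams.from_ratio(n_beads=25, dl_ratio=0.47)
ens = kf.sample_ensemble(params, 20_000, seed=1)
kf.classify_ensemble(ens, seed=2)
kf.annotate_writhe(ens)

kp = kf.knot_probability(ens)
print(f"Rg0/(D+L) = {ens.rms_rg:.3f}")
print(f"P_kn = {kp.p:.4f}  (95% CI {kp.ci_low:.4f}-{kp.ci_high:.4f})")

prof = kf.compaction_profile(ens, [1.0, 0.8, 0.7], min_kept=50)
print(prof[["max_rg_rel", "n_kept", "pkn", "enh_3_1", "enh_4_1"]]
      .round(4).to_string(index=False))
```

prints

```
Rg0/(D+L) = 1.599
P_kn = 0.0223  (95% CI 0.0204-0.0245)
 max_rg_rel  n_kept    pkn  enh_3_1  enh_4_1
        1.0   11076 0.0368   1.6420   1.7081
        0.8    1688 0.1001   4.1745   6.4045
        0.7     184 0.2065   7.6031  26.4395
```

Read: at the calibrated geometry (`D/L = 0.47`, where the model reproduces
the in-vivo basal knotting level of ~0.02), the unconstrained ring has RMS
gyration radius 1.6 center-spacings.  Keeping only conformations below 80%
and then 70% of `Rg0` raises the conditional knotting probability to 0.10
and 0.21, and the rarer figure-eight knot is enriched faster than the
trefoil — compaction boosts both knot abundance and knot complexity,
exactly the signature seen when positive supercoiling condenses chromatin.

The same pipeline is scriptable from a shell:

```
knotfiber sample --n-beads 25 --dl-ratio 0.47 --n-samples 20000 --seed 1 \
    --out ens.xyz --manifest run.json
knotfiber classify --in ens.xyz --seed 7 --out knots.tsv
knotfiber compact --in ens.xyz --cutoffs 1.0,0.9,0.8,0.7 --out profile.tsv
knotfiber gel-sim --seed 4 --out gel.tsv
knotfiber gel-stats --in gel.tsv --basal 0.02 --out stats.tsv
```

Every subcommand writes plain text (multi-frame XYZ, TSV, JSON manifests),
and rerunning with the same seed reproduces the output byte for byte.

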