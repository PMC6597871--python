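# landgen

Landscape genomics of gene flow and local adaptation for species sampled
in clusters — several colonies (or individuals) per location — across
their range. The package was built for stingless-bee-style studies
(short-range daughter-colony dispersal, beekeeper-based sampling) but
applies to any SNP dataset with georeferenced, location-clustered samples.

It provides, as one tested pipeline:

- **Genotype QC** — VCF input; Phred-quality, depth, missingness, MAF and
  Hardy–Weinberg exact-test filters; genome-wide LD pruning; cluster
  assignment from an external ancestry Q-matrix.
- **Diversity** — per-cluster Ho, He, F, π with bootstrap CIs; LD-method
  effective population size (monogamy or random mating); genome-wide
  Tajima's D with a coalescent-simulation correction for MAF-filter bias.
- **Relatedness** — the allele-frequency-standardized genomic relationship
  (GCTA/GRM form: ≈0 unrelated, ≈0.5 parent–offspring) and a LOESS
  autocorrelogram of relatedness vs. great-circle distance with a
  coordinate-permutation null envelope.
- **Circuit-theory resistance** — resistance surfaces from raster layers
  (habitat/non-habitat, inverted, raw, or uniform null) and exact
  effective-resistance distances between samples on the cell network
  (graph-Laplacian solve, 8- or 4-neighbour, validated against dense
  oracles).
- **Isolation by resistance** — regression of pairwise relatedness on
  resistance distances under the MLPE mixed model

      y_ij = x_ij'β + u_i + u_j + ε_ij,      ρ = σ_u²/(2σ_u² + σ_e²),

  and its **nested extension (NMLPE)** adding an iid random effect
  v_{L(i)L(j)} per unordered pair of sampling locations. With clustered
  sampling, pairs comparing the same two locations are correlated; plain
  MLPE ignores this and its fixed-effect tests become anticonservative
  (the package demonstrates type-I error ≈ 0.4 where NMLPE holds ≈ 0.05).
  All-subsets AIC selection over non-collinear predictors, likelihood-ratio
  tests, a location-sorted residual serial-autocorrelation diagnostic, and
  a sample-exclusion sensitivity analysis round out the module.
- **Habitat–diversity GLS** — location-level diversity vs. habitat
  fraction in a buffer, with six spatial correlation kernels compared by
  AICc and the habitat effect tested by LRT.
- **Genome scans** — environmental-variable selection by PCA; a
  latent-factor association scan (per-locus regression conditional on
  genotype principal components) with genomic-inflation (λ) calibration,
  Benjamini–Hochberg FDR, and candidate intersection across k−1/k/k+1
  factors; an Fst-outlier scan on the same calibration path.
- **Synthetic data** — Gaussian-random-field landscapes, clustered
  sampling designs, and genotypes whose between-location allele-frequency
  covariance decays with circuit resistance (σ²·exp(−R/φ)), plus
  environmental spike-in loci — so the entire pipeline is exercised and
  validated without any external download.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a study in which gene flow follows habitat (resistance 0.1 in
habitat, 0.9 outside), then ask whether model selection recovers that
surface against a pure isolation-by-distance alternative:

```python
from landgen import synth
from landgen.resistance import build_resistance_surface, pairwise_circuit_resistance
from landgen.relatedness import yang_relatedness
from landgen.ibr import (build_pair_table, all_subsets_selection, fit_mlpe,
                         likelihood_ratio_test, residual_serial_autocorrelation)

rasters = synth.simulate_landscape(nrows=50, ncols=50, autocorr_range=6,
                                   habitat_prob=0.25, seed=0)
design = synth.simulate_sampling_design(
    25, 2.5, synth.habitat_mask(rasters["habitat"]), seed=1)
habitat = build_resistance_surface(rasters["habitat"], mode="habitat",
                                   provenance="habitat")
geo_null = build_resistance_surface(rasters["habitat"], mode="null",
                                    provenance="geo_null")
gt, truth = synth.simulate_genotypes_ibr(design, habitat, n_loci=3000,
                                         fst_scale=0.8, seed=2)

rel = yang_relatedness(gt)
pairs = build_pair_table(rel, {
    "habitat": pairwise_circuit_resistance(habitat, gt.samples),
    "geo_null": pairwise_circuit_resistance(geo_null, gt.samples),
}, gt.samples)

table = all_subsets_selection(pairs, nested=False)
print(table[["predictors", "loglik", "aic", "delta_aic", "weight", "rho"]]
      .round(3).to_string(index=False))
```

```
 predictors   loglik        aic  delta_aic  weight   rho
    habitat 5526.878 -11045.755      0.000     1.0 0.403
   geo_null 5292.289 -10576.578    469.177     0.0 0.248
(intercept) 3859.907  -7713.814   3331.942     0.0 0.000
```

The generating habitat surface outranks geographic distance by 469 AIC
units and carries all the Akaike weight; ρ = 0.40 is the fitted
correlation between pairs sharing an individual. Refitting the winner
with the nested correlation structure gives honest effect estimates for
the clustered design:

```python
best = fit_mlpe(pairs, ["habitat"], nested=True)
print(best.summary().round(4).to_string(index=False))
chi2, df, p = likelihood_ratio_test(fit_mlpe(pairs, ["habitat"]),
                                    fit_mlpe(pairs, []))
print(f"LRT: chi2={chi2:.1f}, df={df}, p={p:.2e}")
```

```
       term  estimate    se   ci_lo   ci_hi
(intercept)   -0.0144 0.007 -0.0282 -0.0007
    habitat   -0.0594 0.001 -0.0614 -0.0573
LRT: chi2=3333.9, df=1, p=0.00e+00
```

Relatedness declines by 0.059 per standard deviation of habitat
resistance distance (predictors are z-standardized), and the effect is
overwhelmingly supported. The location-sorted residual diagnostic shows
why the nested model matters: lag-1 serial autocorrelation drops from
0.201 under plain MLPE to 0.016 under NMLPE.

A YAML-configured end-to-end run (filters → diversity → relatedness →
resistance → IBR selection → scans) is available from the shell:

```bash
landgen simulate --out data/ --n-locations 20 --n-loci 2000 --seed 1
landgen run-all --config config.yaml --out runs/study1
```

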