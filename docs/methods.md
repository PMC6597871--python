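# Methods

`landgen` implements a range-wide landscape-genomics analysis for species
with clustered sampling designs (several colonies per sampling location),
built around three questions: does habitat amount predict genetic
diversity, does landscape resistance predict gene flow, and which loci
track environmental gradients. This note documents the statistical models,
the defaults and why they were chosen, the synthetic-data generator, and
the numerical decisions that affect results.

## Genotype filtering

Input is a multi-sample VCF of biallelic SNPs plus a sample-metadata CSV
(`sample_id, lon, lat, location_id`). The filter chain applies, in order:
site quality (Phred 30–80 by default), per-site mean depth (20–50),
per-locus missingness (> 25% missing removed), optional minor-allele
frequency, and a Hardy–Weinberg exact test (p < 1e-4 removed). LD pruning
(greedy keep-first in position order, squared dosage correlation r² < 0.4
genome-wide) and differentiation-outlier removal are separate steps run on
the surviving loci. Order rationale: cheap scalar filters first; pairwise
and model-based filters on the reduced set. The depth filter is applied to
the per-site mean depth across samples (RAD data rarely support stable
per-genotype depth filters at these thresholds).

The HWE test is the conditional exact test: the distribution of the
heterozygote count given the allele counts is enumerated, and the p-value
sums all configurations whose probability does not exceed the observed
one. Monomorphic loci return p = 1.

## Diversity statistics

Per cluster (assigned by Q-matrix argmax, ties to the lowest index):
observed heterozygosity Ho, unbiased expected heterozygosity
He = 2p(1−p)·2n/(2n−1), per-site nucleotide diversity
π = 2k(2n−k)/(2n(2n−1)) from allele counts, and a method-of-moments
per-sample inbreeding coefficient F = (observed hom − expected hom) /
(loci − expected hom). Cluster values are means over loci (F over
samples); 95% CIs are percentile bootstrap over loci (default 1,000
draws), since loci are the exchangeable units for genome-wide summaries.

Effective population size uses the linkage-disequilibrium method: mean
squared dosage correlation over locus pairs (MAF ≥ 0.05), minus the
expected sampling contribution 1/S + 3.19/S², inverted through the
bias-corrected quadratic (Waples 2006, S ≥ 30 form); the monogamy mating
model doubles the random-mating estimate. CIs are a delete-one-locus
jackknife; a non-positive corrected r² reports Ne = ∞.

### Tajima's D and the MAF-filter correction

D = (π̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the classical constants; diploid
genotypes are treated as 2n haplotypes via allele counts (sufficient under
infinite sites). Loci with any missing call are excluded from the
genome-wide D so a single haplotype count applies.

A MAF filter removes rare variants and pushes D upward. The correction
simulates the standard constant-size coalescent (exponential coalescence
times at rate k(k−1)/2, mutations placed on branch segments with
probability proportional to length) at the observed sample size, matching
either the observed number of segregating sites (default) or a θ value,
applies the same MAF filter to every replicate, and subtracts the mean of
the filtered replicate D values from the observation.

An important caveat, verified against two independent coalescent
implementations: the *per-replicate* expectation of D under neutrality is
not exactly zero — at n = 50 haplotypes and S = 100 it is ≈ −0.10. The
textbook "expected to be zero" applies to the numerator (E[π] = E[S]/a₁),
not to the normalized statistic. The simulation-based correction is
unaffected, because the subtracted null mean carries the same offset; but
a raw neutral D should not be expected to average closer to zero than
about −0.1 at these sample sizes.

## Relatedness and the spatial autocorrelogram

Pairwise relatedness is the allele-frequency-standardized genomic
relationship (the GCTA/GRM estimator): off-diagonal
A_jk = mean_i (g_ij − 2p_i)(g_ik − 2p_i)/(2p_i(1−p_i)) with p from the
full sample, monomorphic loci excluded and missing genotypes excluded
pairwise. Because p is estimated from the sample itself, the estimator is
centered: its expectation is the double-centered (row/column-mean-removed)
covariance among individuals. Node-specific components of any predictor
are therefore invisible to regressions on this response — a property that
shaped the synthetic-data design (below).

The autocorrelogram is a degree-1 local-linear LOESS (tricube weights,
default span 0.5, robustness reweighting off) of pairwise relatedness on
great-circle distance (haversine, R = 6,371 km), evaluated on 100 equally
spaced distances from 0 to the maximum. The null envelope permutes which
individual occupies which sampled coordinate — preserving the clustered
sampling geometry — and takes pointwise 2.5%/97.5% quantiles over the
permuted curves (default 199 permutations). Coverage behavior: the
envelope's pointwise coverage is correct (~95%), but exceedances of the
observed curve are serially correlated along the distance grid (a LOESS
window spans many grid points), so the per-dataset fraction of grid
points inside the band is heavy-tailed; users should interpret isolated
short excursions cautiously and rely on sustained departures.

## Resistance surfaces and circuit-theory distances

Rasters are ESRI ASCII grids in WGS84 decimal degrees (the package's
raster format; degree-based cell sizes are used as-is, without
great-circle correction of cell geometry — a documented limitation
matching common practice). Surface construction modes: `habitat`
(habitat 0.1 / non-habitat 0.9), `invert` (max − value, e.g. inverted
forest cover), `raw` (elevation, roughness, climate), `null` (all cells
0.5 — the isolation-by-distance reference). Surfaces are cropped to the
sample extent plus a one-degree buffer to limit boundary effects, and
zero cells are raised to 0.001.

The raster becomes a resistor network: cells are nodes, edges connect
8-neighbours (4-neighbour mode available), edge conductance is the
arithmetic mean of the two cell conductances, diagonal edges scaled by
1/√2. Effective resistance between the cells containing two samples is
computed from the grounded graph Laplacian: one sparse LU factorization
per connected component, one solve per focal node, all pairs recovered
from node potentials via R(i,j) = u_i[i] + u_j[j] − u_i[j] − u_j[i]. A
direct factorization was preferred over iterative solvers: it is exact to
machine precision, reuses the factorization across focal nodes, and is
faster at the grid sizes involved (validated against the dense Laplacian
pseudoinverse to 1e-8 relative error; note that `numpy.linalg.pinv` is
numerically poor for Laplacians — the exact identity
L⁺ = inv(L + J/n) − J/n is used as the oracle). Samples sharing a cell
are at resistance zero; disconnected pairs are reported infinite and
dropped (with a warning) from regression tables.

## MLPE and nested MLPE

The pairwise regression model is

    y_ij = x_ij'β + u_i + u_j + [v_{L(i)L(j)}] + ε_ij,

with iid normal individual effects u (variance σ_u²), iid normal effects
v per unordered location pair (σ_v²; present only in the nested model,
including a level for within-location pairs), and iid residuals ε
(σ_e²). The shared-individual correlation is reported as
ρ = σ_u²/(2σ_u² + σ_v² + σ_e²) ∈ [0, 0.5]. Predictors (resistance
distances) are z-standardized during pair-table assembly so effect sizes
are comparable across surfaces; means and SDs are stored for
back-transformation.

Fitting profiles β and σ_e² analytically and optimizes the one or two
log variance ratios by bounded L-BFGS-B from three starts (tolerance
1e-12 on the profiled deviance; ratios at the lower bound are snapped to
exactly zero when this does not reduce the log-likelihood by more than
1e-7). Every likelihood evaluation uses the Woodbury identity, reducing
the m×m covariance solve (m = number of pairs) to a Cholesky
factorization of an (n_individuals + n_location_pairs) matrix, so
all-subsets selection over many candidate models is cheap. ML is the
default (required for AIC comparison across fixed-effect sets and for
LRTs); REML is available for variance reporting. Wald SEs and 95% CIs
come from σ_e²(X'Σ⁻¹X)⁻¹. AIC counts fixed effects (including the
intercept) plus variance components (2 for MLPE, 3 for NMLPE).

Degenerate cases: with one colony per location every location pair is
unique and σ_v² is confounded with σ_e²; the fit proceeds but is flagged
non-identifiable. On data with no random-effect variance the ML ratio
estimate lands on the boundary in roughly half of datasets (where the fit
equals OLS exactly) and is O(1/√m) otherwise.

Model selection enumerates all predictor subsets in which every included
pair has |Pearson r| < 0.6, ranks by AIC, and reports ΔAIC and Akaike
weights. The residual diagnostic sorts pairs by location-pair key,
whitens residuals with the Cholesky factor of the fitted covariance, and
reports the lag-1 autocorrelation; plain MLPE on location-clustered data
leaves this clearly positive, and the nested model removes it — the
motivating contrast for NMLPE, which the test suite demonstrates as a
type-I-error calibration experiment (plain-MLPE LRT rejects a null
location-level predictor at ~0.4 when location-pair noise is present;
NMLPE restores ~0.05, at the cost of larger standard errors).

The sample-exclusion sensitivity analysis drops random individuals (all
their pairs), reruns the selection, and reports per-predictor inclusion
frequencies among models with ΔAIC ≤ 2.

## Spatial GLS of diversity on habitat amount

Habitat fraction is counted over cell centers within a great-circle
radius (default 2 km, a typical small-bee foraging range) of each
location; diversity is aggregated per location (mean Ho and F over
colonies; He from location allele frequencies). The GLS model
y = β₀ + β₁·habitat + e allows residual correlation
cov(e_a, e_b) = σ²·k(d_ab; range) under six kernels (none, linear,
exponential, Gaussian, spherical, rational quadratic 1/(1+(d/r)²)); the
range is profiled by bounded 1-D optimization, and a 1e-8 nugget keeps
compact-support kernels positive definite. Heterozygosities may be
logit-transformed (exact 0/1 clipped at a configurable 1e-3 with a
warning). Kernels are compared by AICc on REML fits; the best structure
is refitted by ML and the habitat effect tested by a 1-df LRT.

## Genome scans

Environmental variables (e.g. 19 bioclim layers plus altitude and forest
cover) are reduced by PCA on the scaled matrix: for each leading axis the
variable most correlated with the axis scores is selected (duplicates
fall to the next best, logged).

The association scan conditions on population structure through the
top-k principal components of the centered (mean-imputed) dosage matrix:
per locus, dosage is regressed on the environmental variable plus the
factors, and the environmental coefficient's t-statistic gives a
two-sided p-value. This latent-factor regression preserves the
inferential logic of latent factor mixed models — association conditional
on k structure factors, genomic-inflation calibration, BH FDR, and
intersection of candidates across k−1, k, k+1 — while replacing the MCMC
sampler with its deterministic regression analogue; this substitution is
deliberate and means posterior-based quantities are not produced.

Calibration: p-values map to 1-df chi-square scores; λ is their median
over 0.4549 (the χ²₁ median); adjusted p-values are the upper tail at
score/λ. BH step-up at q = 0.05 flags candidates. The
differentiation-outlier scan uses a per-locus Nei-style Fst (ratio of
small-sample-corrected within- to total heterozygosity) scaled to a
chi-square score with df = n_clusters − 1 (a Lewontin–Krakauer-style
statistic); its null distribution is approximate by construction, and the
λ recalibration absorbs the scale misfit — calibration is established by
island-model simulation, not by distribution theory.

## Synthetic data

The generator instantiates the assumptions the pipeline tests:

- **Landscapes**: unit-variance Gaussian random fields (smoothed white
  noise) for elevation and climate with a correlation length in cells;
  habitat is a third field thresholded to a target habitat fraction;
  roughness is the local 3×3 standard deviation of elevation.
- **Sampling**: locations on distinct valid cells; colony counts
  1 + Poisson(mean − 1); colonies share coordinates (within-location
  distance zero). Locations are placed on habitat cells when a habitat
  mask is supplied — colonies nest in habitat, and this also equalizes
  the node-local resistance of sampling cells.
- **Genotypes**: per locus, ancestral frequency p₀ ~ U(0.1, 0.9);
  location logit-frequencies are multivariate normal with mean logit(p₀)
  and covariance σ²·exp(−R_ab/φ), where R is circuit resistance on the
  generating surface, σ the differentiation scale and φ the decay range
  (default: the median inter-location resistance); logit-normal draws are
  clipped to [0.001, 0.999]; dosages are Binomial(2, p_location).
  Optional extra location-level variance creates the location-pair
  dependence the nested MLPE absorbs. An explicit coalescent over the
  landscape is a documented extension point.
- **Adaptive spike-ins**: a chosen fraction of loci get frequencies
  logistic(a + slope·env) with recorded indices.

Design note on the end-to-end recovery conditions. Because the
relatedness estimator is centered (expectation = double-centered
covariance), predictor components attributable to individual locations
(row/column effects of the resistance matrix) carry no usable signal. On
small fine-grained landscapes most of a heterogeneous surface's pairwise
variance is node-local, and model selection then cannot distinguish it
from a distance-only surface — not a software failure but a property of
the estimand. The end-to-end validation therefore uses conditions where
the signal lies in the estimable space, chosen to mimic the regime of a
range-wide study: a 50×50 landscape with 25% habitat at correlation
length 6 cells (patchy, below percolation, so real barrier structure
exists), 25 locations × ~2.5 colonies sampled on habitat, 3,000 loci,
σ = 0.8, and φ = 5× the median inter-location resistance (decay
approximately linear over the observed range, matching the linear mean
model). Under these conditions the generating surface outranks the
geographic-null surface by AIC in well over 80% of replicates. Passing
tests demonstrate internal consistency of the whole chain at desk scale;
they do not certify power for any particular empirical landscape.

What the generator does not emulate: linkage and recombination maps,
coalescent gene genealogies, selection dynamics beyond static clines,
genotyping error, and non-equilibrium demography.

## Problem sizes and runtime

The validation suite runs at desk scale on one CPU: 1,500–2,000
coalescent replicates for the Tajima's D checks; 50 random grids up to
20×20 against the dense oracle; 200 replicates for MLPE recovery; 500
replicates for the MLPE/NMLPE type-I contrast (60 individuals, 1,770
pairs each); 100 end-to-end landscape replicates; scans at 5,000 loci ×
100 samples; 100 autocorrelogram replicates at 199 permutations. The
acceptance script reruns the same computations at similar or slightly
reduced replicate counts.

## Known limitations

- Raster cells are treated as planar within the grid (degree units);
  only inter-point distances use great circles.
- The latent-factor scan is a regression approximation to LFMM, not the
  MCMC sampler.
- The Fst outlier statistic is calibrated by λ, not derived from an
  exact null.
- Genome-wide Tajima's D uses only loci with complete genotype data.
- Per-replicate neutral Tajima's D has a negative finite-sample
  expectation (≈ −0.1 at n = 50, S = 100); comparisons should use the
  simulation-based correction rather than the nominal zero.
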