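# Methods

`genosdm` implements a genomically informed species-distribution-modelling
workflow: occurrence records are partitioned by genomic ancestry, niche
models are fitted per range and per genetic cluster, niche overlap and
differentiation are quantified, and candidate invasion sources are ranked by
the range expansion they would cause in a focal (non-equilibrium) range.
This note documents the models, the numerical choices, and what the
synthetic study systems do and do not establish.

## Ancestry model

Genotypes are allele dosages g_is ∈ {0,1,2} for individual i at biallelic
SNP s. The admixture model assumes

    g_is ~ Binomial(2, f_is),   f_is = Σ_l q_il p_ls,

with q_i a point on the L-simplex (ancestry proportions) and p_l the
ancestral allele frequencies. Estimation is expectation–maximization on the
complete-data likelihood in which each allele copy is attributed to an
ancestral population. Two modes:

- **joint** (`AdmixtureEM.fit`): q and p updated together from a seeded
  k-means++ start on genotype rows. Stops when the log-likelihood improves
  by less than `tol` (default 1e-3 on the summed log-likelihood; EM is slow
  near the optimum and tighter tolerances change the recovered q by far
  less than its statistical error). Monotonicity of the log-likelihood is
  asserted every iteration.
- **projection** (`AdmixtureEM.transform` / `estimate_q_projection`): p is
  frozen and q estimated per individual from a uniform start, stopping at
  `max |Δq| < 1e-6`. When the frequency rows are identical the likelihood
  is flat and the uniform start is returned unchanged.

Missing dosages are skipped per individual per site. Allele frequencies are
clipped to [1e-6, 1−1e-6] to keep likelihoods finite. Label switching is
resolved by ordering components by descending mean ancestry proportion;
k-means cluster labels (`assign_clusters`, scikit-learn k-means on the rows
of Q) are renumbered by descending cluster size with centroid-lexicographic
tie-breaks, so repeated runs are comparable without alignment.

The number of ancestral populations is chosen by masked-entry
cross-validation (`choose_L`): a random 1/n_folds of dosage entries is
masked per fold, the joint model refitted, and masked entries scored by
binomial deviance; the candidate with the smallest mean CV error wins (ties
to the smaller L). This replaces the original block-relaxation solver and
its held-out-individual CV with an equivalent-in-kind, simpler scheme
appropriate for desk-scale inputs (hundreds of individuals, thousands of
SNPs).

Genetic differentiation uses the Weir–Cockerham (1984) method-of-moments
F_ST for diploid data with observed heterozygosity, generalized to r
groups; the genome-wide value is the ratio of sums Σa / Σ(a+b+c). Negative
per-site estimates are retained and undefined sites are excluded from the
weighted mean, mirroring common variant-toolkit conventions.

## Niche model

The presence–background model is an L1-penalized logistic regression of
presence cells against background cells on standardized linear and
quadratic terms of each environmental layer — the convex analogue of
maximum-entropy niche modelling with its feature set reduced from the full
MaxEnt zoo. The objective is

    Σ NLL + λ · betamultiplier · Σ|coef|,   λ = 1/n_presence by default,

so `betamultiplier` keeps its usual smoothing semantics (the fit is
liblinear with tolerance 1e-8; an effectively unpenalized intercept is
obtained via a large intercept scaling). Three behaviours follow standard
MaxEnt practice:

- **Background sampling** (`sample_background`): uniform without
  replacement from valid cell centres outside a buffer around presences
  (default buffer = one cell width, the analogue of a 1-arc-minute buffer at
  the study's grain) and never from presence cells.
- **Prevalence calibration**: presences and background are sampled at an
  arbitrary ratio, so the raw logistic intercept encodes that ratio rather
  than habitat. The fitted intercept is shifted by −log(n1/n0) — the
  standard case-control prior correction to a common prevalence of 0.5 — so
  suitability surfaces from models with very different record counts are
  directly comparable (the role MaxEnt's logistic output plays). Without
  this, a well-sampled baseline model numerically dominates sparsely
  sampled cluster models in every downstream comparison.
- **Clamping**: when projecting to a new grid, each layer is clipped to its
  training range, preventing runaway quadratic extrapolation in novel
  environments (MaxEnt's default when transferring models).

Model quality is the rank-based AUC (Mann–Whitney form, ties counted half);
binarization for display uses the threshold maximizing sensitivity +
specificity over the unique predicted values, smallest threshold on ties.

## Overlap and comparison statistics

Schoener's D between two suitability surfaces on a common grid first scales
each to sum to 1 over valid cells, then D = 1 − ½ Σ|P_X,i − P_Y,i|. The
niche-similarity randomization test holds one range's model fixed and
refits the other on points drawn uniformly from its range's valid cells
(n_B points for range B), projecting both to the focal grid; the null pools
n_reps replicates of each direction, and the observed D is significant when
it sits at or beyond the empirical 2.5th/97.5th percentiles (linear
interpolation). Replicate model failures are skipped and counted.

Niche breadth is the area of the convex hull of a range's records on the
first two principal components of the pooled, z-standardized environmental
values (correlation-matrix PCA, appropriate for mixed-unit predictors);
breadths are reported as percentages of the pooled-record hull. Pairwise
Welch's t-tests compare environmental means between clusters. The Mantel
test correlates the strict upper triangles of two distance matrices, with
niche similarity converted to dissimilarity (1 − D) before comparison with
F_ST; when `n_perm ≥ n!` the permutation null is enumerated exactly,
otherwise it is the identity plus n_perm − 1 random permutations.

## Risk metrics

The range-expansion score between a baseline surface and a scenario surface
counts, for each threshold z ∈ [0,1], the cells unsuitable under the
baseline but suitable under the scenario (base < z ≤ scenario) and
integrates over z. The closed form Σ_i max(0, scenario_i − base_i) is the
primary computation; the z-curve (default 1001 points) is retained for
reporting and cross-checks the closed form by trapezoid quadrature. The
percentage divides by the number of valid land cells (masked sea cells are
excluded; the choice is recorded in output metadata). `scenario_compare`
fits the baseline on the focal range's own records and one model per
(range, cluster) source — sources with fewer than 2 records are skipped —
and returns the descending threat ranking.

Extrapolation is summarized by 'simple' mobility-oriented-parity maps: per
projection cell, the number of predictors whose value falls strictly
outside the [min, max] observed in the reference region. Distance-based MOP
components are out of scope.

## Synthetic study systems

`ScenarioSpec`/`generate_scenario` emulate the structure the analysis
assumes. Landscapes are linear gradients (layer 1 west–east, layer 2
north–south, further layers in directions shared across ranges) plus
range-specific smoothed Gaussian noise, rescaled by robust 1st–99th
percentiles to the unit interval (min–max rescaling made the tail areas of
the environmental distribution unstable across noise draws); border cells
are masked by a smooth field to emulate coastline. Genotypes follow the
Balding–Nichols model (shared ancestral frequencies ~ U(0.05, 0.95),
per-population frequencies Beta-drifted with parameter F), ancestry is
Dirichlet per range, and dosages are binomial. Individuals settle in cells
with probability proportional to a Gaussian kernel in *environment* space
around their dominant cluster's optimum, which gives cluster-specific
niche models a recoverable target; the non-equilibrium range is restricted
to a sub-rectangle of its landscape.

Default conditions: 3 ranges, 60×60 grids, 5 environmental layers, L = 3
ancestral populations at F = 0.3, 2000 SNPs, 200 individuals per range,
specialist niches (sd 0.08 on the unit environmental range) so each range's
realized niche is compact and separable, and a founder mix in the last
range that nearly lacks the first cluster.

`qualitative_pattern_spec` is a second, smaller configuration (40×40, 3
layers, 400 SNPs, 150 individuals/range) whose geometry mirrors the
cluster structure this kind of analysis is meant to detect: two similar
warm clusters (optima 0.6 and 0.68, sd 0.08) and one distant cool
specialist (optimum 0.2, sd 0.12); the focal range is geographically
restricted (central rows, so no cluster's environmental support is cut)
and its founder mix essentially lacks the cool cluster. Under these
conditions the cool cluster's niche is novel habitat: across seeded
replicates the warm pair overlaps more with each other than with the
outlier, and the cool-cluster source ranks first in the expansion table
(~95% of replicates in a 60-seed audit).

What passing these tests shows — and does not. The generator plants exactly
the association the analysis looks for, with unlinked SNPs, noise-free
environmental layers, no sampling bias, no dispersal limitation and no
temporal dynamics. Recovery therefore demonstrates correctness of the
implementation and internal consistency of the workflow, not performance on
real occurrence and genotype data, where observation bias and
linkage/demographic structure can dominate.

## Pipeline and reproducibility

`run_all` executes simulate → filter (MAF ≥ 0.05, no missing calls by
default) → cluster (CV choice of L on the first range, joint fit there,
projection elsewhere, k-means with k = 3) → fit (one model per range;
cluster-specific record sets assembled per range) → overlap (cluster-level
D on the focal grid, Welch tests, optional similarity tests, Mantel of
1−D against F_ST) → rank. Every random draw flows from the single config
seed through named substreams; the manifest records config, derived
quantities, stage wall times, and SHA-256 hashes of all outputs, so two
runs with the same config produce identical hashes. Problem sizes in the
shipped tests (grids from 25×25 to 60×60, 100–2000 SNPs, 50–200 individuals
per range) are the package's chosen desk scale; every stage is linear or
near-linear in cells × records, so larger runs are a matter of patience,
not code.

## Known limitations

- Planar geometry; no coordinate reference systems or great-circle
  distances. "One cell" replaces arc-minute units.
- The feature set is linear + quadratic; multimodal realized niches within
  a single record set are underfitted relative to full MaxEnt's hinge
  features. The cluster-partitioned workflow mitigates this by design.
- Presence–background logistic output, even prevalence-calibrated, is a
  relative suitability index; expansion percentages are comparable within a
  run, not absolute areas.
- The admixture EM is first-order and desk-scale; genome-scale data would
  want the accelerated solvers of dedicated tools.
- The similarity test's null band is an empirical quantile band; with few
  replicates its coverage is conservative-to-liberal by small-sample error
  (the shipped checks use 20–30 replicates per direction).
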