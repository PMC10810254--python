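# genosdm

Genomically informed species distribution modelling.

Invasion risk depends not only on *where* a species could live but on *which
genotypes* arrive: genetically distinct clusters within a species often
prefer different environments, so the potential range of an introduced
population depends on the genetic composition of its founders. `genosdm`
implements a complete workflow for quantifying that effect:

1. **Cluster occurrences by genomic ancestry.** Ancestry proportions Q are
   estimated under the binomial admixture likelihood
   g<sub>is</sub> ~ Bin(2, Σ<sub>l</sub> q<sub>il</sub> p<sub>ls</sub>) by
   EM (joint estimation in a reference range, projection elsewhere), and
   individuals are grouped by k-means on Q. Differentiation between
   clusters is summarized by Weir–Cockerham F<sub>ST</sub>.
2. **Fit presence–background niche models** per range and per cluster: an
   L1-regularized logistic regression on standardized linear + quadratic
   environmental features (the convex analogue of MaxEnt, with its
   betamultiplier regularization semantics, clamped projection, and
   prevalence-calibrated output), with background points sampled outside a
   buffer around the presences. Models are evaluated by rank-based AUC and
   binarized at the max-sensitivity+specificity threshold.
3. **Compare niches.** Schoener's
   D = 1 − ½ Σ<sub>i</sub> |P<sub>X,i</sub> − P<sub>Y,i</sub>| between
   suitability surfaces scaled to probability surfaces; a randomization
   niche-similarity test (models refitted on random points in each range
   build the null); convex-hull niche breadth on PCA axes; pairwise Welch's
   t-tests; a Mantel test relating niche dissimilarity (1 − D) to
   F<sub>ST</sub>.
4. **Rank invasion sources** by a threshold-independent range-expansion
   metric: for each binarization threshold z, count cells unsuitable under
   the focal range's own model but suitable under a candidate source's
   model, and integrate over z — equal to
   Σ<sub>i</sub> max(0, P<sub>source,i</sub> − P<sub>base,i</sub>),
   reported as a percentage of land cells. 'Simple'
   mobility-oriented-parity maps count out-of-range predictors per cell to
   flag extrapolation.

A fully seeded synthetic-data module generates landscapes (gradient +
smoothed noise rasters with coastline masks), Balding–Nichols genotypes
with admixed individuals, and occurrences with a planted
genotype–environment association, so the whole pipeline is testable without
any external data. See `docs/methods.md` for the models, defaults and
limitations.

## Worked example

Generate a three-range study system whose last range is a geographically
restricted founder population lacking the cool-adapted cluster, then ask
which source population would expand its range the most:

```python
import numpy as np
from genosdm import *

data = generate_scenario(qualitative_pattern_spec(seed=0))
target = data.grids[data.target_range]          # the non-equilibrium range
recs = data.occurrences[data.target_range]

# niche model for the focal range
bg = sample_background(target, recs, n=1000, buffer_radius=1.0, seed=0)
model = fit_niche_model(recs, bg, target)
a = auc(model.predict_points(target.extract(recs.x, recs.y)),
        model.predict_points(target.extract(bg.x, bg.y)))
print(f"focal-range model AUC: {a:.3f}")

# ancestry -> clusters (joint EM in the native range, projection elsewhere)
geno = filter_sites(data.genotypes, min_maf=0.05)
native = geno.range_labels == "native"
anc_native, P = estimate_admixture_joint(geno.subset_samples(native), L=3, seed=0)
q = np.empty((geno.n_samples, 3))
q[native] = anc_native.q
q[~native] = estimate_q_projection(geno.subset_samples(~native), P).q
anc = assign_clusters(AncestryMatrix(q, sample_ids=geno.sample_ids), k=3, seed=0)

# threat ranking: cluster-specific models from the native range
id2cl = dict(zip(geno.sample_ids, anc.cluster))
nat = data.occurrences["native"]
sources = {("native", cl): nat.subset(
               np.array([id2cl[i] == cl for i in nat.df["individual_id"]]))
           for cl in (1, 2, 3)}
print(scenario_compare(recs, sources, data.grids, target,
                       n_background=1000, seed=0).to_string(index=False))
```

Output:

```
focal-range model AUC: 0.995
source_range  cluster  pct_expansion       area  n_records
      native        3      14.393339 212.445685         67
      native        1       0.991752  14.638261         42
      native        2       0.479276   7.074111         41
```

The AUC of 0.995 says the focal range's occupied pocket is sharply
separable from the available background. In the ranking, cluster 3 is the
cool-adapted cluster (mean first-axis environment 0.37 at its records,
versus 0.62/0.57 for clusters 1 and 2): because the focal population lacks
that cluster, its niche is unoccupied habitat there, and introducing it is
predicted to convert ~14% of the landscape — an order of magnitude more
than the warm clusters already represented (~0.5–1%, residual model
disagreement). Pairwise overlaps tell the same story from the niche side:
D(cluster 1, cluster 2) = 0.753 for the two warm clusters against
D = 0.232/0.248 for either warm cluster versus the cool one.

The same analysis runs end-to-end from a config file:

```bash
genosdm run-all --seed 0 --out runs/demo     # writes manifest.json + CSV tables
```

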