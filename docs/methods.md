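# Methods

This note documents the models, defaults and numerical choices behind
`ecotyper`, and what the synthetic validation does and does not show.

## Preprocessing

Singletons are ASVs whose **study-wide** total count is exactly 1; an
ASV seen once in each of two samples is kept. Singleton removal happens
on raw integer counts, before 16S copy-number correction, because
singleton status is a read-count concept. Copy-number correction
divides each ASV column by its per-genome 16S copy number so that
abundances approximate cell proportions. The Hellinger transform
(square root of relative abundance) follows, making Euclidean sample
distances ecologically meaningful and downweighting dominant taxa.

Network QC drops ASVs with variance ≤ 1e-12, keeps the top fraction of
surviving ASVs by mean relative abundance (the pipeline default keeps
90%; the threshold emulates the exclusion of rare sequences before
correlation-network construction — at desk scale the rare tail is far
smaller than in a real survey, where such QC can remove most ASVs),
and then drops samples with more than 50% zeros **among the retained
ASVs**. Sparsity is judged against the abundant ASVs the network will
actually use; judging it on the full table would disqualify most
samples of any realistic sparse count matrix.

## Ordination

PCoA is classical metric scaling: `B = -1/2 J D² J`, eigendecomposition,
scores `v_i sqrt(λ_i)`. Eigenvalues below `1e-8 × λ_max` (including all
negative ones) are dropped with no Cailliez/Lingoes correction, because
the intended input — Euclidean distances of a Hellinger table — gives a
positive semi-definite `B` exactly. On such input PCoA equals PCA of
the centered data; the test suite asserts this equivalence to 1e-8 over
random tables, which is the module's primary correctness anchor (skbio's
PCoA serves as a second, independent cross-check). Axes are oriented so
the largest-magnitude coordinate on each axis is positive, making output
reproducible across BLAS builds.

NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on the input dissimilarities (scikit-learn's
PAV) with Guttman-transform updates. A candidate update is accepted
only while stress-1 decreases, so the iteration trace is non-increasing
by construction; convergence is declared when the decrease falls below
1e-6. The best of 20 seeded random starts plus one PCoA start is
returned. `envfit` regresses each covariate on the ordination axes
(`r² = 1 − SS_res/SS_tot`) with a permutation p-value using the add-one
estimator `(1 + #{r²_perm ≥ r²}) / (1 + n_perm)`, which cannot return 0.

## Self-organizing map

The grid is hexagonal (odd rows shifted +0.5, row spacing √3/2) and by
default toroidal: unit distances are the minimum over the nine shifted
planar copies, which requires an even row count for exact wraparound
(a warning fires otherwise). Training is classical online competitive
learning: `rlen = 100` passes over the data in seeded random order,
learning rate decaying linearly 0.05 → 0.01, bubble neighborhood whose
radius decays linearly from the 2/3-quantile of grid distances to just
below the smallest positive distance, reaching that floor a third of
the way through the run so the remaining passes fine-tune single units.
The codebook is initialized by seeded farthest-point ("maxmin")
selection of data rows: this keeps initialization in the data cloud,
deterministic under the seed, and guarantees that rare but extreme
samples — exactly the ones a small map otherwise averages away — seed a
unit of their own. BMU ties break toward the lowest unit index.

For sample segmentation, k-means is applied to the codebook vectors of
the occupied units and each sample inherits its BMU's cluster. The
k-selection diagnostics (WSS, silhouette) are evaluated on the samples
under those transferred labels, not on the unit vectors: per-sample BMU
rows are duplicated points, and a silhouette over duplicates
degenerately rewards one cluster per occupied unit.

## Co-abundance network

Signed similarity `a_ij = ((1 + cor_ij)/2)^β` with default β = 8; the
soft-power chooser returns the smallest candidate whose scale-free fit
index `−sign(slope)·R²` (log-log regression of binned connectivity
frequencies, 10 equal-width bins) reaches 0.8, falling back to the
argmax with a warning. Topological overlap uses the standard
`TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with the vectorized
form `l = A·A − 2A` (diagonal 1); a triple-loop oracle bounds the
implementation error at 1e-12 in the tests.

Module detection is deliberately "hybrid": k-means on the rows of
`1 − TOM` used as Euclidean feature vectors, with the module count
chosen by the same silhouette/elbow rule (scan 2–10). Labels are
renumbered by descending module size. Eigengenes are the first
principal component of the standardized member profiles, scaled to unit
variance and oriented so the mean member correlation is positive.
Merging is iterative — always the most correlated pair above the 0.7
threshold, eigengenes recomputed after every merge — because a
single-pass merge is order-dependent. kME is the Pearson correlation of
each ASV profile with each eigengene; module–trait correlations carry
two-sided t-distribution p-values (n−2 df) with **no multiple-testing
correction**, matching how module–trait heatmaps are conventionally
reported; downstream consumers should treat them as descriptive.

## Cluster-number selection and statistics

k-means is Lloyd's algorithm from k-means++ seeding, best of 25
restarts by WSS (scikit-learn backend; empty clusters are repaired
internally). The elbow is operationalized as the maximum perpendicular
distance between the WSS curve and the chord joining its endpoints,
after rescaling both axes to [0, 1] — "the inflection" is not
computable verbatim, and the chord rule is parameter-free and
scale-invariant. When elbow and silhouette disagree, the silhouette
wins (it also accounts for between-cluster separation) and the conflict
is recorded in the selection report.

PERMANOVA is one-factor: `SS_total = Σ_{i<j} d²_ij / n`, within-group
sums scaled by group size, pseudo-F with (k−1, n−k) degrees of freedom,
p by label permutation with the add-one estimator. The test suite
checks type-I error calibration (500 null datasets × 199 permutations)
and cross-checks the statistic against skbio. Post-hoc trait
comparisons use Mann–Whitney rank-sum tests — a signed-rank test is
sometimes named in this role in the ecological literature but applies
only to paired samples, which independent unequal-size clusters are
not — exact null when the smaller group has ≤ 8 observations and no
ties, normal approximation with continuity correction otherwise, and
Holm adjustment by default (none/bonferroni/BH selectable).

## Ecotype qualification

Every sample-method cluster and every module (via its dominant-module
timeline) is a candidate. Qualification requires (1) trait
distinctness from *every* other cluster of the same method in at least
one of {doubling time, genome size} (Holm-adjusted pairwise rank-sum
p < 0.05), or, for modules, eigengene correlation with ≥ 2 of
{copy number, doubling time, genome size, GC%, chlorophyll-a} at
p < 0.05; (2) compositional distinctness — Jaccard overlap of the
top-25 most abundant ASVs with each temporally adjacent dominant
cluster < 0.5 (the 25 mirrors the standard "top taxa" heatmap depth;
the 0.5 cut is a declared operationalization, as no numeric rule is
conventional); and (3) functional validation — at least one COG
category with scaled profile ≥ 0.75 for the candidate while ≤ 0.5 for
all temporal neighbours. Candidates without metagenome-matched dates
skip criterion 3 with a warning; candidates with fewer than 3 samples
are rejected outright with reason "insufficient support". COG scaling
is z-score per category followed by min–max to [0, 1]: a raw z-score is
unbounded, so a "0–1 z-score scale" is implemented as this two-step
normalization. Qualified candidates whose sample sets overlap by ≥ 50%
of the smaller set are grouped into one ecotype; each sample joins the
ecotype if at least half of the contributing candidates contain it, and
the window is the span of those core samples.

## Synthetic data generator

The generator emulates a near-daily polar surface-ocean amplicon time
series: 200 samples from 2019-10-29 with two excised gaps (70 d and
22 d, placed in the interiors of planted windows), 800 ASVs with
lognormal(σ = 1) loadings, 30% unstructured background, 20 planted
singletons, multinomial sampling at 50,000 reads per sample, and
per-cell lognormal noise (σ = 0.3 by default). Four seasonal modules
follow flat-topped unimodal bumps (generalized Gaussian, exponent 4)
over the observed-sample axis; the flat top makes each planted window a
quasi-stationary community state separated by fast transitions, which
is what "recurrent ecotype" denotes, rather than a continuously
drifting gradient. Module loadings are rescaled so each module holds a
comparable total share of depth; background ASVs carry independent
random-phase annual sinusoids (±30%) so that, beyond the compositional
closure every relative-abundance table has, they share no planted
co-variation. A pulse module (amplitude 6, sd 0.6 samples, centred
between two sampling days) dominates exactly two samples — the planted
outlier state. Ecotype truth is the argmax of the module signals (label
0 for the two pulse samples). Traits are abundance-weighted mixtures of
per-module archetypes (winter oligotroph 50 h/1.6 Mb through bloom
copiotroph 6 h/4.5 Mb) with 3% lognormal noise; chlorophyll-a tracks
the bloom module; temperature, salinity, latitude and longitude are
smooth seasonal/drift functions of the date with small Gaussian noise.
The COG table has one row per 12th sample (~17 metagenome-matched
dates), rows normalized to 1e6 tpm, with one deterministic enriched
category per ecotype (default effect ×5).

What the generator does **not** emulate: taxonomic structure,
zero-inflation beyond multinomial sampling, unobserved dynamics inside
the date gaps, read-level error, compositional biases of extraction and
PCR, and the very heavy rare tail of real surveys (its rare tail is
~10% of ASVs, not ~75%). Passing the recovery tests therefore shows the
pipeline extracts planted block-plus-noise seasonal structure at
realistic depth and sparsity — not that it resolves every failure mode
of real amplicon data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 50 random 30×12 tables
for the PCoA↔PCA oracle; 20 random 20-node adjacencies for the TOM
oracle; 100 random instances with n ≤ 9, k ≤ 3 for the k-means
enumeration oracle (the oracle comparison uses a high restart count,
since the check targets the optimum of the WSS objective, not restart
luck); 10 generator seeds at 600 ASVs for module recovery (median
ARI ≥ 0.8) and 10 seeds at noise 0.1 without the pulse for ecotype
recovery (median ARI ≥ 0.9, k = 4 chosen in ≥ 8/10); 500 reps × 199
permutations for PERMANOVA type-I calibration and 200 reps × 199 for
envfit; and one full default-seed pipeline run for the end-to-end check
(4 qualified ecotypes, window boundaries within ±3 days, 2-sample
outlier rejected). On one core the whole suite runs in about a minute
and the acceptance script in a few minutes.

## Known limitations

- The hybrid module detector clusters TOM-dissimilarity rows; with a
  coherent low-variance background, the background forms its own
  "module", which the qualification stage then rejects on functional
  grounds rather than the detector suppressing it.
- NMDS accepts only stress-decreasing steps; on pathological inputs it
  may stop early with `converged=False` rather than escape a plateau.
- PERMANOVA is one-factor with free permutation; there is no strata or
  repeated-measures support, and no dispersion (betadisper-style) test.
- Trait inference itself (copy numbers, doubling times, genome sizes)
  is upstream of this package; trait tables are taken as given inputs.
- The toroidal hex geometry is exact only for even row counts.
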