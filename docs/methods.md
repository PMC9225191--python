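# Methods

This note documents the models, estimators and numerical choices behind
`arvicola`, a landscape-genetics toolkit for microsatellite data from
small-mammal demes (local breeding populations) embedded in a variegated
agricultural landscape. It also describes what the synthetic-data generator
does and does not emulate, so that the meaning of a passing test suite is
clear.

## Data model

A `GenotypeDataset` holds diploid multilocus genotypes. Allele codes are
kept verbatim (fragment sizes in base pairs); a call is either two positive
codes or wholly missing (`0/0`). Half-missing calls are rejected as
malformed, reflecting how microsatellite scoring produces both alleles or
neither. Deme metadata (planar UTM-style coordinates in metres, plot area,
sampling date) comes from a CSV whose row order authoritatively defines
deme indices; Genepop `POP` order must match.

## Diversity statistics

Per deme and locus, with missing calls excluded pairwise (per locus, never
individual-wise):

- **H_O** — fraction of heterozygous non-missing calls, averaged over loci.
- **H_E** — Nei's unbiased estimator `(2n/(2n-1)) (1 - sum p^2)`, averaged
  over loci.
- **N_A** — mean number of distinct alleles per locus.
- **A_R** — allelic richness rarefied to `g` gene copies by the
  hypergeometric formula `sum_a [1 - C(2n - N_a, g)/C(2n, g)]`. The default
  `g` is twice the smallest per-(deme, locus) sample, which makes `A_R`
  exactly equal `N_A` in the deme that sets the minimum — a useful internal
  consistency check.
- **F_IS** — the single-sample Weir–Cockerham `f`, i.e.
  `1 - sum c / sum (b + c)` over alleles and loci, with the within-sample
  components `b` and `c` from the variance-component decomposition. A
  two-sided permutation test (gene copies shuffled among individuals within
  the deme) is available separately.
- **HWE p per deme** — per-locus exact tests combined across loci by
  Fisher's method.

## F-statistics

Differentiation uses Weir & Cockerham's theta. Variance components `a`
(among demes), `b` (among individuals within demes) and `c` (within
individuals) are summed over alleles and loci; the multilocus estimate is
`sum a / sum (a + b + c)` — a ratio of sums, not a mean of per-locus
ratios. Negative estimates are reported as computed; truncating them at
zero would bias the downstream matrix regressions. Pairwise p-values come
from permuting individuals between the two demes (one-sided, add-one rule,
so p is never 0); the overall estimate carries a percentile bootstrap CI
over loci (default 1000 replicates). `F_ST/(1 - F_ST)` linearisation passes
negative values through unchanged.

## Exact Hardy–Weinberg and linkage tests

The HWE test orders genotype tables by their conditional (Levene)
probability given the allele counts. When the number of tables with the
observed margins stays below 1e5 the distribution is enumerated completely
(recursive margin-constrained enumeration); otherwise tables are sampled by
randomly pairing the observed gene copies, which draws from exactly the
conditional distribution, and the add-one Monte-Carlo rule is applied.

Genotypic linkage disequilibrium between two loci is tested per deme with
the log-likelihood-ratio G statistic on the genotype-by-genotype
contingency table, its null obtained by permuting one locus's genotypes
among the deme's individuals; per-deme p-values are combined by Fisher's
method. The locus filter tests all pairs, visits significant pairs in
ascending-p order and drops the member with fewer distinct alleles (ties:
the later locus in file order), mirroring standard practice of removing
redundant linked markers before structure analyses. The filter's
permutation count must resolve finer than its alpha (default 2000
permutations for alpha = 0.001).

## Landscape model

Land cover is a grid of nine categories; a cost-value map assigns each
category a movement cost (defaults: 1 for meadows/orchards/grasslands, 25
for annual crops and shrubs, 50 for settlements and roads, 1000 for
deciduous woodlots, eucalyptus and water). Least-cost paths run on the
8-neighbour lattice with move cost `cell_size * d * (CV_i + CV_j)/2`
(`d = sqrt(2)` for diagonals), computed by Dijkstra with a deterministic
lexicographic tie-break. Three pairwise deme distances derive from the LCP:

- **Effective distance** — the metric path length in metres; with a DEM each
  step becomes the 3-D hypotenuse.
- **Resistance distance** — `sum_i m_i CV_i` with `m_i` the length of the
  path's run through category `i` **in kilometres**. Each move's length is
  split half-and-half between its endpoint cells' categories, so the `m_i`
  sum exactly to the path length. Kilometres (not metres) keep the
  statistic on the magnitude conventionally reported for this model;
  metre-lengths would inflate it by three orders.
- **Euclidean distance** — planar straight-line km (single UTM zone; no
  geodesy).

**Landscape suitability** of a deme pair is the fraction of
suitable-habitat cells (meadow, orchard, pasture) among cells whose centres
fall in the lens-shaped intersection of two discs — each centred on one
deme with radius equal to the pair's Euclidean distance — divided by that
distance in km. Deme locations snap to the nearest cell centre (ties toward
smaller indices).

Grids use the ESRI ASCII (.asc) convention: row 0 is the northern edge,
the georeference origin is the lower-left corner. NoData cells are not
supported in category grids and raise at load.

## Clustering

The no-admixture mixture model: each individual belongs to one of `K`
clusters; its genotypes are independent HWE draws from the cluster's allele
frequencies. A Gibbs sampler alternates Dirichlet(1 + counts) frequency
draws with categorical assignment draws; assignment probabilities are the
Rao-Blackwellised average of the per-sweep conditionals after burn-in. The
no-admixture form was chosen because the deme-level deliverables (labels,
membership matrix, AMOVA grouping) need modal assignments only; admixture
proportions would add MCMC cost without changing any downstream table.

Log model evidence is estimated as `mean(logL) - var(logL)/2` over
post-burn-in sweeps; `Delta K` is the absolute second difference of the
mean evidence across replicate runs divided by its replicate SD. Label
switching is resolved only at comparison time by the best Hungarian
permutation of a confusion matrix, never inside the sampler. Defaults
(20 000 sweeps, 5 000 burn-in; tests and the pipeline use a few hundred to
a few thousand) are deliberately far below classic half-million-sweep
practice; on datasets of this size (~140 individuals, ~11 loci) the
sampler mixes in tens of sweeps and replicate evidence SDs are small.

## AMOVA

Allele-identity (infinite-alleles) distances between gene copies — 0 for
the same allele code, 1 otherwise — are decomposed over four nested strata:
among clusters, among demes within clusters, among individuals within
demes, and within individuals. Although only the first three are usually
tabulated, the fourth is required for percentages that sum to 100. Sums of
squares come from the standard `T(S) = (n^2 - sum m_k^2)/(2n)` identity on
allele counts; variance components solve the expected-mean-square equations
with unbalanced-design coefficients (2 gene copies per present individual;
per-locus missing drops whole individuals at that locus). Fixation indices:
`F_CT = s_a/total`, `F_SC = s_b/(s_b+s_c+s_d)`, `F_IS = s_c/(s_c+s_d)`,
`F_IT = (s_a+s_b+s_c)/total`. Permutation schemes: whole demes among
clusters (F_CT), individuals among demes within clusters (F_SC), and gene
copies among individuals within demes (F_IS) — the third is the only
scheme that perturbs the within-deme component being tested.

## Mantel suite

Mantel r is the Pearson correlation over the strict lower triangle; the
null permutes rows and columns of the second matrix simultaneously.
P-values are one-sided in the direction of the observed r by default
(two-sided by flag). The partial Mantel statistic is the first-order
partial correlation of the triangle vectors; its null permutes the
residuals of the focal matrix on the conditioning matrix (residual
permutation). Conditioning a matrix on itself returns r = 0 by definition;
other perfectly collinear cases are NA. Landscape predictor matrices enter
on a decimal-log scale; the binary cluster-membership matrix (1 for
same-cluster deme pairs) enters untransformed. Reduced major axis
regression (`slope = sign(r) sd(y)/sd(x)`, line through the means)
summarises slopes, treating both axes as error-prone.

## Spatial autocorrelation

Individual pairwise squared genetic distances use the standard codominant
microsatellite metric (per-locus values 0/1/2/3/4 for shared-allele
configurations, summed over loci; missing genotypes contribute 0). The
distance matrix is Gower-centred to a covariance matrix `c`; for distance
class `h` with pair set `P(h)`,

    r(h) = 2 * sum_{(i,j) in P(h)} c_ij / sum_{(i,j) in P(h)} (c_ii + c_jj).

Classes are half-open 100-m bins by default; individuals inherit their
deme's coordinates unless per-individual coordinates are supplied, so
same-deme pairs land in the first class and self-pairs are excluded. The
95% null band comes from permuting genotypes among individuals (999 by
default); the 95% CI from bootstrapping pairs within class (1000). No
omnibus multi-class heterogeneity test is computed (reported as NA): the
single published omnibus p for this analysis type does not identify its
method, so none is imitated.

## Migrant detection

`L_home` is the product over loci of HWE genotype probabilities under the
individual's deme of capture, with leave-one-out allele frequencies (the
focal individual's own alleles removed) and a floor frequency (default
0.01) for alleles absent from the deme. The significance null resamples,
per deme, `n_mc` genotypes by drawing two **distinct** gene copies per
locus from the deme's observed copy pool and scoring them with the same
leave-out adjustment. This exchangeability construction is deliberate:
scoring observed individuals leave-one-out against a null simulated from
plug-in frequencies is strongly anti-conservative at `n ~ 11-18` (measured
flag rate 0.21 at alpha 0.01 in panmictic simulations), while the
pool-resampling null is calibrated (measured 0.010). An individual is
flagged when its score falls beyond the alpha tail (default alpha 0.01,
10 000 simulations). The genetically closest deme (highest likelihood) is
reported descriptively for flagged individuals, without a test.

## Synthetic data generator

The generator provides known-truth inputs for every stage:

- **Landscape** — seeded region growth: Poisson seed points (one per
  `patch_scale^2` cells), cells labelled by nearest seed, seed categories
  drawn from the requested mixture. Defaults give a fine-grained mosaic
  with ~30% suitable habitat on a 100-m cell grid. Realized proportions
  track requests within ~5 points on grids a few hundred cells a side.
- **Genotypes** — forward Wright–Fisher demes of `N_e` diploids: each new
  gene copy picks a parent deme from the migration matrix row, a uniform
  parent there, one of its two alleles, and mutates stepwise (+-1 repeat,
  rate 5e-4) with allele states offset to fragment-size-like integers.
  Migration models: island, linear stepping-stone, and cost-decay
  `m_ij = m0 exp(-c * d_ij)` with the row scaled down only if total
  emigration would exceed `m0` (the cap preserves the absolute distance
  scale of gene flow).
- **Study-shaped fixture** — ten demes at the published orchard
  coordinates with the published sample sizes (137 individuals), 11 loci,
  cost-decay migration driven by least-cost-path distances (km) across a
  generated mosaic. Defaults `m0 = 0.15`, `c = 0.3 per km`,
  `N_e = 100`, 150 generations were chosen once so the realized structure
  sits in the intended regime — pairwise theta roughly 0 to 0.3 with a
  strong isolation-by-distance signal — and verified across independent
  landscape seeds (overall theta 0.07-0.14, Mantel IBD r 0.73-0.83).

Non-equilibrium sampling is intentional (150 generations from a common
ancestral pool); the truth object records the horizon. The generator does
not emulate demographic cycles or outbreaks, sex-biased dispersal,
kin-structured trapping, null alleles or genotyping error. Passing tests
therefore demonstrate correctness of the estimators and the pipeline's
ability to recover known spatial-genetic structure — not robustness to
those real-data complications.

The island-model equilibrium used in parameter-recovery tests is
`theta = 1/(1 + 4 N_e m d/(d-1))`, derived from the structured coalescent
for the quantity Weir–Cockerham theta estimates (`1 - T_w/T_b`, with
`T_w = 2 N_e d` and `T_b = T_w + (d-1)/(2m)`). Identity-based F_ST
definitions carry an extra `d/(d-1)` factor; the two converge as the number
of demes grows.

## Numerical conventions

- All permutation/Monte-Carlo p-values use the add-one rule and are never 0.
- Every stochastic routine takes an explicit seed; the pipeline derives
  per-stage seeds from the master seed by hashing the stage name, so stage
  results are independent and byte-reproducible.
- Dijkstra ties break toward the lexicographically smaller cell;
  deme-to-cell snapping ties toward smaller indices; tied cluster labels
  take the lower index (logged).
- Matrix triangles exclude the diagonal everywhere; suitability has an NA
  diagonal by construction.

## Problem sizes in the shipped tests

Oracle-equivalence suites run on 1000 random grids (LCP vs an independent
Dijkstra), exhaustive 4x4 Mantel enumeration, brute-force AMOVA
decomposition and a from-scratch autocorrelation formula. Calibration
suites use 150-300 null replicates per test (binomial 3-SE bands).
Parameter recovery uses a two-island simulation (60 individuals, 20 loci)
for Delta-K, 20 replicates for the island closed form, 50 replicates for
stepping-stone IBD recovery, and 20 replicates for the cost-barrier
contrast. These sizes were chosen to keep the whole suite comfortably
inside a desk-scale run while leaving the statistical bands meaningful.

## Known limitations

- The resistance distance is evaluated along the least-cost path only; no
  circuit-theory (all-paths) resistance.
- The clustering model ignores admixture and spatial priors; on real data
  with gradual clines it will favour fewer, sharper clusters than
  admixture-aware samplers.
- The lens suitability uses cell-centre membership, so very narrow lenses
  (nearly collinear close pairs) can contain few cells and be noisy.
- Coordinates are planar metres in one zone; datasets spanning zone
  boundaries must be re-projected upstream.
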