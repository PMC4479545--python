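# Methods

`delimix` implements a comparative species-delimitation analysis: one
identical ordination-plus-clustering procedure applied to four datasets
(mtDNA sequence, nuclear SNPs, quantitative phenotype, climate at
specimen localities), followed by cross-dataset congruence, geographic
contiguity screening, introgression tests, and an allometric ANCOVA.
The package ships a synthetic-data generator with known truth so that
every stage is verifiable without downloading anything. This note
records the models, the tunable parameters, the numerical choices, and
what the synthetic worlds do and do not show about real data.

## The shared clustering procedure

Every dataset is reduced to a numeric specimen-by-feature matrix,
ordinated by PCA on the correlation matrix (all variables standardized
to mean 0, sd 1), and clustered on the retained principal components
with Gaussian mixture models fitted by EM and compared by BIC.

**Encoding.** mtDNA alignments are reduced to haploid 0/1 loci at sites
biallelic among unambiguous bases; gaps, N, and IUPAC ambiguity codes
count as missing; the majority allele is coded 0 (ties broken
alphabetically — PCA is polarity-invariant up to sign, so the choice
only fixes reproducibility). SNP matrices are 0/1/2 alternate-allele
counts. Missing genotypes are replaced by the column mean of observed
codes; loci with no observations are an error, and columns constant
after encoding are dropped and logged. Phenotype encoding passes 18
meristic counts through unchanged (bilaterally counted characters are
averaged; one observed side is used when the other is missing) and
replaces the 9 morphometrics with residuals of log10(trait) on
log10(body length) from a single pooled OLS fit — pooled because the
size correction precedes any grouping — for 27 quantitative columns;
body length itself is excluded. Climate uses the 19 bioclim-style
variables with precipitation-type columns log10(x+1)-transformed
(x+1 rather than x because zero-rainfall values occur in deserts).

**Axis retention.** Components explaining strictly more than 5% of
total variance are retained (never none: axis 1 is kept even in
degenerate cases, since clustering needs at least one dimension). For
molecular datasets, any retained axis whose scores correlate with the
per-specimen missing-data fraction at |r| >= 0.7 is removed: missing
data can masquerade as population structure on leading axes. The 0.7
threshold is deliberately conservative — it flags only axes that are
essentially missingness gradients.

**Mixture engine.** Six covariance families are searched, named by the
volume/shape/orientation scheme of the model-based-clustering
literature: EII, VII (spherical; equal/varying volume), EEI, VVI
(diagonal), EEE, VVV (full). Parameter counts are
(K−1) + K·d + {1, K, d, K·d, d(d+1)/2, K·d(d+1)/2} respectively. Each
(K, family) cell is fitted by EM from seeded k-means++ starts
(default 10 restarts, tolerance 1e-6 on the log-likelihood increase,
at most 500 iterations), and the grid (default K = 1..12) is scored by
BIC = 2·loglik − m·ln(n), maximized; ties within 1e-9 go to smaller K,
then fewer parameters. The full BIC table is always reported so
sensitivity to the lattice is explicit rather than guessed.

Two regularizations guard against the unbounded-likelihood pathology of
mixture ML. First, every covariance estimate is floored: diagonal and
spherical variances are clipped at 1e-8, and full matrices get +1e-8·I
each M-step. Second, a fitted solution is flagged *singular* — recorded
in the BIC table but never selected — when a covariance eigenvalue sits
at the floor or when a component's effective membership falls below
d + 2 observations. Without the second guard, BIC maximization latches
onto two-point components with near-zero variance and systematically
over-selects K; with it, selection behaves like the mclust practice of
reporting such cells as failures. `em_fit` still returns flagged fits
(useful for degenerate point-mass inputs); only model selection skips
them.

**Classification.** Labels are argmax posterior, renumbered 1..K by
descending cluster size; classification uncertainty is 1 − max
posterior (bounded by 1 − 1/K).

## Spatial thinning and consensus (climate only)

Occurrence records oversample roadsides and collections hot-spots, so
the climate dataset is clustered through a bias correction: a square
grid of 0.5 arc-minutes (configurable), anchored at the minimum
lon/lat of the data extent (the anchor is recorded in the output), one
specimen drawn uniformly per occupied cell, clustering run on the
subsample, and the whole procedure repeated (default 1000 replicates;
tests and the acceptance script use 25–50, which is enough for a
stable modal K on worlds of 60 specimens). Points on a cell boundary
belong to the higher-index cell. Replicate RNG streams are spawned from
the master seed by replicate index, so any single replicate is
reproducible in isolation.

How to combine 1000 partitions into one is a genuinely open design
point; we use standard consensus-clustering machinery. Each replicate's
fitted model classifies *all* specimens (not just the thinned subset),
which makes the pairwise co-assignment frequency well defined even for
specimens sharing a grid cell (such pairs are never co-sampled). The
final partition is an average-linkage hierarchical cut of
(1 − co-assignment) into the modal K (modal over replicates; ties to
smaller K), and a specimen's uncertainty is 1 minus its mean
co-assignment with its own group.

## Congruence, contiguity, and delimitation

Partitions are compared by the Hubert–Arabie adjusted Rand index.
The species rule is conservative: specimens joined by an edge when
co-clustered in at least `min_support` datasets (default 2, "two or
more data sources"), connected components become candidate species
groups, and every group is screened for geographic contiguity —
failures are flagged, not dissolved.

Contiguity is formalized as connectivity on a pruned Delaunay graph:
triangulate all specimen localities (plain geographic degrees — no
projection, matching the analysis scale of a few degrees), drop edges
longer than the 95th percentile, induce the subgraph on the cluster's
members, and score 1 − (components − 1)/(members − 1); the flag is
score >= 0.9. Islands within the pruning length of the mainland remain
connected, which is the desired behavior for near-shore insular
populations. Fewer than three localities fall back to a complete graph.

Diffuse-cluster merging handles the situation where one biological
population is split into overlapping, uncertain clusters: two clusters
merge when the mean classification uncertainty over their union exceeds
0.25 *and* their locality convex hulls overlap by more than 20% of the
smaller hull, iterated to a fixed point with every merge logged. Both
thresholds are exposed configuration, not claims about any particular
empirical dataset; uncertain-but-allopatric clusters are never merged.

## Introgression (ABBA–BABA)

For a quartet (P1, P2, P3, O) of single diploid representatives,
per-site weights are abba = (1−p1)p2p3(1−p4) and
baba = p1(1−p2)p3(1−p4) on derived-allele frequencies (genotype/2),
polarized by the outgroup: O's major allele is ancestral, sites with a
heterozygous O are excluded (a single-individual outgroup carries no
polarity information there), and sites with any missing member are
dropped. D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA), undefined (NaN, not an
exception) when the denominator is zero. Significance uses a delete-m_j
block jackknife over 50 contiguous blocks in locus order with the
weighted variance of Busing et al. (the convention of ADMIXTOOLS);
Z = D/SE and p is two-sided normal, flagged at p <= 0.001 in the
battery output. Fewer informative sites than blocks reduces the block
count to ⌊sites/5⌋; an SE of zero (identical blocks) is reported as
Z = ±inf, p = 0.

Null calibration is excellent (simulated sd(Z) ≈ 1.0; |Z| < 3 in
>~99% of no-gene-flow worlds). Power, however, is physically limited at
desk scale: with 5000 unlinked SNPs and single diploid representatives
the total informative ABBA+BABA weight is a few hundred, which bounds
the attainable |Z| near D·√W ≈ 2.5 at a 15% admixture pulse. A
coalescent cross-check (msprime, same D machinery) reproduces the same
ceiling, so detecting γ = 0.15 at |Z| > 3 is unreliable at these locus
counts — a limitation of the statistic at this data scale, not of the
implementation. Mean D̂ is monotone in γ, and larger pulses or more
loci push Z over the threshold.

## Allometric ANCOVA

The homogeneity-of-slopes test compares a full per-group
slope+intercept regression of log10(head size) on log10(rattle size)
(any two positive trait columns; log10 is the default and can be
disabled) against a common-slope reduced model:
F = ((RSS_r − RSS_f)/(g−1)) / (RSS_f/(n−2g)). Groups need at least 3
points and nonzero x-variance. Fits go through statsmodels OLS; the
test suite checks F against an explicit normal-equations computation
and against the squared interaction t-statistic for two balanced
groups.

## The synthetic world

The generator's defaults are the package's reference study conditions:
four lineages on a balanced tree ((1,2),(3,4)), Balding–Nichols drift
c = 0.25 per branch, 15 specimens per lineage, 1000 SNP loci with 5%
missing genotypes, a 590 bp mtDNA alignment at 0.01
substitutions/site/branch (Jukes–Cantor, with a 0.1-length
within-population star phase), and ranges laid out west to east as
tall ellipses. Meristic means shift by 4 counts per lineage index
(divergence of the order seen between rattlesnake subspecies for scale
counts) and allometric intercepts by 0.04 in log10 units; the residual
sd on log10 morphometrics is 0.02.

Climate is generated from two latent landscape fields: a
temperature-like regime step T = tanh((coordinate − boundary)/0.3°) and
a precipitation-like field P (a Gaussian "monsoon" bump centered off
the southeastern corner of the extent plus a weak latitudinal
gradient). Nineteen variables are fixed linear mixtures — 11
temperature-type loading mainly on T, 8 precipitation-type mainly on P,
passed through a softplus to stay non-negative — plus Gaussian noise
(sd 0.25 in latent units). In the **crossing** scenario the T boundary
is latitudinal, orthogonal to the lineage ranges, so every lineage
straddles both climate regions and climate clusters cannot coincide
with lineages; in **aligned** it is longitudinal and coincides with the
boundary between the second and third lineages (the analog of a
midpeninsular divide). `truth_climate` is the sign of the latent T
field. The step is sharp and the P field weak relative to noise by
design: the climate regimes are discrete regimes, the situation the
comparison targets, and P structures the second PC axis without
manufacturing spurious clusters.

For introgression testing a separate quartet world uses the
caterpillar topology (((P1,P2),P3),O), two specimens per population,
no missingness, and a per-branch drift profile (0.5 and 0.3 on the
internal branches, 0.2 on the P1/P2 tips, 0.5 on P3 and O) that
represents deep, well-supported splits with shallower sister tips.
Admixture is a frequency-level pulse: the recipient tip frequency
becomes (1−γ)·own + γ·donor, which gives an analytically predictable
E[D] direction.

**What the worlds do not emulate.** Balding–Nichols drift is not a
coalescent: no linkage, no recombination, no shared gene trees, and
within-population mtDNA genealogy is a star. Climate variables have a
two-factor covariance, not WorldClim's empirical structure, and
localities are uniform within ellipses rather than road-biased (the
thinning machinery is therefore validated by construction — duplication
invariance — rather than by realistic bias). Passing tests demonstrate
that the *procedure* behaves as designed under known truth; they do not
certify recovery rates on real specimen data.

## Problem sizes used in tests and the acceptance script

The shipped experiments use the reference conditions above with 20
seeds for the signal-contrast medians, 20 seeds each for the mixture
model-recovery rates (3 well-separated blobs at Δ/σ = 10, and a single
n = 200 cloud with K_max = 4, 300 EM iterations), 200 simulations each
for the D-statistic null and power rates at 5000 loci, 50 consensus
replicates for the thinning-duplication check, and one full
compare-signal run (25 consensus replicates) for end-to-end species
recovery. These sizes give stable medians and rates while keeping a
full run in the minutes range on one CPU; the library defaults (1000
replicates, 10 restarts, K_max 12) remain the recommended settings for
real analyses.

## Known limitations

* D-statistic power at small locus counts, discussed above.
* The six-family lattice spans sphere/diagonal/full ×
  equal/varying but not the rotation-constrained intermediate families
  of the full model-based-clustering taxonomy; the BIC table makes any
  resulting sensitivity visible.
* Consensus aggregation (co-assignment + average linkage) is one
  defensible choice among several; it is isolated behind
  `consensus_cluster` and swappable.
* Geographic computations use plain decimal degrees; at continental
  scales or high latitudes a projected or ellipsoidal treatment would
  be preferable.
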