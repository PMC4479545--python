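# delimix

**Do climatic data carry taxonomic signal?** `delimix` is a toolkit for
comparative species delimitation: it applies one identical
ordination-plus-clustering procedure to genetic (mtDNA, nuclear SNPs),
phenotypic, and climatic datasets from the same specimens, quantifies
how well the resulting partitions agree, and delimits species as the
groups supported by two or more *intrinsic* (heritable) data sources
that are also geographically contiguous. It is written for
systematists and population geneticists who want the
climate-as-proxy assumption tested rather than assumed: if the climate
partition tracks regional climate regimes instead of any genetic or
phenotypic grouping, climatic envelopes are measuring geography, not
taxonomy.

## What is inside

* **One shared procedure** per dataset: encode → correlation-matrix PCA
  → retain axes explaining > 5% of variance (screening axes that
  correlate with missing-data fraction, |r| ≥ 0.7) → Gaussian mixture
  model selection by BIC = 2·logL − m·ln n over six covariance families
  (EII/VII/EEI/VVI/EEE/VVV, i.e. spherical/diagonal/full ×
  equal/varying volume), EM-fitted from seeded k-means++ restarts, with
  per-specimen classification uncertainty 1 − max posterior.
* **Spatial sampling-bias correction** for climate: thin occurrences to
  one per 0.5-arc-minute grid cell, cluster, repeat (default 1000
  replicates), and combine replicates through a co-assignment
  consensus.
* **Congruence and delimitation**: pairwise adjusted Rand indices,
  diffuse-cluster merging (high cross-pair uncertainty + overlapping
  ranges), ≥2-dataset co-assignment groups, and geographic contiguity
  on a pruned Delaunay graph.
* **Introgression tests**: four-taxon Patterson's D,
  D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA) with
  abba = (1−p₁)p₂p₃(1−p₄), baba = p₁(1−p₂)p₃(1−p₄), polarized by the
  outgroup's major allele, with delete-m_j block-jackknife Z and p.
* **Allometric ANCOVA**: homogeneity-of-slopes F-test on log-log
  trait regressions between delimited groups.
* **A synthetic world generator** (Balding–Nichols SNP drift,
  Jukes–Cantor mtDNA, Poisson meristics + log-linear allometry,
  ellipse ranges, and a two-field climate landscape whose regime
  boundary either crosses or aligns with the lineage ranges) with known
  lineage and climate-region truth, so every stage is testable.

## Worked example

```python
from delimix import RunConfig, SimConfig, run_compare_signal, sim_world

world = sim_world(SimConfig(seed=1))          # 4 lineages, crossing climate
result = run_compare_signal(
    {"mtdna": world.alignment, "snp": world.snps,
     "phenotype": world.traits, "climate": world.climate},
    world.localities,
    config=RunConfig(K_max=8, restarts=4, reps=30, seed=1),
)
print(result.manifest["selected_K"])
print(result.congruence.to_frame().round(3))
```

prints

```
{'mtdna': 5, 'snp': 4, 'phenotype': 4, 'climate': 2}
           mtdna    snp  phenotype  climate
mtdna      1.000  0.908      0.861    0.048
snp        0.908  1.000      0.955    0.040
phenotype  0.861  0.955      1.000    0.034
climate    0.048  0.040      0.034    1.000
```

The three intrinsic datasets select 4–5 clusters that agree with each
other (ARI 0.86–0.96; mtDNA's extra cluster is within-lineage
mitochondrial structure), while the climate partition (K = 2, the two
climate regimes) is incongruent with all of them (ARI ≤ 0.04). The
species hypothesis from the intrinsic partitions recovers the four true
lineages exactly, each supported by at least two datasets and
geographically contiguous. The `examples/` directory holds one short
script per capability (simulation, single-dataset clustering, climate
thinning, delimitation, D-statistics, allometry).

A thin CLI mirrors the library:
`delimix simulate | cluster | thin-consensus | congruence | dstat |
allometry | compare-signal` (see `delimix --help`).

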