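# cryptotyper

Delimitation of pseudo-cryptic species in planktonic foraminifera from
molecular, ecological and morphometric evidence.

Planktonic foraminiferal morpho-species — defined on shell morphology and
used as paleoceanographic proxies — often hide several genetically distinct
sibling species with different ecologies. `cryptotyper` implements, as a
tested and reusable pipeline, the multi-stage analysis by which such a
morpho-species is split into two pseudo-cryptic species:

1. **Molecular genotyping** — rDNA clone libraries (SSU/ITS), majority-rule
   consensus sequences, synapomorphy/autapomorphy diagnosis of atypical
   individuals, and an in-silico RFLP assay (BstNI, motif CC/WGG: the warm
   genotype's ITS amplicon is cut into a ~400 + ~600 bp pattern, the cold
   genotype's is not cut).
2. **Patristic-distance delimitation** — p-distance matrices, deterministic
   neighbor-joining with nonparametric bootstrap, patristic distances from
   any newick tree, and within/between-genotype summaries
   (median, 95% percentile interval, min, max). Two groups are delimited
   when min d(between) > max within-group 97.5th percentile (a barcode gap).
3. **Sampling sufficiency** — with q = (1 − p)^N, the largest undetected
   rare-genotype abundance at confidence c is p_max = 1 − (1 − c)^(1/N),
   justifying single-genotype treatment of unsequenced samples.
4. **Thermal niche** — inverse-angular-distance interpolation of a gridded
   13-depth (0–500 m) temperature climatology, correlation-matrix PCA of
   the depth temperatures (PC1 = mean thermal state of the water column),
   bin-mean PC1 vs SST regression, occurrence statistics of the
   morpho-species in core-top assemblages, and the genotype boundary
   temperature from plankton-tow stations.
5. **Biometrics** — two-group discriminant analysis on (log size,
   log aperture/chamber ratio) with Wilks' Λ = det(W)/det(T) and its exact
   F transform on (p, N − p − 1) df, plus Mann-Whitney U (reported as
   min(U, n₁n₂ − U)) and two-sample Kolmogorov–Smirnov tests and Gaussian
   kernel densities of the 1-D log-ratio descriptor.

A first-class synthetic-data module generates every input the pipeline
consumes — two-genotype clone libraries with an engineered diagnostic
restriction site, strictly allopatric stations across an 8–12 °C SST front,
a 1°-gridded temperature field with missing cells, core-top assemblages of
37 morpho-species, and two weakly separable morphometric populations — so
the whole analysis runs offline and every stage is testable against known
ground truth.

## Worked example

Run the full pipeline on synthetic inputs:

```bash
cryptotyper run --seed 1 --outdir run1
```

The run directory contains machine-readable tables (genotype calls,
distance summaries, sampling-power bounds, biometrics JSON, newick trees)
and a `report.md` whose core numbers, for seed 1, are:

```
## 2. RFLP genotyping
- concordance with generator labels: 100.0%
## 3. Patristic distances (p-distance NJ tree)
- within Type I:      median 4.600e-02 [2.118e-02, 5.552e-02] over 780 pairs
- within Type II:     median 5.500e-02 [2.593e-02, 6.800e-02] over 780 pairs
- Type I vs Type II:  median 1.360e-01 [1.260e-01, 1.490e-01] over 1600 pairs
- Type I / Type II split support: 100.0% (500 replicates)
## 4. Delimitation
- barcode gap: 5.3000e-02 -> two species supported: True
## 6. Thermal niche
- warm edge of Type II: 9.31 °C; cold edge of Type I: 9.64 °C; sympatry: False
## 7. Biometrics
- Wilks' λ = 0.845; F = 27.74; df = 2, 303; p = 8.7e-12
- correct classification: 67.6% (leave-one-out: 67.3%)
```

Reading: the in-silico digest recovers every true genotype; between-genotype
distances exceed within-genotype 97.5th percentiles (a barcode gap, so two
species); the genotype boundary falls inside the generating 8–12 °C front
with no sympatry; and shell morphometry separates the populations weakly
(≈ 2/3 correct) but highly significantly — the signature of pseudo-cryptic,
not fully cryptic, species.

Individual stages are available as library functions
(`cryptotyper.rflp.digest`, `cryptotyper.phylo.delimit`,
`cryptotyper.thermal_niche.thermal_pca`, ...) and as CLI subcommands
(`simulate`, `rflp`, `consensus`, `classify-sites`, `merge-alignments`,
`tree`, `patristics`, `delimit`, `sampling-power`, `niche-pca`, `boundary`,
`biometrics`).

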