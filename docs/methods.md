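# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, the assumptions of the synthetic-data
generators, and the limits of what passing tests demonstrate.

## The problem

A planktonic foraminiferal morpho-species is suspected to be a complex of
two pseudo-cryptic species. The pipeline assembles the independent lines of
evidence used to test that hypothesis: (1) rDNA sequence clustering and a
diagnostic restriction digest; (2) patristic-distance statistics showing a
barcode gap between the two sequence clusters; (3) a probability argument
that single-genotype samples are not a sampling artifact; (4) water-column
thermal structure versus occupancy, locating the biogeographic boundary on
an SST front; and (5) a weak but significant morphometric discrimination of
the two populations.

## Molecular genotyping

**In-silico RFLP.** The BstNI assay digests the ITS amplicon at CC/WGG
(W = A or T), cut offset 2 from the motif start. Motif matching is
IUPAC-aware with subset semantics: a sequence position matches a motif
symbol only when the sequence symbol's base set is contained in the motif
symbol's set, so a reported site is guaranteed to cut under any
disambiguation (an N in the amplicon never fabricates a site). Amplicons
are linear; only top-strand cut coordinates are reported. Because the
recognition set is its own reverse complement but the cut offset is
asymmetric (2 of 5), recognition sites mirror exactly under reverse
complementation while the two terminal fragments shift by 1 bp — invisible
on an agarose gel, and asserted at exactly that precision in the tests.
Genotype calling is lenient by default (>= 2 fragments = cut = Type I;
single full-length fragment = Type II); a strict mode additionally requires
the two largest bands within a tolerance (default 100 bp) of the canonical
400/600 bp pattern.

**Consensus alignment masking.** Two alignments of the same sequences
(e.g. manual and automatic) are reconciled by homology statements: a column
is described by the map from sequence id to the 0-based index of its
residue in the ungapped sequence (gap = absent). Columns of the first
alignment whose statement recurs anywhere in the second are kept, in first-
alignment order; all others are treated as ambiguous and dropped. This is
the only alignment-order-free definition of "the same column". A merge with
zero concordant columns is an error. Idempotence (re-merging changes
nothing) holds whenever the merge drops no residue-bearing column;
otherwise the merged rows are no longer the same sequences and the
precondition rejects the re-merge.

**Consensus sequences and site classification.** Group consensus at
threshold t (default 0.6, the conventional majority level) emits the most
frequent non-gap residue when its frequency over the group size (gaps count
in the denominator) reaches t, else N. Site classification of a query row
against two group consensuses considers only columns where the mask is
true, both consensuses are called and the query holds a residue: if the
consensuses differ, agreement with one group is a synapomorphy with it; a
state differing from both is an autapomorphy. Whether autapomorphies are
also counted at columns where the two consensuses agree is ambiguous in
descriptive use; both rules are implemented (`strict_autapomorphy`), with
the inclusive rule as default.

## Distances, trees and delimitation

**p-distances.** Observed (uncorrected) proportions of differing sites with
pairwise deletion of columns holding a gap or any ambiguity code, computed
over retained columns only. A pair with zero comparable sites is an error
naming the pair.

**Neighbor joining.** Standard Saitou–Nei Q-criterion agglomeration,
implemented in-repo to guarantee determinism: ties on Q are broken toward
the lowest (row, column) index in the current active ordering, and negative
branch lengths are clamped to zero with the clamped deficit recorded on the
returned tree. On additive matrices NJ reconstructs the generating tree and
the patristic round trip is exact to 1e-9 (tested on random additive
matrices against a brute-force path-sum oracle). NJ here stands in for the
externally computed maximum-likelihood trees of a real analysis; any
newick tree can be ingested for the patristic statistics instead, with
bootstrap supports read from internal node labels, plain comments, or
`[&support=...]`-style annotations.

**Bootstrap.** Nonparametric: retained columns resampled with replacement
per pseudo-replicate (default 500), trees rebuilt with the same builder,
support = percent of replicates containing each original internal
bipartition. The resampling stream is a seeded PCG64 generator, so supports
are reproducible across runs and platforms.

**Summary statistics.** For a set of pairwise distances the summary is
median, 2.5th/97.5th percentiles (linear interpolation), min, max and pair
count. The "95% nonparametric confidence interval" is read as the central
95% percentile band of the pooled pairwise-distance distribution — the
published intervals span nearly min–max, which is inconsistent with a
bootstrap-of-the-median reading. Pairs from n tips are not independent
(n(n−1)/2 pairs); no correction is applied since the use is descriptive.

**Delimitation.** Two groups are called distinct when the minimum
between-group distance exceeds both within-group 97.5th percentiles — a
barcode-gap criterion. The report carries all within/between summaries so
a borderline verdict can be inspected.

## Sampling sufficiency

With p the relative abundance of a rare genotype and N sampled individuals,
q = (1 − p)^N is the probability of having collected none; inverting at
confidence c gives p_max = 1 − (1 − c)^(1/N), the largest abundance still
consistent with observing none. These are exact inverses (tested to 1e-12)
and p_max ≈ −ln(1 − c)/N for large N. The station report gives p_max per
station and pooled per side of the front and flags the weakest (largest)
bound; no single "mixture probability" headline is emitted because that
quantity is not well-defined without a pooling convention.

## Thermal niche

**Grid and interpolation.** The temperature climatology lives on a
1° grid (cells keyed by the integer south-west corner, values at cell
centers; longitude wraps at ±180°), with 13 standard depths from 0 to
500 m. A missing locality × depth value is filled in one pass from the ≤ 8
surrounding cells by a weighted average with weight 1 / great-circle
angular distance between cell centers — read literally, so meridional and
zonal neighbors differ in weight at high latitude; planar 1/√2-degree
weights are available behind a flag. Only originally observed values feed
the fill (no cascading); a cell with all 8 neighbors missing stays missing
and is flagged.

**PCA.** Correlation-matrix PCA of the 13 depth temperatures: variables
z-scored (ddof = 1), eigendecomposition of the correlation matrix, so
eigenvalues sum to 13 and explained variances to 100%. Orientation is
deterministic: PC1 is flipped to correlate positively with the depth-mean
temperature (high PC1 = warm column); each higher component is flipped so
its deepest-depth loading is non-negative, which renders PC2 as the
conventional cold-surface/warm-subsurface contrast when such a mode exists.
Loadings are reported as correlations (eigenvector × √eigenvalue).

**PC1–SST regression.** Localities are binned by ⌊SST⌋ (SST = the 10 m
temperature); the regression of bin-mean PC1 uses bin centers as the
predictor over bins inside 0–25 °C, skipping empty bins. Bin centers rather
than bin-mean SST were chosen as the predictor (both are close at 1 °C
width); bin means and SDs are exported alongside.

**Boundary temperature.** Warm edge = max SST over stations bearing the
cold genotype; cold edge = min SST over stations bearing the warm genotype;
overlap (warm edge above cold edge) flags sympatry. Under strict allopatry
the interval brackets the front.

## Biometrics

Descriptors are natural logs: size = ln(major axis), size-normalized
apertural length = ln(aperture/terminal chamber), and the combined 1-D
descriptor ln(aperture/chamber) − ln(major axis). The two-group linear
discriminant uses the feature pair (log size, log ratio): Wilks'
Λ = det(W)/det(T) from within-group and total scatter; the exact two-group
F transform F = ((1 − Λ)/Λ)·((N − p − 1)/p) on (p, N − p − 1) degrees of
freedom (p = 2); classification by the Fisher axis w = S_w⁻¹(m₁ − m₂)
against the midpoint of the projected group means. The resubstitution rate
is the headline (matching how such rates are conventionally quoted); a
leave-one-out rate is reported alongside and runs a refit per held-out
specimen. Mann-Whitney U is reported direction-free as min(U, n₁n₂ − U),
with exact enumeration for tie-free samples of ≤ 20 per group and the
normal approximation otherwise; the two-sample Kolmogorov–Smirnov p-value
uses the asymptotic Kolmogorov distribution. Kernel densities are Gaussian,
default bandwidth by Silverman's rule, evaluated on a grid padded by 8
bandwidths so the curve integrates to 1 within 1e-6.

## Synthetic data: what it emulates and what it does not

All generators are bit-reproducible: each draws from its own stream spawned
from the config seed.

**Sequences.** Uniform (Jukes–Cantor-like) substitution from a random
ancestor; no rate heterogeneity, no indels, no coalescent structure. The
config divergences are expected p-distances at the level named:
between-type clone distance 0.14, individual-from-type-ancestor 0.02,
clone-from-individual 0.005 (ITS defaults; SSU rates scaled by 0.12).
The two type ancestors are separated by the between-type target minus the
within-type budget so realized clone-to-clone between-type distances track
the config value. A CC(A)GG site is engineered into every Type I ITS clone
with its first occurrence at 40% of the amplicon (earlier chance
occurrences ablated), and all occurrences are ablated from Type II clones —
the RFLP contrast is guaranteed by construction, not awaited from chance.
Genotype, specimen and station provenance travel in FASTA description
key=value fields. Consequences: tests prove the pipeline's logic, not the
adequacy of any substitution model; distances are honest p-distances but
their variance structure is simpler than real rDNA with concerted
evolution.

**Stations.** A jittered stratified SST transect over 1–24 °C (49 stations
by default), temperature profiles anchored so the 10 m value is the SST,
and a deep-chlorophyll-maximum-like fluorescence bump. Occupancy is
strictly allopatric across a hidden front drawn uniformly inside the 8–12 °C
band per seed. Real surveys have clustered stations, seasonal aliasing and
possible sympatry; none of that is emulated.

**Core-top grid.** 1° cells over latitudes −65..64 and a configurable
longitude span; temperature = exponential thermocline under a variable-depth
mixed layer, strictly non-increasing with depth by construction; the
mixed-layer mode is what loads on PC2. Exactly
⌊missing_fraction × n_localities × 13⌋ locality × depth couples are masked
(default fraction 0.0327). The focal species has a transitional thermal
optimum (relative abundance peaking near a 15 °C mean-column temperature
and vanishing at the extremes); 36 background species share the remainder
of a log-normal assemblage count via a Dirichlet-multinomial. Ocean
dynamics, fronts, preservation bias and spatial autocorrelation are not
modelled, so PCA variance fractions from the generator characterize the
generator, not the ocean.

**Morphometry.** Log-normal shared size (log-SD 0.18 around 450 µm),
group difference only in the log aperture/chamber ratio: ±δ/2 of its 0.16
dispersion, δ = 0.82 standardized by default — calibrated so a two-group
discriminant classifies ≈ 66% correctly at n = 154/152, with Wilks' Λ
averaging ≈ 0.85 (Λ = (1 + T²/(N−2))⁻¹ with T² = (n₁n₂/N)D², D = δ).
The north (warm-side) group carries the larger normalized aperture. No
allometry and no measurement-error model; the combined 1-D descriptor is
diluted by size dispersion, so its rank-test statistics are weaker than the
discriminant's separation.

## Problem sizes in the default runs

The end-to-end pipeline and the acceptance script run at the study's scale:
80 ITS + 80 SSU clones (20 individuals per type × 2 clones), 500 bootstrap
pseudo-replicates, 49 stations, 1265 core-top localities × 13 depths, and
306 morphometric specimens (154/152). Simulation-heavy tests use 100 seeds
for the discriminant envelope and boundary recovery and 2000 null
replicates for rank-test calibration.

## Known limitations

- NJ on p-distances replaces model-based ML trees; fine for distance
  summaries and split support on well-separated clusters, not for branch
  lengths under rate heterogeneity.
- The barcode-gap criterion is a fixed rule, not a model-based species
  delimitation; borderline gaps should be read from the full report.
- One-pass interpolation leaves isolated holes unfilled by design.
- The leave-one-out classification rate refits the scatter matrices per
  specimen and is O(N²) in specimens; adequate at N ≈ 300.
- Bootstrap support is attached only to bipartitions present in the
  full-data tree.
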