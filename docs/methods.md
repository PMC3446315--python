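# Methods

This note documents the models, parameter choices and numerical
conventions behind `medipkit`, and what the synthetic validation does and
does not establish about real data.

## Coordinates and containers

All coordinates are 0-based half-open (BED convention) everywhere.
Interval sets are pandas DataFrames (`chrom`, `start`, `end`, plus
`name`, `feature_class`, `strand`, `gene_id` where relevant); matrices
are feature × sample DataFrames wrapped with aligned feature and sample
metadata (`FeatureMethylationMatrix`).  Gene models carry an explicit
3'UTR length; the TSS is the 5' end by strand and the CDS is the gene
body minus the 3'UTR.

## Feature annotation

**CGI location subtypes.**  Each CpG island receives exactly one label
with precedence promoter > 3'UTR > intragenic > intergenic.  The
promoter window is [TSS − 1000, TSS + 500), strand-aware and
configurable; promoter status takes precedence because it is the
functionally dominant context when an island spans several.  An island
overlapping windows of several genes is linked to the gene with the
nearest TSS (logged).

**Shores.**  Two 2,000-bp flanks per island, clipped at chromosome ends,
with any bases inside another island subtracted — shores never contain
island bases, so total shore length is at most 4 kb per island.  Flanks
of two nearby islands may share the intervening gap; the shared bases are
counted in each flank but never re-enter an island.  Shores inherit the
parent island's location subtype.

**Promoter CpG classes.**  The promoter window [TSS − 700, TSS + 200) is
scanned with 500-bp sub-windows (50-bp step).  HCP: any sub-window with
GC ≥ 0.55 and CpG observed/expected ≥ 0.75; LCP: no sub-window reaches
o/e 0.48; ICP otherwise.  The o/e ratio is (#CpG × L) / (#C × #G) with
#C = #G = GC·L/2.  For synthetic genomes #C and #G derive from the
configured two-level GC track (island vs background GC) rather than
literal sequence; all four thresholds and the window geometry are
configurable.  Windows clipped short of 500 bp are classified on the
full window and logged.

## Coupling-factor normalization

Bins of 500 bp tile each chromosome at a 250-bp step (both configurable;
the step must not exceed the bin size or the tiling would leave gaps).
Reads are assigned to every bin containing their midpoint — on the
half-overlapping default grid a read lands in at most two bins and is
counted once on the non-overlapping half-grid, keeping counting
O(n log n) without double counting.  The coupling factor of a bin counts
CpGs within `max_distance` (default 500 bp, fragment scale) of the bin
boundaries.

The calibration curve is the mean rpm per integer CF level, with sparse
adjacent levels pooled until each calibration point has at least
`min_bins_per_level` (default 10) bins, taken from CF = 1 up to the
level of maximal mean signal (the ascending range).  A least-squares
line over that range summarizes the curve; a non-positive slope or fewer
than two usable levels raises an error, since the signal then shows no
CpG dependence and the correction would be meaningless.

The relative methylation score divides each bin's rpm by its
CF-expected signal and scales into [0, 1]:

    raw(b) = rpm(b) / max(ε, expected(CF_b)),   ε = 1e-6
    rms(b) = min(raw(b) / Q99(raw), 1)

The expected signal is the **interpolated empirical calibration curve**
(capped at the top of the ascending range), not the fitted straight
line: MeDIP capture efficiency saturates with CpG density, so a linear
expected value leaves a systematic density-dependent residual in the
score (measured residual |cor(rms, CF)| ≈ 0.12–0.15 on simulated data
versus < 0.04 with the interpolated curve).  The 99th percentile (rather
than the maximum) makes the [0, 1] scaling robust to outlier bins, and
makes the score invariant to library-size rescaling when the calibration
is refit.  Bins with CF = 0 get a flagged missing score: with no CpGs no
MeDIP signal is expected and the ratio is undefined.  bedGraph output is
written per non-overlapping step window (overlapping bins averaged),
with equal-valued adjacent windows merged and missing windows omitted.
This transform is a self-contained analog of the MEDIPS-style procedure;
bit-compatibility with MEDIPS is not promised.

## DMR ranking and enrichment

Feature-level methylation is either the mean corrected score of
overlapping bins (default) or an RPKM-style read-depth score,
count × 10⁹ / (total × length).  When quantifying from bin-level counts,
only the primary non-overlapping half-grid enters the RPKM sum so reads
are not double-counted.

The DMR statistic is CV = SD / (mean + 1) with the sample SD (n − 1
denominator — with three tissue groups this choice is material, so it is
documented and fixed).  "Across tissues/samples" is ambiguous in
general, so both modes exist: CV over per-tissue-group mean profiles
(the 3-way cortex/cerebellum/blood contrast, with cortex summarized as
the mean over its regions) and CV over individual samples (within-cortex
analyses).  Ranks are 1..n by decreasing CV with ties broken by feature
id for determinism.  Selection is top-k (default 50) or CV > threshold
(e.g. 1.0).

Class enrichment uses genome-wide class proportions: E_c = |DMR|·n_c/N,
o/e_c = O_c/E_c, and a Pearson goodness-of-fit chi-square over classes
(df = K − 1).  Classes with expected < 1 are pooled into "other" to keep
the chi-square approximation honest.  A per-class 2×2 variant with Yates
correction is provided as an option.

## Sample structure and individual differences

Sample relationships use Pearson correlation; clustering is average
linkage on the dissimilarity 1 − r, with samples canonicalized by id
before linkage so results do not depend on column order.  PCA operates
on the feature-centered matrix; component variances are returned
non-increasing.

Between-individual differences are computed per feature and tissue group
(multi-region groups averaged first):
d_t(f) = value(f, ind_a, t) − value(f, ind_b, t); swapping individuals
negates every difference and leaves correlations unchanged.  The
cross-tissue correlations of these difference profiles get two-sided
permutation p-values by feature-label permutation (default 1,000
permutations, seeded), p = (1 + #{|r_perm| ≥ |r|}) / (n_perm + 1).

Note an identifiability fact used throughout: the measured cross-tissue
correlation of individual differences is the generative ρ attenuated by
measurement noise, ρ·σ²_ind/(σ²_ind + σ²_noise).  Recovery of ρ within
±0.1 therefore needs the individual-effect scale to dominate the
per-observation noise (roughly 3×); the generator defaults
(individual_sd = 0.2, noise_sd = 0.05) satisfy this, and clipping at the
[0, 1] boundaries adds a small further downward bias visible at
boundary-near feature classes.

Genic metaprofiles rescale each gene body to 40 segments with ten
200-bp flank windows on each side; the bin signal is treated as
piecewise-constant on the grid's step windows and segment values are
exact length-weighted means (computed from cumulative integrals, with
missing windows weighted out).  Minus-strand genes are reversed; genes
with bodies shorter than the segment count are skipped and counted.

## Co-methylation networks

Profiles are log2(x + 1) transformed (monotone, so per-feature sample
rankings are preserved).  The signed adjacency is
((1 + cor)/2)^β (unsigned |cor|^β optional); β defaults to 6 with an
optional data-driven choice: the smallest candidate β whose signed
scale-free fit R² (regression of log10 p(k) on log10 k over ≥ 8
connectivity bins) reaches 0.8, else the best-fitting β.  Topological
overlap uses the standard form

    TOM_ij = (Σ_{u≠i,j} A_iu A_uj + A_ij) / (min(k_i,k_j) + 1 − A_ij)

computed via matrix products ((A·A)_ij − A_ij in the numerator when the
diagonal is 1) and checked in tests against the exhaustive triple-loop
definition to 1e-12.

Modules come from average-linkage clustering of 1 − TOM with a **static
cut** at 0.95 × the maximal merge height; clusters below the minimum
module size (default 30) are left unassigned ("grey").  A static cut is
simpler and deterministic and recovers planted blocks cleanly; a dynamic
tree cut is a possible extension.  Modules are named by decreasing size
from the conventional color palette.  The module eigengene is the first
principal component (leading right singular vector) of the module's
z-scored profiles, scaled to unit variance with its sign aligned to the
module mean profile to fix the PCA sign ambiguity.  Module–trait
statistics use plain Pearson correlation against one-hot tissue
indicators (point-biserial), with Student-t p-values on n − 2 df; module
membership is |cor(profile, eigengene)| and trait significance is
|cor(profile, trait)|.  By default the network takes the top 2,000
features by variance (ties broken by id) to keep the TOM quadratic in a
desk-scale number of features; a full-matrix mode is available.

## Synthetic data generator

The generator emulates the ingredients of a cross-tissue MeDIP-seq
cohort at desk scale.  Defaults (all configurable, fixed once):

- **Genome**: 2 chromosomes × 1 Mb; ~60 CGIs per chromosome (length
  ~N(1000, 300²) bp, min 200, non-overlapping, anchored at promoters /
  gene bodies / 3'UTRs / intergenic space so every location subtype is
  populated); 40 non-overlapping genes per chromosome (3–15 kb, 500-bp
  3'UTRs); CpGs from a two-rate Bernoulli process, 0.01/bp background
  vs 0.08/bp in islands; a two-level GC track (0.40 background, 0.60
  islands).  An island rate at or below background is allowed but warned
  about; gene sets that cannot pack into a chromosome raise an error.
- **Cohort**: cortex, cerebellum, blood × 3 individuals (cortex may be
  split into multiple regions sharing the group-level state plus
  region noise).
- **Methylation**: class baselines follow the canonical ordering
  (promoter CGIs 0.10 and HCPs 0.12 lowest; intragenic/3'UTR/intergenic
  CGIs 0.35; shores 0.55; CDS 0.65; LCPs 0.80 highest) with per-feature
  jitter (sd 0.05).  A per-class fraction of features (defaults: 20% of
  intragenic CGIs, 15% of LCPs, 5% elsewhere — concentrating planted
  tissue effects where cross-tissue variability is expected) receives a
  ±0.4 shift in one random tissue; the default sign rule points away
  from the nearer [0, 1] boundary so planted effects are never weakened
  by clipping (a random-sign mode clips and logs instead).  Individual
  effects use the exact shared/private decomposition
  e = σ_ind(√ρ·z_shared + √(1−ρ)·z_private) giving cross-tissue
  correlation ρ in expectation (ρ ∈ [0, 1]; the decomposition does not
  extend to negative equicorrelation across three tissues).  Per-cell
  noise sd 0.05; everything clipped to [0, 1].
- **Counts**: count(b, s) ~ Poisson(L_s·[m_bs·g(CF_b) + bg]) with the
  saturating capture curve g(CF) = CF/(CF + 10) — the minimal shape that
  makes coupling-factor correction non-trivial — and the per-sample
  factor L_s normalized so the expected library total equals
  `library_size` (default 5×10⁵) exactly; doubling the library size
  doubles every expected count.  Poisson is the default for analytic
  checkability; a Gamma-mixing dispersion parameter adds
  negative-binomial-like overdispersion when wanted.  Feature-free bins
  carry a heterogeneous background methylation (N(0.75, 0.15²) clipped,
  drawn once per bin) so that bin-level truth varies genome-wide.
- **Determinism**: a single seed fans out to per-stage generators via
  `SeedSequence` spawn keys; identical config + seed gives byte-identical
  fixtures (checksum-tested).

Fragment-level read simulation is deliberately out of scope: counts are
generated at bin level, and the interval-counting operation is tested
separately on hand-made read fixtures.  No sequence-level simulation
(FASTA/FASTQ), bisulfite chemistry, or batch artifacts beyond library
size.

### What the synthetic validation shows — and does not

Passing tests establish that each algorithm recovers the structure it is
designed to detect under a generative model matching its assumptions:
CpG-density correction under a saturating Poisson count model, CV
ranking under additive tissue shifts, network modules under block
correlation.  Real MeDIP-seq data add fragment-length effects, mappability
and GC biases beyond CpG coupling, overdispersion, copy-number
differences between individuals, and cell-composition heterogeneity —
none of which the generator emulates, so performance numbers here bound
behavior under ideal conditions rather than predicting field accuracy.
Published cohort-specific values (enrichment ratios, module counts,
specific correlations from any real brain/blood dataset) depend on that
cohort and are not reproduction targets of the synthetic validation.

## Problem sizes and numerical choices

The validation suite uses 1-Mb single-chromosome genomes (4,000 bins) at
5×10⁵ reads, 2,000-feature matrices, 600-feature networks and 1,000
permutations — sizes chosen so the planted effects are measured with
comfortable statistical margins while the whole suite runs in seconds.
Division guards use ε = 10⁻⁶ (score denominators) and 10⁻¹²
(variance/zero checks, treating float-rounding-level SDs as constant);
ties are always broken by id; degenerate inputs (constant matrices,
zero-variance samples or features, constant traits, empty CF levels)
raise errors naming the offender rather than propagating NaNs, except
where a missing value is meaningful (CF = 0 bins, grey-module
membership).

## Known limitations

- The calibration curve assumes enough bins per CF level; very small
  genomes or very sparse CpG landscapes can leave too few levels.
- The static tree cut can merge planted modules whose latent profiles
  correlate by chance when samples are very few; module recovery is
  validated with orthogonal planted latents.
- RPKM quantification from bin-level counts uses the non-overlapping
  half-grid, which is exact for the simulator's bin-level counts but
  approximates read-interval RPKM near feature boundaries.
- Permutation p-values are bounded below by 1/(n_perm + 1).
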