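# Methods

This note documents the models, statistical procedures, numerical
choices, and the synthetic-data design behind `miratlas`, in the spirit
of the methods documentation of packages like statsmodels or msprime.

## Normalization and QC

Counts are scaled to reads per million mapped (rpmm): for sample *s*,
`rpmm(f, s) = count(f, s) / Σ_g count(g, s) × 10⁶`, where the
denominator runs over a configurable feature class (default: every
feature in the input table, so the normalization is reproducible from
the count table alone; restricting to e.g. miRNA-mapped counts is a
one-argument change).

Filters, with their boundary conventions:

- samples are kept with **strictly more** than 2 million aligned reads
  (presets: 1.8 M for sorted-microglia libraries, 10 000 for the human
  cohort);
- a feature is kept iff in at least one experimental group, at least
  10 % of the group's samples have raw count ≥ 5 (**both bounds
  inclusive**; the human preset lowers the count bound to 2). The
  grouping defaults to (region, age, sex) — the design cells — and is
  configurable;
- after sample filtering, a brain region retaining ≤ 3 samples is
  removed entirely;
- "expressed in a region" uses the same 10 % / ≥ 5 rule within that
  region's samples.

All filters are idempotent and report exactly what they dropped.

## Statistical tests

**Spearman age correlation.** Midrank-based ρ per (feature, region).
The two-sided p-value of ρ = 0 follows the domain split of the classical
AS 89 algorithm: for tie-free samples with n ≤ 8 the exact distribution
of S = Σ dᵢ² is enumerated (cached per n); for tie-free 8 < n ≤ 1289 an
Edgeworth series approximates the S tail (verified against an exact
Ryser-permanent enumeration of the S distribution at n = 12; the frozen
reference values live in the test suite); with ties or larger n the
t-approximation t = ρ√((n−2)/(1−ρ²)) is used. Significance:
BH-adjusted p < 0.05 **and** |R| > 0.5 (strict comparator by default,
inclusive available, since published figure legends often state ≥).

**Differential expression.** Fold change is the ratio of group centers;
the center statistic is per-contrast configurable: median for
within-atlas age contrasts, scalar geometric median (exp of the median
of logs, zero-excluded) for the male/female contrast, geometric mean for
the human preset — these follow the distinct conventions such studies
apply per contrast. Features with fold change exactly 1 are removed
before testing; a zero center makes the fold change undefined and the
feature is excluded with a flag. P-values come from two-sided Welch's
t on the per-sample rpmm values; BH runs within each
(stratum, region, contrast) family, matching how results are reported
per region (a global-family mode exists). The significance flag requires
p_adj < 0.05 and fc ≥ 1.5 or ≤ 1/1.5. Cohen's d uses the pooled-sd
definition; |d| ≥ 0.5 (inclusive) marks age-related candidates in the
human preset. Tests run on rpmm without log transform; a log2(rpmm+1)
option exists for robustness studies.

**Taxonomy.** A feature is a *candidate* if significantly age-correlated
in ≥ 1 region or significantly deregulated in ≥ 1 age comparison; a
feature whose direction flips between regions is still one candidate.
*Unique* = evidence in exactly one region; *multiple* = more than one
region in the same direction. Cross-sex aging features are candidates
with same-direction evidence in both sex strata.

**Enrichment rank list.** Positive-effect features sorted by ascending
p head the list; negative-effect features sorted by descending p form
the tail (most significant negatives last). This is one consistent
reading of "ranked increasingly (decreasingly) by significance"; ties
break by |effect| then feature id so the list is deterministic.

## PVCA

Features are z-scored, the sample–sample covariance eigendecomposed,
and the first K components retained where cumulative explained variance
first reaches 0.6 (the convention of the original PVCA description;
configurable). For each retained PC, a variance-component model with
one random effect per factor and per two-way interaction (only
interactions that genuinely refine both parents) plus residual is fit
by EM-REML: tolerance 1e-8 relative, ≤ 500 iterations, components
clipped at zero so proportions are well defined. The fitter agrees with
statsmodels MixedLM on one-way fixtures to ~1 %. Reported shares are
eigenvalue-fraction-weighted averages over the retained PCs,
renormalized to 1; interaction terms with share < 1e-6 are omitted from
the summary but kept in the full result. Single-level factors are
dropped with a warning; "individual" (animal id), when present, is an
ordinary categorical factor.

## Region signatures

CV = sample sd / mean of the per-region medians (n−1 denominator, the
default of mainstream statistics libraries; recorded in output
metadata). Top-50 by CV; z-scores of region medians per feature, also
with sample sd; binarization at |z| ≥ 0.5 (inclusive per the stated
rule; the strict variant is exposed because figure captions sometimes
print >). Exactly one flagged region ⇒ region-specific; several ⇒
multi-region; none ⇒ not-different and excluded from heatmap export.
Region columns of the binary matrix are clustered by complete linkage
on Euclidean distance (equivalent ordering to Hamming on 0/1 data),
cut at four clusters; columns are sorted before linkage so the
partition is order-invariant.

A note on compositionality: rpmm is a relative measure, so strongly
elevated features in one region depress every other feature's rpmm
there. With few regions this can push otherwise-null features past the
|z| ≥ 0.5 line in that region, turning single-region labels into
multi-region ones that still contain the true region. Recovery of a
planted region-distinct feature is therefore scored as "flagged in its
planted region", and the false-discovery proportion is measured over
the region-specific calls.

## Trajectory clustering

A trajectory is the median rpmm of one feature in one region per age,
standardized across the age axis with **sample sd** (matching R's `sd()`
used by the established soft-clustering time-course tools; for medians
(1, 2, 3) the vector is (−1, 0, 1)). Zero-variance trajectories are
dropped with a record; regions with < 3 ages are excluded. Because
c-means needs equal-length vectors, the default age grid is the
intersection of ages available in all retained regions.

Fuzzy c-means (Bezdek): memberships
u_ij = 1/Σ_l (d_ij/d_lj)^(2/(m−1)), centers as u^m-weighted means,
converged when the max center shift < 1e-6; the objective
Σ u^m d² is asserted non-increasing every iteration. The fuzzifier m
defaults to the Schwämmle–Jensen heuristic from the data size and the
age-grid length. Initialization draws k distinct trajectories by seeded
choice; three seeded restarts are run and the lowest-objective fit kept,
so results are deterministic given the seed. Cluster-count selection is
a diagnostic table of minimum pairwise centroid distance over a k range
("minimum centroid" is implemented as the minimum pairwise center
distance, the standard diagnostic; no automatic choice is made).

Assignment: argmax membership; max membership strictly below 15 % is
discarded (exactly 0.15 is kept). Each (region, feature) tuple appears
in at most one cluster. Singleton clusters are excluded from profiling.
A cluster is region-specific when one region holds ≥ 30 % of members,
feature-specific when one miRNA occurs ≥ 4 times.

## Genomic neighborhoods

Loci are 1-based inclusive (GFF3, parsed with gffutils; one locus per
feature id, first record wins with a warning on duplicates). For each
anchor in the significant set, other significant loci whose interval
overlaps [start − 10 kb, end + 10 kb] on the same chromosome are
counted, split by strand equality; the anchor never counts itself.
Overlap is of the neighbor's full locus with the window around the
anchor's full locus (interval, not point, semantics). Reference
averages run the same count over *all* annotated loci. Cumulative
coordinates add the declared lengths of preceding chromosomes to the
locus start. Enrichment testing of positional clustering is out of
scope; the counts themselves are the deliverable.

## isomiRs and target integration

isomiR variants are quantified per archetype; the canonical fraction is
canonical / Σ variants of the per-(region, age) medians. Top isomiRs
rank by median expression over all samples. Region clustering uses
per-variant z-scores (across regions) of region-mean expression,
complete linkage, three clusters.

Target screening: Spearman correlation of the miRNA with each target
gene across the matched samples of every region; BH over all computed
(gene, region) pairs of one miRNA's analysis. Flag at R ≤ −0.3 and
p_adj < 0.05 — the negative reading of the stated threshold, since the
screen is for anti-correlation; sign and comparator are exposed. The
validated-target mode uses strict R < −0.5. Genes missing from the
mRNA table are recorded, not fatal.

## Synthetic atlas

The generator emulates the atlas design: a grid of regions × ages ×
sexes with replicates, negative-binomial counts (Var = μ + αμ²,
α = 0.15 — a typical bulk small-RNA-seq dispersion), lognormal
library-size variation (mean 3 M reads, σ = 0.25, so a small tail of
libraries falls below the 2 M QC line), and per-feature lognormal
baselines spanning the dynamic range. Planted structure, all applied on
the log2-mean scale:

- region-specific features (+3 log2 in one region),
- sex-linked features (+1.5 log2 in males),
- aging features over four regions with linear, step-at-15-months, or
  peak-at-15-months shapes and total magnitude 2 log2 — the changepoint
  at 15 months mirrors the abrupt mid-life switch seen in ventricular
  tissue and the transient pons pattern,
- target genes coupled to planted aging miRNAs through a Gaussian
  copula calibrated to a target Spearman correlation (−0.8), and
- isomiR tables that split each archetype's counts multinomially with
  an age-drifting canonical fraction.

The default grid is deliberately small (6 regions × 4 ages × 2 sexes ×
4 replicates, 300 features) so a full pipeline run takes seconds; the
study-scale 15 × 7 × 2 grid with 1174 features is one call away
(`full_atlas_config`). The dedicated trajectory-archetype simulator
uses the full 7-age grid, since that is the grid real trajectories are
defined on.

What the generator does **not** emulate: batch effects, sample-specific
GC or length biases, correlated feature blocks beyond the planted
effects, cell-type composition shifts, or missing design cells (e.g.
missing oldest-age females). Passing recovery tests therefore
demonstrates correctness of the computations under the stated
generative model, not robustness to every artifact of real libraries.

## Determinism

Every stochastic component takes an explicit seed (numpy Generator
streams); the pipeline writes SHA-256 checksums of all outputs and
reruns reproduce them exactly. Floating-point output is serialized at
10 significant digits.

## Known limitations

- EM-REML converges linearly; near-zero components are clipped, which
  can slow terminal convergence (bounded by the iteration cap).
- The AS 89 Edgeworth tail is approximate (absolute error ~1e-3 in the
  far tail at n ≈ 10–15); with the tied age grids of real designs the
  t-approximation path is what actually runs.
- The fold-change "exactly 1" removal rule is measure-zero on
  continuous data but matters for ties in low-count features.
- Neighborhood counting is O(n²) per chromosome; fine for miRNA-scale
  annotations (~10³ loci), not meant for genome-wide feature sets.
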