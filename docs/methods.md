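# Methods

This note documents the models, conventions and numerical choices behind
`mirnaome`, and what the synthetic-data generator does and does not emulate.

## Reference model

A miRBase-style reference consists of hairpin FASTA, mature FASTA and a GFF3
with `miRNA_primary_transcript` and `miRNA` rows (`ID`/`Name`/`Derives_from`
attributes). Sequences are normalized to the RNA alphabet (T → U).
Internally all coordinates are 0-based half-open; GFF3 I/O converts to and
from the format's 1-based inclusive convention. Every mature must occur
verbatim inside its hairpin: this is a hard error otherwise, because all
downstream end-shift logic depends on the mature-in-hairpin placement. For
minus-strand hairpins whose FASTA was extracted from the genome plus strand,
the loader retries the match after reverse-complementing, and stores the
sense-oriented sequence; miRBase-style files (already sense-oriented) match
directly. Mature genomic coordinates are derived from the hairpin's span and
the offset, with strand arithmetic.

**Seed.** Nucleotides 2–8 of the mature (the canonical 7-mer determinant of
target recognition). The seed length is a convention, not a fitted choice.

**Genomic clusters.** Matures on one chromosome, coordinate-sorted, are
chained while the count of intervening bases between consecutive matures is
at most `max_gap` (default 10,000, the miRBase convention). The gap is
measured end-to-start (intervening bases), not start-to-start; clusters are
strand-agnostic because the convention is purely positional. Chains of one
are reported separately, not as clusters. Names are `Chr{N}.{k}` with `k`
the 1-based start-order ordinal on the chromosome.

**Families.** Seed mode partitions matures by exact seed identity. Curated
family labels (which group near-identical seeds, e.g. miR-99/100/125 under
one name) can be supplied as an annotation table (`annotated` mode); matures
missing from the table fall back to seed grouping and are flagged. Seed mode
is the default because it is fully reproducible from sequence alone.

## isomiR classification

For a read of length n and a mature of length L, every shift pair
(s5, s3) ∈ [−3, 3]² with L + s5 + s3 = n is a candidate placement (negative
shift = bases trimmed from the canonical end, positive = bases added).
Mismatches inside the canonical body are substitutions, reported in
1-based canonical-mature coordinates even for shifted reads; at most one is
allowed (`max_sub=1`). Bases added at an end are compared to the flanking
hairpin: all matching → templated addition; any mismatch, or extension past
the hairpin boundary → non-templated. Non-templated tailing does **not**
count against the substitution budget — 3′ tailing by nucleotidyl
transferases is a distinct biological process from internal editing, and
conflating the two would discard genuine tailed reads.

The best candidate minimises `|s5| + |s3| + #substitutions`; ties break by
fewer substitutions, then smaller |s5| (5′ variation is biologically rarer,
so smaller 5′ displacement is the more parsimonious explanation), then
mature name, then (s5, s3) lexicographically. Each read is assigned to
exactly one mature — no fractional multi-mapping — so results are
deterministic and counts are conserved: input totals always equal called
plus unassigned totals per sample. The ±3/±1 tolerance window is the
default; both the window and the substitution budget are parameters.
Unassigned reads carry a reason; when a read would match under a wider end
window, the reason says so.

The class is determined by the shifts alone: `exact` (0, 0), `iso5`, `iso3`,
or `iso5_iso3`. Substitution spectra are reported in the DNA alphabet
(U → T) over the 12 ordered base pairs, for comparability with
sequencing-convention plots.

**ADAR.** A-to-I editing is read out as A>G on the sense read (inosine pairs
like guanosine). A substitution qualifies as an ADAR event only if the
canonical mature has A at that position — guaranteed by construction since
substitution coordinates are canonical, and re-checked against the
reference. Per site, edited counts are accumulated against the assigned
mature's total expression. The per-sample summary reports the number of
distinct edited matures, edited expression in CPM of the called library, and
edited expression as a percentage of the affected matures' totals. Group
differences are compared with an unpaired two-sided t-test on per-replicate
counts of edited matures (the choice of test is a package convention; with
zero variance in both groups the statistic is defined as 0 with p = 1).
Collapsed input has no quality scores, so no quality-aware error model is
attempted.

## Quantification and differential expression

CPM scales each sample to a library of 10⁶. Distances and PCA (and the
trajectory profiles) use log2(CPM + 1); the offset keeps zeros finite and
the transform is stated explicitly because results depend on it.

Size factors are median-of-ratios: for features with nonzero counts in every
sample, the median per sample of count / geometric-mean, rescaled to
geometric mean 1. If no feature is shared by all samples the estimator
fails loudly rather than silently degrading.

The Wald test works on normalized counts q = K/s. Per feature, the
within-group pooled variance gives a raw method-of-moments dispersion
α̂ = (s² − μ̂)/μ̂². With 2–3 replicates per group this estimate has so few
degrees of freedom that plugging it into a normal-referenced Wald statistic
is badly anticonservative (the statistic is effectively t-distributed with
~4 df; simulations at any dispersion between 0.005 and 0.2 put the null
p ≤ 0.01 fraction at 0.04–0.06). The default `dispersion_mode="max-common"`
therefore floors each feature's dispersion at the median raw estimate across
all features — the classic conservative rule of the early DESeq lineage,
using a constant rather than a fitted mean-dispersion trend. Under this rule
the null p ≤ 0.01 fraction is 0.010–0.016 across the same dispersion range
(measured by the acceptance script). `dispersion_mode="per-feature"` gives
the unmoderated estimator for comparison.

`log2FC = log2((μ̂_B + pc)/(μ̂_A + pc))` with pseudocount 0.5, which keeps
fold changes finite for group-absent features. The standard error comes from
the delta method with NB variance μ + αμ² per replicate. p-values are
two-sided normal; BH adjustment runs over tested features. Deliberately not
implemented: dispersion-trend fitting and shrinkage, Cook's distance
filtering, independent filtering — the intent is a transparent, simulation-
calibrated test, not a DESeq2 clone. Volcano labels default to raw p
(`use="padj"` switches), with `up` iff log2FC ≥ 3 and p ≤ 0.01.

The expression filter has two modes because the published phrasing of such
filters is genuinely ambiguous: `strict` requires every replicate of some
population ≥ 5 reads; `mean_only` requires a replicate mean ≥ 5 in some
population. Strict selects a subset of mean-only for any matrix.

## Trajectory clustering

Profiles are per-population replicate means of log2(CPM+1) — three points
for a three-stage course, matching how such trajectories are displayed —
row-standardized with the sample s.d. (ddof 1). Constant rows are dropped
with a warning (their shape is undefined).

Fuzzy c-means uses the standard alternating update: memberships
u_ik = 1/Σ_j (d_ik/d_ij)^(2/(m−1)) with Euclidean d, centroids the
u^m-weighted means. A point coincident with a centroid gets membership 1
there. Convergence is max |Δu| < 1e-6 or 500 iterations; the recorded
objective trace is non-increasing by construction of the alternation.
Defaults: m = 2 (the standard softness; data-driven m estimation is out of
scope), 10 restarts with the best final objective kept — single restarts
find a bad local optimum on roughly 1 run in 4 with five planted shapes,
restarts make recovery reliable. Initial centroids are distinct data rows
chosen by seeded draw *in row-content-hash order*, so permuting the input
rows permutes the fitted memberships identically.

The number of clusters is chosen as the largest c whose best model keeps all
centroids at least 0.5 standardized units apart; the full diagnostic table
(objective and minimum centroid distance per c) is returned for inspection.
This minimum-separation heuristic is a package decision — it reads as "stop
adding clusters when two of them describe the same shape". Hard assignments
take the argmax membership when it is at least `min_membership` (default
0.5), ties to the lowest cluster index.

## Grouping and the three-tier report

Group expression is the per-sample sum over members; features in no group
are returned separately so column totals are conserved exactly. A feature
may belong to at most one group per grouping (clusters and families are each
partitions). Word-cloud weights are population-mean CPM normalized to max 1,
ordered weight-descending then name.

The three tiers: (1) top-n expressed among filter-passing features, ranked
by target-population mean CPM; (2) up versus **all**: the feature must earn
the `up` volcano label against every other population in separate pairwise
tests (an intersection, not a pooled one-vs-rest test — pooling would let a
single extreme population carry the label); (3) unique: zero raw counts in
every sample of every other population, with a target mean CPM floor of 5 so
single-read features are not called "unique". Ranking in all tiers is
target-population mean CPM, and the column is labelled CPM.

## Target-set statistics

Filtering keeps scores strictly above 0.8 by default (a flag makes the
boundary inclusive; the behavior at exactly 0.8 is documented because
"above" is ambiguous). Correlations between predictors run over genes
scored by both only — zero-filling unscored genes would fabricate agreement
— with Pearson default and Spearman optional; fewer than 3 common genes is
reported as undefined. Enrichment is the upper-tail hypergeometric
P(X ≥ k) with BH across sets; query and sets must lie inside the declared
universe. Real ontology annotations are user-supplied (GMT); none ship with
the package.

## Synthetic data

The generator plants known structure at study-shaped defaults: 3 populations
× 3 replicates; a reference of 30 hairpins / 40 matures with three planted
multi-hairpin genomic clusters (intra-cluster hairpin gap 2 kb, everything
else ≥ 50 kb apart) and four 3-member shared-seed families; ~1,500 distinct
read sequences per fixture (10,000 in the at-scale check); isomiR class mix
25/15/35/25% (exact/5′/3′/both) with 5′-shift mode at −3 and 3′-shift mode
at −1; substitution rate 0.15 per sequence with spectrum weights 6:1
favouring C>G, G>A and U>C; A>G is reserved for ADAR editing (sites planted
at internal A positions of 10% of matures, edited at rate 0.2) so editing
calls are attributable; 70% of end additions templated from the hairpin;
NB counts with base means log-uniform over 10^0.7–10^3.5 and dispersions
0.01–0.15, planted fold changes of 2⁶, and trajectory features following the
five standardized shapes with amplitude 2 (log2 units) and Gaussian noise
s.d. 0.2 on the standardized scale. Isolated hairpins carry a single mature
so that singletons genuinely test the no-singleton-clusters rule.

Each generated read records its generating tuple and an `ambiguity_free`
flag computed by an independent naive enumeration (the generating
explanation is the unique minimal-cost one); recovery rates are measured on
ambiguity-free reads because a read equally well explained by two matures
has no single correct answer. All generators are deterministic: a fixed seed
yields byte-identical FASTA/GFF3/TSV/JSON outputs.

What the simulator does **not** emulate: sequencing errors and quality
scores, adapter read-through, expression-coupled isomiR usage, genome-wide
multi-mapping outside the reference, or curated family structure beyond seed
identity. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated generative model, not
performance on any particular real library.

## Problem sizes

Default test fixtures are small (hundreds of reads/features) so the suite
runs in seconds; the at-scale checks use 10,000 read sequences, 2,000-feature
null count matrices and 250 trajectory profiles, which keeps the full
acceptance run under a minute on one CPU. These sizes were chosen as the
smallest at which the measured rates are stable across seeds.
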