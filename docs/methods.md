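# Methods

This note documents the models, rules and numerical conventions behind
`forefield`, the design choices made where several reasonable options
existed, and what the synthetic data generator does and does not emulate.

## Coordinates and formats

All intervals are 0-based half-open internally. BLAST tabular files use
1-based inclusive query coordinates with `qstart > qend` encoding the minus
strand; conversion happens exactly once, at the file boundary, and is a
bijection (round-trip tested). Strand is inferred solely from coordinate
order — frame numbers of frameshift-aware translated searches are not
modelled, because downstream logic needs only the interval and orientation.
Hits whose subject accession is missing from the accession→taxid map keep a
`None` taxid: they are excluded from taxonomic assignment but retained for
gene calling, since functional annotation does not require a resolved taxon.
Parsers never drop rows silently; drops are counted and logged.

## Region building and taxonomic assignment

**Gene-coding regions.** Hits on the same contig and strand whose intervals
overlap or lie within `merge_gap` (default 30 bases, a typical intergenic
spacer) merge into one region spanning their hull. Merging is strand-aware
so divergently oriented genes are not fused. The region's gene label and GO
terms come from the maximum-bitscore hit, ties broken by lexicographically
smallest label so runs are bit-reproducible.

**Region taxon.** The region taxid is the lowest common ancestor of the
taxa of all hits with bitscore ≥ (1 − `top_fraction`) × best, with
`top_fraction` = 0.1. This mirrors an aligner's top-10% retention window;
applying the filter in memory keeps the operation correct on files that
were produced with other settings. LCA ignores hit multiplicity
(redundancy is already handled by the bitscore window).

**Chimera detection.** A chimeric contig joins sequence from two unrelated
organisms. No standard algorithm exists for alignment-based chimera calling,
so the rule here is the package's own design, using only the information the
alignment file carries: adjacent runs of regions are
compared at `conflict_rank` (default phylum); a split point is placed
between two runs whose rank-ancestors differ when each run spans at least
`min_flank` bases (default 1,000 — a single spurious short region cannot
split a contig). The split coordinate is the floor midpoint of the
inter-run gap, the shared boundary if the runs abut. Splitting partitions
the contig exactly (child lengths sum to the parent length, fuzz-tested);
regions straddling a split point are truncated on both sides, so a
straddling gene is counted once per child afterwards — a documented
consequence, not a bug.

**Contig lineage.** For each of phylum, class, order, family and genus, the
regions' ancestors at that rank vote with region-length weights; the winner
is assigned only with a strict majority (> 0.5 of the taxonomically
resolved length at that rank), and assignments are nested-consistent (a
genus is dropped unless every shallower assigned rank is its ancestor).
Length weighting plus the strict majority reproduces the common situation
of contigs classified at phylum but unclassified at genus.

## Abundance currencies

Base coverage of a contig in a sample is aligned bases ÷ contig length
(units "×"); SAM records flagged unmapped, secondary or supplementary are
excluded, and no deduplication or mapping-quality filter is applied by
default. Whole-sample coverage is the length-weighted mean over contigs.
Aggregating contigs into taxa or genes uses the length-weighted mean by
default, which keeps the "×" unit interpretable; a raw base-count sum mode
is also provided. Relative abundance defaults to the sum mode because only
under summed base counts do genus abundances within a phylum add up exactly
to the phylum abundance (a property the test suite checks); "unclassified"
contigs are excluded from the denominator by default (flag to include).
When a chimeric parent is split, its children inherit the parent's mean
coverage — read placement is uniform in the generator and approximately
uniform in practice, so the per-base expectation is unchanged.

Weighted gene coverage divides a gene's coverage by the whole-sample base
coverage. This is the depth normalisation that makes samples with different
sequencing effort comparable: multiplying every read count in a sample by a
constant leaves it invariant (tested through the full pipeline).

## Statistics battery

* Shannon diversity uses natural logarithm (nats); inverse Simpson is the
  effective number of genera. Diversity is computed on genus-level
  abundance of classified taxa.
* Community dissimilarity is Bray–Curtis on relative abundance (two
  all-zero rows have distance 0 by convention); geochemistry (TN, TOC) uses
  Euclidean distance.
* PERMANOVA is one-way (the study design has a single fixed factor, the
  forefield), computed from squared distances: SS_total = Σ_{i<j} d²_ij/n,
  SS_within summed per group, R² = 1 − SS_within/SS_total,
  pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)). For two groups and
  Euclidean distances on one-dimensional data the pseudo-F equals the
  classical one-way ANOVA F (closed-form limit, tested).
* The Mantel statistic correlates the lower triangles of two distance
  matrices; the default inner correlation is Pearson with a one-sided
  "greater" p-value (the convention of the vegan R package); Spearman mode
  is available. Permutation relabels rows and columns of the second matrix
  simultaneously.
* Permutation Spearman uses midranks (average ranks on ties) and a
  two-sided p-value on |r_s|.
* Every permutation test defaults to 9,999 permutations, takes a seed, is
  bit-reproducible, and uses the add-one convention
  p = (1 + #extreme)/(1 + n_perm), so p ≥ 1/(n_perm+1). For small n an
  `exact=True` mode enumerates all n! permutations (the identity is then
  included in the count). Significance is strict everywhere: p < 0.05.
* The GO screen correlates every GO category with a covariate (distance,
  TN or TOC) and keeps categories with p < α and |r_s| strictly greater
  than 0.4. No multiple-testing correction is applied by default,
  mirroring the analysis this package reproduces; constant columns are
  skipped with a log entry.
* PCA is eigendecomposition of the covariance matrix of column-centered
  data; component signs are fixed by making each component's
  largest-magnitude loading positive.
* LOWESS uses a tricube-weighted local linear fit, span 2/3, one
  robustness iteration (conventional defaults; the source analysis states
  none).

**Distance bins.** The eleven ice-edge bins are 0–50, 50–150, 150–250,
250–350, 350–500, 500–750, 750–1,000, 1,000–1,250, 1,250–2,000,
2,000–4,000 and >10,000 m, half-open on the right. As printed, the scheme
leaves a hole over [4,000, 10,000) where no samples exist; to make the bins
a partition of [0, ∞) the "2,000–4,000" bin internally absorbs that range.

## Target gene sets

The four sets — nitrogenase (nifH/nifD/nifK), *obcA* (oxalate biosynthetic
component A, the first step of bacterial oxalogenesis), cyanide synthase
(hcnABC) and siderophore synthesis/transport — are defined in an editable
YAML file as case-insensitive label patterns plus GO ids; either criterion
admits a region. The exact annotation vocabularies of any given protein
database are not knowable in advance, which is why the definitions are
configuration, not code. "Possession" of a set by a genus means coverage
> 0 in at least one sample (any evidence), and the per-bin genus fraction
is genera-possessing ÷ genera-detected in the bin; a bin with no detected
genera reports a missing value, not 0. The figure-style reporting filter
keeps genera with strictly more than `min_regions` regions (e.g. > 1 for
nitrogenase, > 10 for *obcA*).

Per (genus, sample) set coverage is the plain sum over the genus's set
regions of the host contig's coverage divided by sample coverage, so a
genus carrying more copies of a gene scores proportionally higher.

## The synthetic chronosequence generator

The generator emulates the statistical structure of a three-system Arctic
chronosequence; all randomness derives from one seed.

* **Design.** Forefields G, SV and SW sample the distance bins they
  plausibly span (G all 11 bins, up to >10 km; SV the first 9, to
  ~1.6 km; SW the first 4, to ~350 m), two soil samples per bin plus two
  ice samples (distance 0) per forefield — 54 samples by default.
* **Geochemistry.** TN follows a + b·log(d+1) (b = 0.25 mg g⁻¹ per log
  metre) in SV and SW, and in G a Gaussian-in-log-distance hump
  floor + h·exp(−c(log d − log 200)²) with h = 1.6 mg g⁻¹ and c = 0.6,
  peaking inside the 150–250 m bin; measurement noise is 0.03 mg g⁻¹.
  TOC = 3·TN plus noise, so TN and TOC are strongly rank-correlated by
  construction.
* **Community.** Genus relative abundance is a softmax of
  α_g + β_g·log(d+1) + ice_g·1[ice] + forefield offset + noise. Five
  early dominants (α = 4, β = −0.45, three of them ice-affine) decay along
  the succession; eight "late specialists" (α = −9, β ∈ [0.55, 0.75]) are
  below detection near the ice edge and appear far out; the remaining
  genera drift gently upward (β ∈ [0.05, 0.10]). Evenness — inverse
  Simpson — therefore rises with distance, the programmed diversity
  signal.
* **Assembly and alignments.** 40 genera × 50 contigs (2,500–8,000 bases)
  carry 1–3 planted gene regions each, labels drawn from the genus's gene
  content (30 background genes plus its target-set genes; nitrogenase goes
  to the ten steepest-β genera, i.e. mostly late specialists, so the
  fraction of genera with nitrogenase rises with distance). Each region
  emits one on-target hit (identity ~ N(85, 5) clipped to [50, 100],
  bitscore ≈ 0.45/base) plus sister-genus hits at rate 0.5 with 70–98% of
  the best bitscore and rare cross-phylum hits capped below the LCA window.
  1% of contigs are chimeric: two fragments from different phyla, each
  with a leading region of ≥ 1,100 bases so the discordance is detectable
  under the default flank rule.
* **Mappings.** Expected contig coverage is depth × genus abundance ×
  n_genera × a lognormal contig effect (σ = 0.3); read counts are Poisson,
  placed uniformly; target mean sample coverage is 2×. Output is a
  mapped-bases table or per-sample SAM.

**What it does not emulate** — and hence what passing tests do not show
about real data: sequences are random nucleotides (no real homology, so
aligner behaviour itself is untested); there are no sequencing errors,
strain mixtures, conserved cross-phylum genes (horizontal transfer), GC or
mappability bias, or assembly fragmentation; the taxonomy is balanced and
complete, unlike NCBI's ragged lineages; chimeras are clean two-phylum
junctions, the easiest kind. Recovery rates near 1 on this generator
establish correctness of the pipeline's logic, not expected field
performance.

## Problem sizes and defaults

Default study size (54 samples, 2,000 contigs, ~6,000 hits) keeps a full
simulate→annotate→abundance→stats run around ten seconds and the whole test
suite, including a 50-replicate parameter-recovery study and 2,000-replicate
type-I-error calibrations, under a minute — sizes chosen so the complete
battery is routinely runnable while leaving the detection problems
non-trivial (per-contig read counts are small enough that rare genera
genuinely fall below detection).

## Known limitations

* Chimera detection places split points at inter-region gap midpoints;
  against the generator's truth the flag-level calls are near-perfect but
  breakpoint placement is only as precise as the gap between planted
  regions (several hundred bases).
* One-way PERMANOVA only; no two-way or stratified designs, no dbRDA/CCA,
  no partial Mantel.
* The flat gene→GO map carries no ontology structure; GO categories are
  treated as independent labels.
* Merged/deleted taxid remapping and taxonomy versioning are out of scope.
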