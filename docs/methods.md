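# Methods

## Scope and model

`trenchomics` implements the post-annotation analytical layer of a
depth-stratified marine metagenome study: starting from per-sample gene
coverage tables, gene→KO annotations and CheckM-style genome quality tables,
it computes coverage-normalized relative abundances at gene, KO and pathway
level, per-genome pathway completeness, genome quality tiers and inventory
summaries, tag-based abundance ratios, and rank-based enrichment comparisons
between depth strata. Upstream steps — read QC, assembly, binning, read
mapping, and the annotation searches themselves — are out of scope;
their outputs are this package's inputs.

## Relative abundance

The relative abundance of a gene in one metagenome is its average read
coverage divided by the summed average coverage of all genes in that sample,
so each sample column sums to 1 and is invariant to rescaling all coverages
by a common factor. KO abundance sums member-gene abundances. A gene
carrying several KOs contributes its full abundance to each assigned KO:
duplication was chosen over splitting because single-KO assignment is the
overwhelmingly common case with GhostKOALA-style annotation, and duplication
keeps marker-gene panels conservative-complete; the KO matrix flags how many
multi-KO genes were seen (`attrs["multi_ko_genes"]`).

MAG abundance is standardized to *genome copies per million reads*: the
unweighted mean of member-feature coverages × 10⁶ / the sample's total read
count. Whether the denominator is mapped or total reads is underdetermined
in the field's usage; total reads was chosen (it is the quantity a sample
sheet always carries), and a length-weighted mean is available behind the
`lengths` argument.

## Pathway grammar and evaluation

A pathway definition is an ordered list of steps; each step lists
alternative enzyme complexes; each complex is an AND-set of KOs
(`K02586+K02591+K02588` = the nifD+nifK+nifH nitrogenase complex;
`K00362+K00363 | K03385+K15876` = nirBD or nrfAH). Two evaluators share the
grammar:

* **abundance** — a complex is limited by its scarcest subunit (min over the
  AND-set); substitutable routes add (sum over alternatives); the pathway
  value is the arithmetic mean over steps. This scheme was chosen for
  monotonicity (raising any KO abundance never lowers any pathway value) and
  unit consistency (a one-step, one-KO pathway equals that KO's abundance).
  The step combiner is pluggable (`MIN_OVER_STEPS`, `MEDIAN_OVER_STEPS`)
  because other pathway-abundance tools differ exactly here; whether shared
  KOs should split their mass across pathways is an open modelling question,
  so sharing-without-splitting is the default and documented (pathway values
  are not additive across a library).
* **completeness** — the fraction of steps for which a genome's KO set fully
  contains at least one alternative complex. Bounded in [0, 1], monotone in
  the KO set, 1 for a fully annotated genome, 0 for an empty one.

The shipped library covers the carbon-fixation, central-carbon, terminal
oxidase, hydrogenase/fermentation, nitrogen- and sulfur-cycle marker panels
used in depth-profile studies. The KO↔gene-symbol table is a static,
versioned snapshot curated into `data/ko_symbols.tsv`; no live KEGG queries
are made, and a handful of minor markers (the 3HP bi-cycle mct/meh pair,
for instance) are best-effort assignments.

## Annotation acceptance rules

Peptidase-style BLASTp hits are accepted at e-value ≤ 10⁻⁵, identity ≥ 30%
and query coverage ≥ 50% — all inclusive, reading "maximum"/"minimum"
literally — then reduced to one best hit per query (highest bitscore, ties
to lowest e-value, then lexicographic subject id, so filtering is
deterministic and idempotent). CAZyme calls are confirmed when at least
`min_tools = 2` of the three dbCAN-style searches (HMM, alignment, peptide
pattern) agree; 2-of-3 is the dbCAN2 recommendation, and the threshold is
configurable because "two searches" is ambiguous between "two specific
tools" and "any two".

## Quality tiers and inventory

Tiers follow the completeness/contamination rules: **high** requires
completeness > 90 and contamination < 5; **medium** requires ≥ 50 and < 10;
everything else is **low**. High takes precedence, so tiers partition — a
726-genome inventory reported as 254 high + 472 medium forces exclusive
tiers. Depth strata are {0 m, 2000 m, 4000 m, 8000 m, 9600 m, >10,000 m},
the 10,400 m and 10,500 m casts merged into ">10,000 m". Percentages are
rounded half-away-from-zero, with the decimal count chosen per call site
(field reporting mixes 1- and 2-decimal precision); `TraitFraction` keeps
the exact rational until formatting.

## Rank-sum testing

Two-sided Wilcoxon rank-sum with midrank ties. When the number of group
labelings C(n_a+n_b, n_a) is ≤ 20,000 the p-value is exact: full enumeration
of labelings, p = mass of rank sums at least as far from the null mean as
observed. Beyond that, the normal approximation with tie correction and a
0.5 continuity correction is used; the method applied is recorded on every
result. The 20,000 cut keeps exactness for all desk-scale group sizes
(16 samples in every split) while bounding cost.

Two statistical facts matter for interpreting the screen at the study's
group sizes (4 deep vs 12 shallower samples):

* the exact test is **discrete**: its true size at α = 0.05 is the largest
  attainable level, 2·38/1820 ≈ 0.0418, not α itself
  (`exact_test_size(4, 12, 0.05)` computes this from the null
  distribution). Simulation checks of type-I control are therefore
  compared against the attainable size, with α as an upper bound;
* pathway features within one sample set are **correlated** (they share the
  relative-abundance denominator, and some definitions share KOs, e.g.
  narGHI appearing in both nitrate-reduction and nitrite-oxidation
  entries), so uncertainty in a simulated false-positive rate is estimated
  over independent replicates, not over pooled feature-tests.

Significance defaults to raw p at 0.05 (with a 0.01 flag), matching the
field's single-panel reporting; Benjamini–Hochberg adjustment is available
as an opt-in column.

## Synthetic cohort generator

The generator emulates the 16-sample Challenger Deep profile. Per-depth
sample counts are {0 m: 3, 2000 m: 2, 4000 m: 4, 8000 m: 2, 9600 m: 1,
10,400 m: 2, 10,500 m: 2} — the published totals do not state the grid
explicitly, but this is the unique assignment consistent with the reported
per-sample MAG means (87/3 = 29 at 0 m, 71 at 9600 m, 145/4 = 36.25 at
>10,000 m); it is recorded in the emitted sample sheet. Per-stratum MAG
counts default to 87/77/224/122/71/145 and tier proportions to 254:472:0.

Per-gene average coverage is log-normal (μ = 2.0, σ = 1.0 on the log scale),
independent across genes and samples — a simple, documented stand-in for the
heavy-tailed coverage distributions seen in real shotgun data. Enrichment
effects multiply raw coverages of a pathway's KO-annotated genes in the
target stratum **before** normalization, so relative-abundance effects are
diluted by the rest of the catalog exactly as a biological enrichment would
be. Each sample draws from its own RNG stream derived from (seed, sample
index); MAG and catalog generation use reserved streams, making every table
byte-reproducible under a fixed seed and any sample regenerable alone.

The catalog assigns `genes_per_ko = 2` genes to every library KO, annotates
half of the background genes with decoy KOs, and carves peptidase / CAZyme /
alkane / aromatic tag groups (5% / 5% / 0.6% / 1.5% of the catalog) out of
the background pool for the ratio statistics. MAG KO sets are generated by
gating each pathway at a prevalence of 0.3 and retaining each step with
probability equal to the genome's completeness/100, so measured pathway
completeness co-varies with CheckM completeness as it does in real bins.

What the generator does **not** emulate: gene-length and GC coverage biases,
correlated co-abundance of genes within a genome across samples,
compositional covariance between taxa, inter-sample batch effects, and
chimeric/contaminated bins. Passing tests therefore demonstrate correctness
of the arithmetic and calibration of the statistics under a clean null —
not robustness to those real-data pathologies.

## Problem sizes and numerics

Default analyses run at 2,000 genes × 16 samples; the replicated
power/type-I experiment uses 100 replicate pairs (with and without a 4-fold
nif-panel enrichment in the deepest stratum), a size at which the exact
4-vs-12 screen detects the effect in ≈94% of replicates. Sum-to-one checks
use 10⁻⁹ relative tolerance; exact-test tail comparisons absorb midrank
floating error with a 10⁻⁹ slack; percent rounding is half-away-from-zero
via exact decimal arithmetic. Degenerate inputs are defined, not fatal:
all-tied groups give p = 1, a zero denominator in a ratio gives a flagged
missing value, an all-zero coverage column is an explicit error.

## Known limitations

* Pathway abundance formulas differ between tools; ours is one documented,
  monotone choice, and cross-tool numerical agreement should not be expected.
* The multi-KO duplication rule means KO columns need not sum to ≤ 1 when
  multi-KO genes exist.
* The exact test's conservatism at tiny group sizes (size 0.0418 at
  nominal 0.05 for 4 vs 12) is inherent to discrete tests, not a defect;
  interpret marginal p-values accordingly.
* `mag_abundance` standardizes by total reads; with mapped-read denominators
  values will differ by the mapping rate.
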