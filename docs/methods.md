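# Methods

This note documents the models and procedures implemented in `mitogeo`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not establish about real data.

## Coordinate frame and mutation model

All positions are 1-based on a fixed mitochondrial reference frame of
L = 16,569 sites (the rCRS convention); intervals are closed. A mutation
is a substitution (`A263G`), an insertion indexed after its anchor
position (`309.1C`), or a deletion (`16189d`). A sample is represented by
its `VariantProfile`: the canonically sorted list of its mutations plus
the set of positions carrying `N`/ambiguity codes. Canonical ordering
makes haplotype identity textual identity, which every downstream module
relies on.

Missing data are handled by pairwise deletion: a site that is missing in
either of two samples is excluded from their pairwise comparison, and
expected tree mutations at a sample's missing sites are not counted
against its haplogroup score.

The package does not perform read mapping or multiple alignment; inputs
must already be in reference coordinates. FASTA input cannot represent
insertions — the long-format variant table must be used when insertion
calls matter. Heteroplasmy is not represented.

No real reference sequence is bundled. `ReferenceGenome.synthetic()`
produces a deterministic random reference of the right length, which is
sufficient for every simulation-based analysis (only *differences from*
the reference matter); real-data runs must load the actual reference
FASTA via `load_reference`.

## Sample retention (qc)

A sample passes when all four amplified fragments have mean coverage
above 15× and its haplogroup-classifier quality score is above 0.85.
A sample failing *only* the score condition is rescued when its minimum
depth across the whole reference is at least 5×. The rescue clause is
deliberately restricted to score-only failures: applying it to every
failure category would also retain coverage failures with ≥ 5× minimum
depth, which contradicts the category accounting this rule is meant to
reproduce (the report output carries a note stating the rule). Kinship
exclusion is an input flag — one member of each detected relative pair,
chosen upstream; the package does not infer kinship. Threshold
comparisons are strict (`>`) by default and configurable.

## Haplogroup classification

The haplogroup tree is data: a TSV of (node, parent, defining
mutations). A node's expected profile is the fold of the defining
mutations along its root-to-node path; a token with a trailing `!`
removes the previous mutation at its site (back-mutation), and a later
mutation at an already-mutated site replaces the earlier one.

Calls maximise the Kulczynski score
`½(|found|/|expected| + |found|/|observed|)` with
found = expected ∩ observed, computed after removing masked mutations
from both sides. Conventions: an empty expected set contributes 1 to the
first term (so the root scores 1 against an empty profile); an empty
observed set contributes 1 to the second. Ties break by greater node
depth, then lexicographically smallest name — fixed purely for
determinism. This mirrors the score behind the standard mtDNA
classifier's quality value but does not replicate its proprietary
hotspot weighting; the recurrent-site mask plays that role, and the
package makes no claim of matching that tool's scores on real phylotree
input. HVS-I-only classification uses the same operation on windowed
profiles (window default 16024–16365, configurable; scores are expected
to be lower in window mode).

Supergroup binning is an ordered prefix-rule table. The default bins are
M1, U6, sub-Saharan L, H/HV, and a catch-all "other WE" (West Eurasian)
— every non-matching haplogroup falls in the catch-all. The table is
data and should be adjusted when finer conventions are needed (e.g.
where to place N1 or X).

## Diversity and structure

Distances are counts of differing unmasked sites under pairwise
deletion. Haplotype diversity is Nei's H = n/(n−1)·(1−Σpᵢ²) with Nei's
large-sample variance for the standard error; nucleotide diversity is
the mean per-site pairwise difference with per-pair denominators.

AMOVA is one-level (groups within total), following the standard
variance-component construction from squared distances with unequal
group sizes. Negative variance components are reported as computed, with
an optional clamp-to-zero flag, since packages differ on this point. The
permutation test permutes whole labels, uses the add-one correction
(b+1)/(m+1), and defaults to 9,999 permutations (the pipeline default is
999 to keep interactive runs fast; both are seedable and reproducible).
Pairwise Φst runs the same machinery on each pair of groups.

Frequency PCA column-centres the raw frequency table (no scaling — the
compositional scale is already common) and decomposes by SVD;
coordinates are left singular vectors scaled by singular values, so
full-rank PCA distances equal Euclidean distances between centred rows.
A constant table yields zero coordinates and an empty explained-variance
list.

## Clade detection

A focal-region-specific clade: ≥ `min_size` (default 2) focal sequences
of one haplogroup sharing at least one unmasked mutation carried by no
other sequence under consideration. The carrier-set algorithm computes,
for each unmasked mutation, its carrier set; keeps carrier sets that are
non-empty, all-focal and large enough; groups mutations with identical
carrier sets; and emits maximal sets as clades. Nested kept sets are
reported as internal substructure rather than as separate clades —
one clade per lineage, with its internal branching visible in the
report. Equivalence with exhaustive subset enumeration is asserted in
tests on hundreds of random panels.

Design points:

* **min_size = 2** — singletons are not clades; external singletons are
  handled separately (paired with their closest focal sequence in the
  reverse-direction analysis).
* **Strictness** — a member that lost a defining mutation through a
  later hit fails the definition; the strict rule is applied, and
  focal samples carrying all but one defining mutation are listed as
  near-misses for manual review.
* **Identical clusters** — groups of focal samples with identical
  unmasked profiles are flagged `is_identical_cluster`; their defining
  mutations (vs. a supplied panel) may be empty, in which case the flag
  alone marks them.
* **Indels** count as potential defining mutations by default
  (restriction to substitutions is a flag); each insertion event counts
  once regardless of length.
* The closest external sequence minimises the minimum distance to any
  member, with ties broken by mean distance then id. A panel-subsetting
  helper keeps the k = 20 nearest externals per focal haplotype,
  mirroring similarity-based neighbourhood construction.
* The minimum-spanning haplotype network (all ties retained: an edge is
  kept iff it lies in some minimum spanning tree) is a reporting
  artifact only; no clade call depends on it. Median vectors
  (median-joining networks) are out of scope.

## Strict-clock rho dating

The clock: every branch accumulates substitutions at
µ = 2.355 × 10⁻⁸ per site per year — a rate corrected for purifying
selection — over L = 16,569 sites, so λ = µ·L ≈ 3.9 × 10⁻⁴ expected
mutations per genome per year. Time is in years throughout; no
generation-time conversion exists anywhere.

The clade root haplotype is the strict intersection of member profiles —
a conservative founder estimate requiring no tree inference. ρ is the
mean count of member mutations outside the root; TMRCA = ρ/λ;
σ_ρ = √(ρ/n) is the star-phylogeny form (no topology-aware variance is
computed, since no tree is estimated). External mode re-infers the root
over members ∪ {closest external} and averages over the union; the
resulting age upper-bounds the lineage's arrival in the focal region.
Note the union estimate is a mean over tips: adding an external tip very
close to the union root can pull the external date below the internal
one; such rows are flagged in the date report, never dropped.

**Bootstrap CI.** Members are resampled with replacement
(default 1,000 resamples) and the CI is read from percentiles of the
resampled ρ. The plain 2.5/97.5 percentile interval of a mean is
systematically narrow at typical clade sizes (n ≈ 10) — measured
coverage ~0.88 for small Poisson counts — so the implementation uses
expanded percentile levels (Hesterberg's small-sample adjustment: the
nominal levels are widened by the t/normal quantile ratio at n−1
degrees of freedom). The acceptance script measures the resulting
coverage directly. Degenerate cases: ρ = 0 (identical members) yields
TMRCA 0 with CI (0, 0); the reported interval always brackets the point
estimate.

This estimator deliberately replaces full Bayesian tree dating: it is
deterministic given a seed, runs in milliseconds, and is testable by
simulation at scale. Agreement with Bayesian point estimates on real
data should be expected only to loose tolerance — rho is unbiased under
a star genealogy but noisy and topology-blind, and shares the clock's
time-dependency caveats (no rate correction beyond the
selection-adjusted input rate).

## Synthetic-data generator

The generator is the ground-truth surface for every stage. A planted
clade is built as: a stem branch from the split node (age
`true_split_years`) down to the focal clade root (age
`true_internal_tmrca_years`), carrying `n_anchor_mutations` anchor
mutations at non-hotspot sites; a focal subtree (star, or a Kingman
coalescent topology rescaled so its root sits exactly at the internal
age); and external tips hanging from the split node. Every branch of
length t years receives Poisson(λt) substitutions at sites drawn with
hotspot weighting (multiplier ≥ 1 at listed sites; 1 recovers uniform
placement, verified by chi-square in tests). Mutations use a 10:1
transition:transversion bias, the classic mtDNA pattern.

Numerical choices:

* Infinite sites is **not** assumed: repeated hits are resolved
  last-event-wins along each root-to-tip path — this is precisely what
  makes the recurrent-site mask matter, and homoplasy at anchor sites is
  the (rare) failure mode of clade recovery.
* Anchor mutations consume part of the stem's clock budget: the stem's
  random branch length is reduced by `n_anchor/λ` years so the total
  stem mutation count keeps its strict-clock expectation. Without this,
  forced anchors would bias external dating upward. When the stem is
  shorter than the anchors' years-equivalent, detectability wins and the
  stem is slightly over-mutated by construction.
* One RNG per clade, keyed by (seed, CRC32 of the clade label), so panel
  composition order does not change any clade's sequences.
* Locality-structure panels draw haplotypes from pools: one shared pool
  (differentiation 0 — the exchangeable null used to calibrate the
  AMOVA permutation test) and locality-private pools entered with
  probability equal to the differentiation fraction. Each pool descends
  from its own founder (default divergence 15,000 y; within-pool
  diversity 1,500 y), so high differentiation with divergent pools
  drives Φst toward 1, and repeated haplotype draws produce the
  identical-haplotype clusters real panels show.

What the generator does **not** emulate: recombination (absent in
mtDNA), selection, demographic history (growth, bottlenecks), rate
heterogeneity beyond the hotspot multiplier, sequencing error, and
alignment artifacts. Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated model, not robustness to
real-data artifacts — on real panels, clade calls remain sensitive to
panel composition and the mask, and dates to the clock rate.

## Default problem sizes

The simulation experiments run at desk scale: dating recovery uses
star clades of 10 tips, 200 replicates per true age (1,000 / 5,000 /
10,000 y) with 1,000 bootstrap resamples; AMOVA calibration uses three
localities of 50 samples with 199-permutation tests over 100–200
replicates; clade-detection oracle checks use 200 random panels of at
most 12 sequences. These sizes put Monte-Carlo error well below the
effect sizes being checked while keeping a full run in the order of a
minute.

## Known limitations

* The classifier approximates, but does not reproduce, the standard
  tool's scores; real-data haplogroup calls should be sanity-checked.
* Rho dating ignores topology; for strongly non-star clades the
  internal date is biased toward the mean coalescent depth rather than
  the root age, and σ_ρ understates uncertainty.
* The 302→264 retention accounting reflects one reading of an ambiguous
  prose rule (rescue restricted to score-only failures); the report
  states the rule applied.
* Pairwise deletion makes distances non-metric in the presence of heavy
  missingness.
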