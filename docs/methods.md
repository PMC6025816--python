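# Methods

## Distance model

Pairwise distances use the Kimura 2-parameter (K2P) substitution model.
For a sequence pair, alignment columns where either sequence carries a
gap or an N are excluded for that pair only (pairwise deletion); N is
treated as missing throughout. Over the remaining shared sites,
transitions are A↔G and C↔T, all other mismatches transversions, and

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

with P and Q the transition and transversion proportions. When a log
argument is non-positive the distance is undefined (saturation). The
library call raises; the pipeline uses a drop-pair policy that stores
NaN and logs the pair, on the grounds that congeneric material should
not saturate and a silent cap would bias every downstream mean. A cap
policy exists for callers who prefer it. Distances are kept at full
floating precision internally; tables round to 4 decimals.

No other substitution models, gamma rate heterogeneity or model
selection are provided: every statistic in this package is defined on
the K2P scale, and mixing scales across regions would invalidate the
paired comparisons.

## Divergence parameters

Six parameters summarise a region, each reported as mean ± SD
(population SD, ddof = 0, over the contributing values, whose count is
always reported):

* **average interspecific distance** — mean over all heterospecific
  sample pairs;
* **theta prime (θ′)** — for each species, the mean over partner
  species of the species-pair mean distance; averaged over species.
  Aggregating at species-pair granularity gives every species one vote
  at both ends of each comparison, so θ′ is exactly invariant to
  duplicating (or otherwise over-sampling) the individuals of any one
  species — the property that motivates quoting it next to the raw
  mean. The per-individual variant ("mean distance of this species'
  samples to all heterospecific samples") does not have this property,
  because partner species with more individuals would weigh more;
* **minimum interspecific distance** — per species, the distance to its
  nearest heterospecific sample; averaged over species;
* **average intraspecific distance** — mean over all conspecific pairs;
* **theta (θ)** — per-species mean conspecific distance, averaged over
  species with ≥ 2 individuals;
* **coalescent depth** — per-species maximum conspecific distance,
  averaged over the same species.

Singleton species contribute nothing intraspecific; a region with no
replicated species reports the three intraspecific parameters as
undefined rather than zero.

## Barcoding gap

Conspecific and heterospecific distances are binned at a width of 0.01
substitutions/site in half-open intervals [k·w, (k+1)·w) starting at 0.
Two scalar diagnostics accompany the histogram: an overlap flag
(max intra ≥ min inter) and the overlap fraction, the proportion of
conspecific distances at or above the smallest heterospecific distance.
Both are deliberately sensitive to extremes — a single pair of
near-identical species collapses min inter and can push the overlap
fraction to 1 even when the bulk of the distributions separate — so the
histogram TSV is always emitted alongside for inspection.

## Wilcoxon signed-rank comparisons

Regions are compared on matched units: for interspecific divergence,
the species-pair mean distance for every species pair present in both
regions; for intraspecific divergence, every conspecific sample pair
sequenced in both regions. The unit roster is returned for audit, since
region-specific sequencing success makes the paired n differ between
comparisons. Zero differences are dropped; absolute differences are
ranked with midranks. For n ≤ 12 the two-sided p-value is exact by full
enumeration of the 2^n sign assignments on the observed midranks,
P(|W − μ| ≥ |W⁺ − μ|) with μ = n(n+1)/4; beyond that, the normal
approximation with tie correction and a 0.5 continuity correction.
Both p-values are retained on the result object. Verdicts use
α = 0.05 ("A=B" when p ≥ α, otherwise "A>>B"/"A<<B" by the larger rank
sum). No multiple-testing correction is applied across region pairs;
with three regions the comparisons are few and are reported in full.

## Identification assessments

**Best-match.** Every sequence is queried in leave-one-out mode against
the remaining sequences of its region, scored by K2P distance; the hit
set is all references within ε = 1e-9 of the minimum (exact ties in
floating point, nothing looser). A query is correct if the hit set is
exactly its own species, ambiguous if the set spans several species
including its own, incorrect otherwise. Queries whose species has no
other sample are excluded and logged, so the evaluable-species
denominator is always printed with the rate. This is a self-contained,
reproducible stand-in for database-search classification: the reference
set is the study's own data, and no external database is contacted.
A species counts as identified when all of its queries are correct;
the per-query rate is reported alongside.

**Tree-based.** Saitou–Nei neighbor joining on the full K2P matrix.
The join criterion is the standard rate-corrected Q matrix; ties are
broken by the lexicographically lowest pair of cluster representative
labels (a cluster is represented by its smallest leaf label), making
the topology deterministic on equidistant inputs. Negative branch-
length estimates are retained internally — on additive inputs the tree
reproduces the input matrix exactly, which the tests exercise — and
clamped to zero only at Newick export, with a warning. Bootstrap:
alignment columns resampled with replacement, NJ re-run per replicate,
and each internal edge of the original tree annotated with the
percentage of replicates containing the same bipartition (supports are
mapped onto the single original topology, not a consensus tree).
Replicates whose resampled matrix is undefined are dropped and logged.
A species is identified when some edge bipartition isolates exactly its
leaves; singletons are monophyletic by definition. With an outgroup
present this unrooted test equals the rooted test after rooting on the
outgroup edge, because the outgroup is never part of a study species;
outgroup samples are excluded from rates, divergence parameters and
best-match references, and used for rooting/display only.

**Ranking.** Regions are ordered lexicographically by (tree species
rate, best-match species rate, average interspecific distance),
descending, ties broken by name. No composite score is invented — the
criteria are ordered, not weighted.

## Synthetic data generator

The generator exists so that every stage is testable against known
truth. Sequences evolve by the K2P process itself (per-site transition
probability matrix with transition/transversion rate ratio κ, default
2), so the downstream estimator is correctly specified and the expected
K2P distance between two tips equals their tree path length — recovery
tests are then pure Monte-Carlo-error checks. Model misspecification is
deliberately out of scope.

Structure: a species tree — Yule (pure birth) by default, with branch
lengths rescaled so the mean tip-to-tip path equals twice the requested
depth, or an equidistant star radiation for scenarios that must
guarantee a clean gap (under Yule the minimum species-pair path can be
arbitrarily small, which genuinely prevents 100% identification; that
is a feature when emulating recent radiations and a nuisance when a
clean-gap scenario is wanted) — then per-species subtrees: a uniform
star by default, or a simple Kingman coalescent for variable
within-species depths. The species tree is scaled to
(interspecific target − intraspecific target) so that the expected
distance between heterospecific *individuals* (species path plus two
tip branches) hits the interspecific target exactly; conspecific pairs
hit the intraspecific target by construction. Terminal indels
(Poisson-trimmed ends padded with gaps) induce length variation without
requiring alignment. GC is controlled only through the root
composition; K2P's stationary distribution is uniform, but drift toward
it is negligible at depths ≤ 0.1 substitutions/site, so simulated GC
stays near the root value.

Everything is driven by one `numpy` Generator seeded from the config,
and identical seeds reproduce identical FASTA bytes.

### The emulated study design

`barcodegap.study` fixes one design used by the analysis drivers and
the acceptance script: 13 congeneric species, 69 individuals with
per-species counts (25, 15, 8, 5, 4, 3, 3, 1, 1, 1, 1, 1, 1) — heavy
sampling of two cultivated species, six singletons — and three loci:
two nuclear spacers (225 bp and 445 bp, GC-rich, mean interspecific
depth 0.080/0.085, intraspecific 0.009/0.010) and one plastid spacer
(450 bp, AT-rich, length-variable, interspecific 0.045, intraspecific
0.0005). Each locus keeps a region-specific random subset of 61/63/65
individuals, emulating sequencing failure and making the cross-region
paired sample sets differ. These sizes run the full pipeline, including
a 1000-replicate bootstrap per region, in about a minute.

What passing on such data shows — and does not. The generator produces
ungapped-by-construction alignments, independent sites, no
recombination, paralogy, heterotachy or base-composition heterogeneity,
and species that are reciprocally monophyletic populations by design.
Results on real spacers, which violate several of these (notably
alignment ambiguity in length-variable plastid spacers and nuclear
paralogs), can be worse than the synthetic rates; the synthetic runs
validate the *computations*, not any field protocol.

## Numerical choices and degenerate inputs

* SDs are population SDs; contributing-value counts are always carried.
* Histogram bins are half-open and left-closed from 0; a value on an
  edge belongs to the upper bin.
* NJ requires ≥ 3 labels and a fully defined matrix; undefined entries
  must be resolved (drop/cap) before tree building, and the pipeline
  builds trees from the error-policy matrix so an undefined pair aborts
  the region with a stage-named error rather than producing a silent
  partial tree.
* Wilcoxon with all-zero differences returns n = 0, p = 1.
* A region whose species are all singletons reports intraspecific
  parameters and the gap as unavailable and continues; single-region
  runs skip the between-region stage with a log notice.
* Warnings (dropped pairs, dropped bootstrap replicates, clamped branch
  lengths, excluded singleton queries) are mandatory log entries, never
  silent.

## Known limitations

* Multiple sequence alignment is consumed, not produced; unaligned
  real data must be aligned upstream (the simulator induces alignment
  by construction).
* The best-match assessment is leave-one-out within the study's own
  sequences; it does not model searching a public database with its
  taxonomically heterogeneous references.
* Bootstrap supports are attached to the original topology; very low
  supports on that topology are reported as-is rather than collapsed.
* The exact Wilcoxon path enumerates 2^n patterns and is capped at
  n = 12 by default; beyond that only the corrected normal
  approximation is reported.
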