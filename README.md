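# barcodegap

Evaluation toolkit for candidate DNA-barcode loci in closely related
plant (or animal) species complexes. Given species-labelled sequences
for one or more barcode regions, it answers the questions a barcoding
study asks of each locus: how divergent are species relative to the
variation within them, is there a usable barcoding gap, and how often
does the locus actually identify specimens to species?

It is aimed at molecular taxonomists comparing loci (e.g. nuclear
ribosomal spacers such as ITS2 or ETS against plastid spacers such as
*trnH-psbA*) on congeneric material, where species are recently
diverged, sampling per species is uneven, and several species may be
represented by a single specimen.

## What it computes

**Distances.** All pairwise distances use the Kimura 2-parameter model
with pairwise deletion of gap/ambiguous columns. With transition
proportion *P* (A↔G, C↔T) and transversion proportion *Q* over the
shared sites of a pair,

    d = -½ ln(1 - 2P - Q) - ¼ ln(1 - 2Q)

Pairs where the correction is undefined (1-2P-Q ≤ 0 or 1-2Q ≤ 0) raise
a saturation error, or are dropped/capped under an explicit policy.

**Divergence parameters** (each mean ± population SD):

| interspecific | intraspecific |
|---|---|
| mean over all heterospecific sample pairs | mean over all conspecific pairs |
| θ′ — mean over partner species of the species-pair mean distance, averaged over species (one vote per species, so uneven sampling cannot bias it) | θ — per-species mean conspecific distance, averaged over species with ≥ 2 individuals |
| minimum interspecific distance — per-species nearest heterospecific neighbour, averaged | coalescent depth — per-species maximum conspecific distance, averaged |

**Barcoding gap.** The conspecific and heterospecific distance
distributions binned at 0.01 substitutions/site, with an overlap flag
(max intra ≥ min inter) and the fraction of conspecific pairs above the
smallest heterospecific distance.

**Between-region comparisons.** Wilcoxon signed-rank tests on matched
units: species pairs (interspecific) or conspecific sample pairs
sequenced in both regions (intraspecific). Exact sign-flip enumeration
for n ≤ 12, normal approximation with tie and continuity corrections
otherwise.

**Identification efficiency**, two ways:

* *best-match*: each sequence queried against all others
  (leave-one-out); the hit set is everything within 1e-9 of the minimum
  distance; verdicts are correct / ambiguous / incorrect, and a species
  is identified when every one of its queries is correct;
* *tree-based*: Saitou–Nei neighbor joining on the K2P matrix with
  bootstrap supports from column resampling; a species is identified
  when its individuals form a monophyletic group (singletons count).

A built-in simulator (K2P substitution process down a Yule or
equidistant species tree, star or coalescent within-species structure,
optional terminal indels) generates labelled datasets with known truth
for testing and calibration.

## Worked example

The numbered drivers under `analysis/` run a complete emulated study:
13 congeneric species, 69 individuals sampled unevenly (six
singletons), three loci with contrasting divergence, region-specific
sequencing success.

```bash
cd analysis
python 01_simulate.py --seed 1
python 02_summaries.py
python 03_divergence.py
python 04_wilcoxon.py
python 05_identification.py --replicates 1000 --seed 1
```

At seed 1 this prints, among other things:

```
ITS2: avg inter 0.0737 ± 0.0275, avg intra 0.0065 ± 0.0049, gap overlap True (37.5% ...)
ITS2 vs ETS [species-pair]: W+=987 W-=1224 n=66 p=0.451 -> A=B
ITS2 vs trnH-psbA [species-pair]: W+=2113 W-=98 n=66 p=1.25e-10 -> A>>B
ITS2: best-match 100.00% of 7 evaluable species (100.00% of 55 queries); tree 92.31% of 13 species monophyletic
best region by identification efficiency: ITS2
```

Read: the ITS2-like locus recovers a mean interspecific distance of
0.074 against 0.0065 within species, but the two distributions still
overlap (no clean barcoding gap). Its interspecific divergence is
statistically indistinguishable from the other nuclear spacer
(p = 0.45) and far exceeds the plastid spacer (p ≈ 1e-10), and it
identifies every evaluable species by best-match — so it ranks first.
All tables land in `results/` (`summary.tsv`, `divergence.tsv`,
`wilcoxon.tsv`, `identification.tsv`, `ranking.tsv`, per-region gap
histograms, verdicts and Newick trees with bootstrap supports).

The same operations are available as a CLI
(`barcodegap summarize|distances|divergence|gap|wilcoxon|identify-best-match|identify-tree|simulate|evaluate`)
and as plain library calls; see `docs/methods.md` for the model and
its assumptions.

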