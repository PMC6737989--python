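# Methods

`tissueatlas` implements a multi-tissue mRNA/miRNA expression-atlas
analysis for a nine-organ design (fat, heart, kidney, liver, lung,
skeletal muscle, ovary, spleen, testis) in which muscle is sampled at
three postnatal stages (D0, D30, D240), giving eleven libraries in
total.  The pipeline starts from count matrices; read processing and
alignment are out of scope.

## Normalization

mRNA counts are converted to RPKM: `counts * 1e9 / (library_size *
transcript_length)`.  A zero-depth library yields an all-zero column
rather than NaN.  Mature miRNAs are all ~22 nt, so their "TPM" carries
no length term: `counts * 1e6 / library_size`, i.e. reads per million
mapped miRNA reads, the standard small-RNA practice.  A length-aware
mode would be redundant at negligible length variation and is not the
default.  Features with abundance strictly above 0.1 in at least one
library are flagged expressed.  Sample similarity is Pearson
correlation of `log2(x + 1)` (pseudocount 1 handles zeros and is the
dominant convention), clustered with average linkage on `1 - r`
(average linkage is the least shape-sensitive default; configurable).

## Atlas classification

The tissue panel is one column per organ, with muscle represented by
its adult (D240) library; D0 and D30 are reserved for the
developmental analyses.

* **Universal mRNA** — RPKM strictly above 10 in every tissue.
* **Universal miRNA** — TPM strictly above 1 everywhere and
  coefficient of variation (sample sd over mean, n-1 denominator)
  below 0.5.
* **Tissue-associated** — across-tissue z-score >= 1.5 in that tissue
  with abundance >= 1 there.  Z-scores use the n-1 standard deviation
  on the linear abundance scale (a log-scale mode would change the
  call set; the linear rule is the one stated with unlogged RPKM).
  Constant profiles are associated with nothing; a feature may be
  associated with several tissues.
* **Tissue-specific** — abundance >= 10 in the tissue and strictly
  greater than 10 times the *leave-one-out mean* of the other tissues.
  "Mean of the other tissues" is read as the mean, not the maximum.
  When the other tissues are all zero the fold condition is vacuously
  satisfied.  For T <= 11 tissues and fold 10 the specific sets are
  provably disjoint: mutual specificity of two tissues would require
  (T-1)^2 > 100.

## Co-expression network and Markov clustering

Expressed genes become nodes; an edge joins two genes when the Pearson
correlation of their tissue-panel profiles is >= 0.90.  Edges enter
Markov clustering unweighted (thresholding then clustering the
topology; using r as a weight is an option).  MCL: self-loops of
weight 1, column-stochastic normalization, then repeated expansion
(matrix squaring) and inflation (elementwise power 2.2 with column
renormalization), pruning entries below 1e-5, until the largest column
change falls below 1e-6 (at most 200 iterations; non-convergence
returns the current state with a warning flag).  Clusters are the
connected components of the limit matrix's support; size-1 components
are reported separately as singletons.  The pruning threshold and
tolerance are insensitive within an order of magnitude on test graphs.
Clusters are labelled by the tissue with maximal mean member
expression; exact ties go to the alphabetically first tissue with a
logged warning.  Driver scripts cap the graph at the 800 most variable
expressed genes so that the dense MCL iteration stays fast on one CPU;
the cap is a parameter.

## Intragenic miRNA / host-gene pairs

Five conjunctive criteria, applied as commuting filters:

1. the miRNA locus is fully contained in the gene span (the "100%
   overlap" of a ~22-90 nt locus with a gene is read as containment —
   the literal reverse reading is impossible);
2. same strand;
3. the miRNA has exactly one genomic locus (copy counts are computed
   at annotation load as loci sharing a name);
4. both partners reach abundance >= 0.1 in at least five libraries
   (inclusive >=, unlike the strict expressed flag);
5. Pearson r > 0.6 with two-sided p < 0.05, where
   `t = r * sqrt((n-2)/(1-r^2))` with n-2 degrees of freedom.
   Correlations run across all eleven libraries; a nine-column
   tissue-panel mode is available.  Two-sided is the conservative
   choice; the r > 0.6 condition already fixes the direction.

## Differential expression and dynamic patterns

DESeq2 is not reimplemented; the stage comparisons use a transparent
negative-binomial Wald surrogate.  Counts are normalized with
median-of-ratios size factors (geometric-mean reference over features
positive in all samples; column-sum fallback with a warning).  The
fold change is `log2((mean_B + 0.5) / (mean_A + 0.5))` — pseudocount
0.5 prevents infinite folds and is configurable in spirit (a module
constant).  The Wald statistic divides the fold by a delta-method
standard error from `Var(K) = mu + alpha * mu^2`; p-values are
two-sided normal.  Dispersion alpha is supplied or pooled by method of
moments across features; a single-library design cannot estimate it
and must supply one (the driver uses alpha = 0.1, a typical bulk
RNA-seq value).  The surrogate is validated by calibration, not by
matching DESeq2 output: on an all-null simulation its p-values are
uniform (KS) and the BH-discovery fraction is at the nominal level.
Calls use log2FC >= 1 and BH FDR < 0.05 (BH via statsmodels, checked
against a hand step-up).  Calls from the two consecutive comparisons
(D0 vs D30, D30 vs D240) are intersected into up/down dynamic
patterns; features significant in only one comparison are reported
separately, and the up_up / down_down classes are flagged as monotone
throughout development.

## miRNA-target interaction screen

Candidate pairs have Pearson r strictly below -0.5.  The screen runs
across all eleven libraries (the screening domain is configurable);
the *persistent* subset additionally requires r < -0.5 across the
three muscle-stage columns alone (n = 3, so that correlation is
reported without a p-value).  A screened pair is kept when the target
3'UTR carries a canonical seed site:

* **8mer** — exact Watson-Crick complement of miRNA positions 2-8 with
  an A opposite position 1;
* **7mer-m8** — complement of positions 2-8;
* **7mer-A1** — complement of positions 2-7 plus the A1 adenine.

Sites are anchored at the UTR position opposite miRNA position 1; only
the highest tier is reported per anchor; no G:U is allowed in the seed
match; the A of A1-type sites is a sequence requirement on the target,
not a pairing requirement.  A 7mer-m8 site may end flush with the UTR
3' end.

Duplex stability is scored by dynamic programming over strictly
intermolecular, antiparallel, non-crossing pairings: +4.1 kcal/mol
initiation; stacking of adjacent pairs from a reduced pair-additive
nearest-neighbor table `stack(p1,p2) = -(w(p1)+w(p2))` with w(G:C) =
1.6, w(A:U) = 1.1, w(G:U) = 0.5 kcal/mol; +4.0 loop opening plus +0.5
per unpaired nucleotide between non-adjacent pairs; dangling ends
free.  The table is symmetric under reading the duplex from the other
side, and G:U stacks are strictly weaker than Watson-Crick ones, which
makes a perfect complement strictly optimal against every single-point
target mutation.  The DP is O(n*m) via a prefix-minimum auxiliary
matrix and is validated against exhaustive enumeration of all
pairings at small sizes.  Absolute energies are *not* calibrated
against a full nearest-neighbor model; only orderings are meaningful,
and the energy filter is therefore off by default (site presence
suffices; `mfe_max` enables it).

## Synthetic atlas and planted truth

The generator plants expression on the normalized scale (expected RPKM
/ TPM), rescales background features per library so each column's
expected depth matches the design (planted values survive
normalization exactly in expectation), and draws counts as
gamma-Poisson with dispersion alpha = 0.1 (Var = mu + alpha mu^2);
alpha -> 0 gives Poisson.  Defaults: 5,000 genes, 300 miRNAs, gene
lengths uniform on 500-5,000 nt, 2e7 mRNA / 2e6 miRNA reads per
library, 500 nt UTRs, 22 nt miRNAs.

* Background genes: lognormal baseline (median ~5 relative units,
  capped), per-tissue lognormal modulation sigma 0.4, and two randomly
  silenced tissues (factor 1e-3) so no background gene is universally
  expressed.
* Universal genes (30): flat at RPKM 80-200 — high enough that the
  strict >10 rule holds in every library at the default counting
  noise.
* Tissue-specific genes (20 per tissue): baseline 1.5-3, elevated
  50-fold in exactly one tissue (all three stage columns when that
  tissue is muscle).  The planted fold is required to exceed the
  10-fold cutoff so recovery is well-posed.
* Tissue-associated genes (10 per tissue): elevated 5-fold — z ~ 2.4,
  comfortably over the 1.5 cutoff yet far enough under the 10-fold
  rule that noise rarely promotes them to specific.
* Host genes and intragenic miRNAs: hosts get a wider tissue profile
  (sigma 1.0, three silenced tissues) so co-expression is not drowned
  by counting noise; each intragenic miRNA sits fully inside its host,
  same strand, single copy, with TPM proportional to the host profile
  (multiplicative noise sigma 0.05).  One labelled violation of each
  kind is planted: antisense, partial overlap, multi-copy,
  narrow-breadth, and a low-correlation miRNA whose profile is the
  affine anti-image of its host (so criterion 5 cannot pass by
  chance).
* Repressor pairs (10): the miRNA decreases 16-fold across the muscle
  stages and varies across tissues; the target is an exact affine
  anti-image of the miRNA profile over every library, so the
  population correlation is -1 on any column subset and only counting
  noise moves it.  A canonical site (type drawn uniformly from the
  three tiers) is spliced into the target UTR, with guards against
  accidental tier upgrades at the splice boundaries.  Decoy pairs (10)
  get the same anti-correlation but a UTR regenerated until the
  scanner finds no site for their miRNA.

What the generator does *not* emulate: isoforms and length ambiguity,
GC or mappability bias, batch effects, correlated gene programs beyond
the planted ones, miRNA arm switching, non-canonical or G:U seed
sites, and biological replicates (each library is a single pooled
sample, as in the study design).  Passing recovery tests therefore
demonstrates correctness of the decision rules under the stated noise
model, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

Strictness follows the stated rules: expressed and universal use
strict `>`, breadth uses inclusive `>=`, the screen uses strict `<`.
Zero-variance profiles are excluded from correlation structures (with
logged counts) and can never be tissue-associated; a constant sample
is excluded from similarity clustering with its correlations reported
as undefined.  Result tables serialize floats at 6 decimals,
correlations at 7.  Two runs with the same inputs, configuration and
seed produce byte-identical outputs.

## Problem sizes in the test and acceptance runs

Recovery checks use ten seeds of the default 5,000-gene atlas;
interaction recovery in the acceptance script uses five seeds; the
oracle comparisons use 1,000 random miRNA/UTR pairs, 200 tiny duplex
instances, and 10,000 uniform p-values; the driver scripts run one
full atlas end to end.  These sizes make every check reproducible on a
laptop-class single core in minutes.
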