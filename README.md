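# tissueatlas

Analysis pipeline for a multi-tissue mRNA/miRNA expression atlas:
nine organs with skeletal muscle sampled at three developmental stages
(D0, D30, D240 postnatal days).  The package quantifies expression,
classifies features by tissue breadth, clusters the co-expression
network, discovers intragenic miRNA/host-gene pairs, partitions
developmental expression dynamics, and screens miRNA-mRNA repressive
interactions.  A synthetic-atlas generator with planted ground truth
makes every stage verifiable without access to deposited sequencing
data.

## The rules at the core

With abundance `x_gt` (RPKM for genes, reads-per-million TPM for
miRNAs) of feature g in tissue t:

* **expressed** — `x_gt > 0.1` in at least one library;
* **universal mRNA** — `x_gt > 10` in every tissue; **universal
  miRNA** — `x_gt > 1` everywhere and CV `sd/mean < 0.5`;
* **tissue-associated** — z-score `(x_gt - mean_g)/sd_g >= 1.5` with
  `x_gt >= 1`;
* **tissue-specific** — `x_gt >= 10` and `x_gt > 10 * mean(x_g, other
  tissues)` (leave-one-out mean);
* **co-expression network** — edges at Pearson `r >= 0.90`, Markov
  clustering at inflation 2.2;
* **host-gene pairs** — miRNA locus contained in the gene, same
  strand, single copy, both expressed (>= 0.1) in >= 5 tissues, and
  `r > 0.6` with `p < 0.05`;
* **differential expression** — NB Wald test, `|log2FC| >= 1` and BH
  `FDR < 0.05`, between consecutive muscle stages, with up/down
  pattern overlap across the two comparisons;
* **interaction screen** — `r < -0.5`, a canonical 3'UTR seed site
  (8mer / 7mer-m8 / 7mer-A1, no G:U), optional duplex-energy filter;
  pairs also below -0.5 across the three stages are "persistent".

See `docs/methods.md` for the models, assumptions and numerical
choices.

## Worked example

Generate a synthetic atlas and run the analysis steps:

```sh
python analysis/01_simulate_atlas.py
python analysis/02_quantify_normalize.py
python analysis/03_classify_atlas.py
python analysis/04_coexpression_network.py
python analysis/05_host_gene_pairs.py
python analysis/06_muscle_de_patterns.py
python analysis/07_interaction_screen.py
```

Output from one run (seed 0):

```
atlas: 5000 genes x 11 samples, 300 miRNAs, 5301 annotation records
planted: 30 universal genes, 180 specific genes, 30 host pairs,
         10 repressor and 10 decoy pairs
expressed: 5000/5000 genes, 300/300 miRNAs (abundance > 0.1 anywhere)
sample similarity: muscle_D30 vs muscle_D240 r = 0.969; testis vs muscle_D240 r = 0.107
mRNA: 50 universal, 3280 associated calls, 187 tissue-specific calls
planted-truth recovery: {'universal_planted_recovered': '30/30',
                         'specific_sensitivity': 1.0, 'specific_precision': 0.9626}
graph: 800 nodes, 5978 edges at r >= 0.90
MCL (inflation 2.2): 125 clusters (largest [50, 48, 47, 45, 41]), 97 singletons
34 containment candidates, 29 passed all five criteria
planted pairs recovered: 29/30; all five planted violations rejected
D0_vs_D30: 80 up, 77 down; D30_vs_D240: 46 up, 43 down
74350 pairs below r = -0.5; 3862 also carry a 3'UTR seed site;
1775 persist across the muscle stages
planted repressor pairs in persistent set: 9/10; decoys passing: 0
```

Reading the numbers: the two adjacent muscle stages are by far the
most similar libraries (r = 0.97 versus ~0.1 between unrelated
organs); all 30 planted housekeeping-like genes and all 180 planted
tissue-specific genes are recovered, with ~4% of specific calls being
chance background fluctuations; the co-expression clusters are
dominated by single-tissue programs; 29 of 30 planted intragenic
miRNA/host pairs pass all five criteria (one falls just under the
correlation cutoff at this noise level) while every planted violation
is rejected for its designated reason; and the interaction screen
narrows ~74k anti-correlated pairs to ~3.9k with genuine seed sites,
recovering 9 of 10 planted repressors in the persistent set and zero
scrambled-site decoys.

The same stages are available as CLI subcommands
(`tissueatlas simulate | quantify | classify | network | hostpairs |
de | interact | run-all`).

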