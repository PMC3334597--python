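# chromotif

Predicting transcription-factor (TF) target genes in a compact genome
like *Saccharomyces cerevisiae*'s from sequence motifs alone is noisy:
thousands of promoters match a typical position-specific scoring matrix
(PSSM), but only a fraction are bound. `chromotif` implements an
integrative predictor that combines two complementary channels per gene —

* the **cumulative motif matching score** of the gene's promoter
  (sum of log-odds scores of all PSSM occurrences on both strands), and
* **chromatin signals**: mean probe-level histone occupancy /
  methylation / acetylation in fixed windows around the ATG start codon
  (500 bp / 1000 bp up- and downstream), in the upstream intergenic
  region (IR), and over the ORF —

in a per-TF radial-kernel SVM trained against ChIP-derived target calls
(gene is a target iff binding *P* < 0.01), evaluated by repeated
two-fold cross-validation with ROC/AUC and positive predictive value
(PPV). Downstream of the classifier the package profiles each TF's
targets across 25 chromatin modifications, clusters TFs into
**histone-sensitive** and **histone-insensitive** classes with k-means
(k = 2), contrasts the classes on external attributes (rank-sum and
Fisher tests), detects **TF cooperativity** by cross-PSSM prediction
(TF A's targets predicted better by TF B's motif), compares
condition-matched vs mismatched chromatin features, and extends the
model to genome-wide 100-bp-bin binding-site prediction.

It is aimed at regulatory-genomics researchers who want a tested,
scriptable reimplementation of this analysis stack with a fully
synthetic, ground-truthed data generator for validation.

## Core quantities

For a PSSM with probabilities $p_{ij}$ (position $i$, base $j$) and
background frequencies $p_b(j)$ (A=T=0.315, C=G=0.185 at 37% GC):

* information content $\mathrm{IC} = \sum_{i,j} p_{ij}\log_2\!\frac{p_{ij}}{p_b(j)}$ (bits),
* PSSM similarity $= \max_{\text{ungapped offsets}} \frac{1}{n}\sum_{i,j} p^{(1)}_{ij}\,p^{(2)}_{ij} \in [0,1]$,
* window score $= \sum_i \log_2\frac{p_{i,b_i}+\epsilon}{p_b(b_i)}$, hits are
  windows scoring ≥ 60% of the maximum achievable score (configurable),
* AUC = Mann–Whitney probability that a random target outranks a random
  non-target; PPV@k = fraction of the top-k predictions that are targets.

## Worked example

```bash
python examples/01_target_prediction.py
```

```
TF TF005 (histone-sensitive), 57 called targets of 1500 genes
  PSSM only          AUC = 0.536   PPV@57 = 0.053
  chromatin only     AUC = 0.878   PPV@57 = 0.684
  PSSM + chromatin   AUC = 0.877   PPV@57 = 0.684
TF TF000 (histone-insensitive), 60 called targets of 1500 genes
  PSSM only          AUC = 0.612   PPV@60 = 0.100
  chromatin only     AUC = 0.501   PPV@60 = 0.067
  PSSM + chromatin   AUC = 0.566   PPV@60 = 0.083
```

The world is synthetic with planted truth: TF005's targets carry 1.0 SD
chromatin shifts in their promoters, so the chromatin channel dominates
(AUC 0.88 vs 0.54 for the motif alone); TF000 has no chromatin signal,
so only its planted motif informs the model. The other examples cover
sensitivity classification (`02`), cooperativity via cross-PSSM
prediction (`03`), condition specificity (`04`), 100-bp-bin binding-site
prediction (`05`) and bound-vs-unbound site chromatin contrasts (`06`).

A thin CLI mirrors the staged pipeline
(`chromotif simulate|scan|signals|train|profiles|sensitivity WORKDIR`),
writing TSV outputs plus a JSON run manifest into the work directory.

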