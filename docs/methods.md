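# Methods

## Model

For each TF the package trains a binary classifier over genes. The
positive class is defined operationally from ChIP binding *P*-values:
a gene is a called target iff *P* < cutoff, strict inequality, with
cutoff 0.01 by default (stricter cutoffs give purer positives and higher
AUC at the cost of fewer training examples; the package exposes the
cutoff and reports the trade-off). Features per gene:

* **Motif channel.** The promoter (the gene's upstream intergenic
  interval) is scanned on both strands with the TF's PSSM. Window score
  is the log2-odds against an i.i.d. background from the genome GC
  fraction; a pseudocount (default 0.01) is added to the probabilities
  and rows renormalized before the log so absent bases score finitely.
  Windows scoring at or above a threshold — default 60% of the PSSM's
  maximum achievable score, since no canonical occurrence threshold
  exists — are hits; overlapping hits all count. The feature is the
  *cumulative matching score*, the sum of hit scores (0 when no hits).
  Summing log-odds bits is one of several defensible readings of a
  "cumulative" occurrence score; it is the package's choice and is
  configurable via the scan threshold and pseudocount.
* **Chromatin channel.** Probe-level tracks are aggregated per gene
  region as the unweighted mean of all probes overlapping the region by
  at least 1 bp (a midpoint-inclusion rule is available). Regions:
  ATG-flanking windows (up/down, 500 and 1000 bp, mirrored for minus-
  strand genes and truncated at contig edges), the upstream intergenic
  region, and the ORF. Regions covered by no probe are missing; genes
  missing more than half of the selected feature columns are dropped,
  the remaining gaps mean-imputed per column.

The classifier is an RBF-kernel SVM with reference-style defaults
(gamma = 1/n_features, C = 1) wrapped in a pipeline whose
standardization is fit on the training fold only, so no test-fold
statistics leak into the transform. Two deliberate deviations from the
plain defaults:

* **Inverse-prevalence class weights.** Target sets are ~5% of genes;
  at C = 1 the unweighted hinge loss collapses toward the all-negative
  solution (measured: motif-only training AUC 0.54 unweighted vs 0.63
  weighted, the latter matching the raw feature's rank AUC). Balanced
  weights restore the intended geometry without touching kernel, C or
  gamma.
* **Scores via a logistic squash of the decision function** rather than
  internally cross-validated probability calibration. The map is
  strictly monotone, so every ranking metric (AUC, ROC, PPV) is
  identical to the calibrated version, at a fraction of the fit cost;
  the scores are in [0, 1] but are not calibrated probabilities.

Evaluation is repeated two-fold cross-validation: genes are split at
random into equal halves (redrawn, up to 100 times, if a half lacks a
class), each half is scored by a model trained on the other, and the
per-repeat AUC is the mean over held-out halves. The package default is
50 repeats; the test-suite and acceptance runs use 3–5 repeats, which
changes the AUC estimate's noise, not its expectation. AUC is computed
by the rank (Mann–Whitney) formula with ties counted half, which equals
the trapezoidal area under the ROC. PPV@k uses stable original order to
break score ties, and PPV@n equals prevalence by construction.

## Downstream analyses

**Sensitivity profiling.** A TF's *target modification profile* is the
mean signal of its called targets per modification (1-kb upstream
windowed set plus intergenic acetylation set; TFs with fewer than 10
targets are excluded). Profiles are z-normalized per modification
across TFs and clustered with k-means (k = 2, 50 restarts, seeded,
best inertia). The cluster with larger mean |z| is labeled
*histone-sensitive* — this operationalizes "larger variations, more
high and low signals"; a per-profile-variance criterion is available.
*Differential profiles* are Welch t-statistics (targets minus
non-targets) per modification; Welch rather than pooled variance
because target sets are small and their variance need not match the
genome background. Modification pairs whose differential profiles
correlate with |r| > 0.5 across TFs form the redundancy network.

**Cross-PSSM cooperativity.** Every TF's targets are predicted with
every TF's motif feature (chromatin features included in all cells).
A pair (A, B) is flagged when B's motif beats A's own by more than
0.02 AUC — chosen below the 0.03–0.04 gains seen in known cooperating
pairs, since no published threshold exists.

**Condition comparison.** Two feature tables sharing genes and labels
(the condition-of-interest targets) but differing in the condition of
their chromatin features are evaluated on identical CV splits, making
the AUC difference a paired comparison.

**Site contrast.** Verified sites are compared with motif matches whose
gene has ChIP *P* > 0.4 and which lie ≥ 2 kb from any verified site.
Site-level signals are the mean of covering probes; an uncovered site
is widened to the nearest probe within 500 bp, else dropped. Per
modification a Welch t is reported; no multiple-testing correction is
applied by default (raw per-modification *P*-values are the quantity of
interest; Benjamini–Hochberg is a flag away in user code via
`scipy.stats.false_discovery_control`).

**Enrichment statistics.** One-sided Fisher tests are computed as the
exact hypergeometric upper tail (identical to the one-sided Fisher
exact test); the two-sided variant delegates to scipy. Co-regulation
scans test every TF pair's target overlap against the hypergeometric
null at alpha = 0.05 and partition significant pairs by sensitivity
class (SS/II/SI). Class attribute comparisons use the two-sided
Wilcoxon rank-sum test.

**Bin-level site prediction.** Contigs are tiled into 100-bp bins
(trailing partial bin kept); a bin is positive iff it overlaps any peak
by ≥ 1 bp. Per-bin motif scores and chromatin means feed the same
classifier/CV machinery as the gene-level model.

## Synthetic worlds

The generator emulates the structure of the emulated experimental
setting so every stage has ground truth:

* **Layout.** Genes are placed sequentially on a few contigs, each with
  a dedicated 800-bp upstream intergenic promoter on its strand side,
  ORFs of 500–1500 bp, and 100-bp spacers. Background sequence is
  i.i.d. at 37% GC; no dinucleotide structure (sufficient for testing a
  log-odds scanner, not for estimating genomic false-positive rates).
* **Motifs.** Per-TF PSSMs of length 7–10 with consensus weight 0.85.
  True targets are i.i.d. Bernoulli per (gene, TF) with prevalence 0.05
  (~100 targets per TF at 2000 genes). Each target promoter receives,
  with probability 0.8 by default, one site sampled from the PSSM at a
  uniform position and strand. Cooperative pairs plant the partner's
  motif instead, making the TF an indirect binder with a decoy PSSM.
* **Tracks.** A shared probe grid (60-bp probes, 85% of slots kept
  uniformly at random) carries i.i.d. N(0,1) values per modification
  (14 windowed + 11 IR/ORF). Sensitive TFs (a configurable fraction;
  default 0.33, echoing the observed 68/203 class split) shift 10 of
  the 25 modifications by ±1.0 SD in their targets' promoter regions.
  The shift *signs* follow one per-world template shared by all
  sensitive TFs: chromatin marks have coherent directions, and without
  a shared template sensitive TFs scatter across orthants and no
  two-cluster structure exists for k-means to find (measured agreement
  drops from ≥0.93 to ~0.65). Optional site-level depletion (default
  −1.5 SD on the two occupancy-like tracks) is added to probes covering
  planted sites.
* **ChIP P-values.** Targets draw Beta(0.1, 1) (63% fall below 0.01,
  50% below 0.001), non-targets Uniform(0, 1). Called labels are
  therefore realistically noisy relative to the planted truth, which is
  what makes the cutoff sweep informative.
* **Conditions.** Condition B redraws target sets independently and
  shifts condition-B tracks at B-targets, so only same-condition
  chromatin features predict B targets beyond the motif channel.
* **Attributes.** Per-TF hierarchy level and PPI degree are drawn with
  planted class differences (sensitive TFs higher), giving the group
  comparison demos a known answer.

Scenario configurations used in validation: the clustering worlds use
60 TFs with a 0.5 sensitive fraction and no motif planting (motifs are
irrelevant to profile clustering); the cooperativity and site-contrast
worlds set the sensitive fraction to 0 so that the motif channel and the
site-level depletion, respectively, are isolated — when the TF under
study also carries promoter-wide shifts the chromatin channel saturates
the comparison (cooperativity gains shrink to ~0.001 AUC) or cancels
the planted depletion at its sites.

What the generator does **not** emulate: nucleosome positioning
structure, probe-intensity normalization artifacts, correlated
modification backgrounds, non-uniform intergenic lengths, or motif
clustering/homotypic runs. Passing tests therefore demonstrate that the
implementation recovers planted structure under its stated noise model,
not that the method attains any particular accuracy on real chromatin
data.

## Numerical choices and conventions

* Coordinates are 0-based half-open everywhere; annotation files may
  declare `# coords: 1-based` and are converted on read.
* The information content uses the positive relative-entropy sign
  convention (IC ≥ 0, zero iff the matrix equals the background), with
  0·log 0 = 0 and an optional pseudocount; log base 2 (bits).
* PSSM similarity for unequal lengths maximizes over ungapped offsets,
  divides by the overlap length, and requires an overlap of at least
  min(3, shorter length) so a 1-column graze cannot dominate.
* Scan windows containing N are skipped rather than scored.
* MEME-style motif blocks are written with 17 significant digits and
  parsed directly so probabilities round-trip to 1e-9; rows must sum to
  1 within 1e-6 and are renormalized exactly on read.
* k-means label assignment is invariant to TF input order and cluster
  index permutation; an all-identical profile matrix yields
  all-insensitive with a warning rather than an arbitrary split.
* Degenerate CV folds are redrawn up to 100 times, then error; fewer
  than 10 positives (configurable) is an error, not a silent fit.
* Per-world audit SEs for the planted-shift recovery are computed
  across TF-level means because a TF's modifications share its target
  set; even so, overlapping target sets across TFs correlate the
  TF-level means, so calibrated recovery checks average independent
  seed replicates.

## Problem sizes

Validation runs use 2000-gene / 20-TF worlds over 10 seeds for the
model-ordering, cutoff and condition analyses (3 CV repeats), 1200-gene
/ 60-TF worlds for clustering, 1000-gene / 4-TF worlds for the
cross-PSSM scan (5 repeats; the scan is quadratic in TF count), and
800-gene worlds for site contrasts. These sizes were chosen to hold the
Monte-Carlo error of each checked quantity comfortably below its
acceptance margin; the library defaults (50 CV repeats) remain the
recommended setting for analyses of real data.

## Limitations

* The SVM scores are monotone margins, not calibrated probabilities.
* The intergenic region is approximated by each gene's dedicated
  upstream interval; real array designs define IRs independently of
  gene annotations and can assign one IR to two divergent genes.
* Promoters are non-overlapping by construction; divergent promoters
  sharing an IR (common in the real yeast genome) are not modeled.
* The correlation network uses plain Pearson correlation across TFs
  with listwise deletion of TFs with any missing differential value.
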