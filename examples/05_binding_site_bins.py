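"""Genome-wide binding-site prediction on 100-bp bins.

ChIP-seq-style peak intervals (here: the planted binding sites of one
TF) label fixed-width genome bins positive or negative; each bin gets a
cumulative motif score and mean chromatin signals, and the same SVM
machinery used for target genes ranks the bins.  At sub-percent
prevalence the combined model's advantage shows up most clearly in the
positive predictive value, not the AUC.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np
import pandas as pd

from chromotif import (
    SyntheticConfig,
    FeatureTable,
    bin_genome_and_label,
    cv_train_evaluate,
    generate_world,
)
from chromotif.signals import aggregate_region_signal
from chromotif.pipeline import bin_motif_scores, genome_motif_hits

world = generate_world(SyntheticConfig(n_genes=1000, n_tfs=3, seed=4, two_conditions=False,
                                       target_prevalence=0.15, sensitive_fraction=0.0,
                                       motif_plant_prob=1.0, site_depletion=-1.5))
tf = "TF000"
peaks = world.planted_sites[world.planted_sites.tf == tf][["contig", "start", "end"]]
bins = bin_genome_and_label(world.contig_lengths, peaks, width=100)

hits = genome_motif_hits(world.genome, world.pssms[0], world.background)
mods = ["H3_occ", "H4_occ", "H3K9ac", "H3K4me3"]
feat = {f"hm_{m}": np.array([aggregate_region_signal(world.tracks["A"], b.contig, (b.start, b.end), m)
                             for b in bins.itertuples()]) for m in mods}
feat["pssm_score"] = bin_motif_scores(bins, hits).to_numpy()
X = pd.DataFrame(feat).fillna(0.0)
labels = bins["label"].astype(float)

print(f"{len(bins)} bins of 100 bp, {int(labels.sum())} overlap a {tf} peak")
for name, cols in [("PSSM only", ["pssm_score"]),
                   ("chromatin only", [c for c in X if c != "pssm_score"]),
                   ("PSSM + chromatin", list(X))]:
    res = cv_train_evaluate(FeatureTable(X[cols], labels), repeats=3, seed=0)
    print(f"  {name:<18} AUC = {res.auc:.3f}   PPV@{res.top_k} = {res.ppv_at:.3f}")
print("combining the planted motif with the local occupancy dip mostly")
print("pays off in precision: a larger share of the top bins are real sites.")
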