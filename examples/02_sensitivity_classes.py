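"""Classify TFs into histone-sensitive and -insensitive classes.

Averages each TF's target-gene modification signals into a target
modification profile, clusters the normalized profiles with k-means
(k=2), and compares the two classes on a planted attribute (PPI degree)
with a rank-sum test plus a Fisher enrichment on an interaction list.
"""

import warnings

warnings.filterwarnings("ignore")

import pandas as pd

from chromotif import (
    SyntheticConfig,
    build_gene_signal_matrix,
    call_targets,
    cluster_sensitivity,
    diff_mod_profiles,
    fisher_enrichment,
    generate_world,
    group_attribute_compare,
    modification_correlation_network,
    target_mod_profiles,
)

world = generate_world(SyntheticConfig(n_genes=1200, n_tfs=40, seed=3, sensitive_fraction=0.4,
                                       motif_plant_prob=0.0, two_conditions=False))
signals = build_gene_signal_matrix(world.annotations, world.tracks["A"], widths=(1000,),
                                   contig_lengths=world.contig_lengths)
labels = call_targets(world.pvalues["A"])

raw, norm = target_mod_profiles(labels, signals)
classes = cluster_sensitivity(norm, seed=0)
truth = pd.Series({t: "sensitive" if world.sensitive[t] else "insensitive" for t in norm.index})
agreement = (classes.labels == truth).mean()

print(f"{len(norm)} TFs profiled over {norm.shape[1]} modifications")
print(f"k-means split: {len(classes.sensitive)} sensitive / {len(classes.insensitive)} insensitive "
      f"(agreement with planted truth {agreement:.2f})")

u, p = group_attribute_compare(classes, world.attributes["ppi_degree"])
print(f"PPI degree, sensitive vs insensitive: Wilcoxon rank-sum P = {p:.2e}")
print("  (sensitive TFs were planted with more interaction partners)")

diff = diff_mod_profiles(labels, signals)
edges = modification_correlation_network(diff.loc[norm.index])
print(f"modification correlation network: {len(edges)} edges with |r| > 0.5")

# enrichment of sensitive TFs among the high-degree half, Fisher one-sided
deg = world.attributes["ppi_degree"].reindex(classes.labels.index)
high = deg >= deg.median()
sens = classes.labels == "sensitive"
table = [[int((high & sens).sum()), int((high & ~sens).sum())],
         [int((~high & sens).sum()), int((~high & ~sens).sum())]]
odds, p = fisher_enrichment(table)
print(f"sensitive TFs among high-degree TFs: odds ratio {odds:.2f}, one-sided Fisher P = {p:.4f}")
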