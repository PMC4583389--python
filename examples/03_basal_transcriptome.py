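"""Screen basal expression, find the regulatory-hub gene cluster, run PCA.

The one-way ANOVA screen keeps probes whose basal (untreated) expression
varies across cell lines at 0.1% FDR.  Clustering the selected genes
recovers a co-regulated hub cluster; PCA over line-averaged profiles
yields components that can be correlated with per-line phenotypes such
as the synergy score.
"""

import pandas as pd

from melsyn.basal import (
    cluster_screened_genes,
    correlate_component_with_phenotype,
    correlate_genes_with_component,
    oneway_anova_screen,
    pca_basal,
)
from melsyn.synergy import panel_summary
from melsyn.synthetic import default_truth, generate_bundle

truth = default_truth()
bundle = generate_bundle(seed=2, truth=truth)

screen = oneway_anova_screen(bundle.expression, q_cutoff=0.001)
print(f"{int(screen['selected'].sum())} of {len(screen)} probes vary across lines at 0.1% FDR")

clusters, _, _ = cluster_screened_genes(bundle.expression, screen, height_cutoff=0.41)
hub_cluster = clusters[truth.hub_gene]
size = int((clusters == hub_cluster).sum())
print(f"hub gene {truth.hub_gene} sits in cluster {hub_cluster} with {size} genes "
      f"(planted hub cluster has {1 + len(truth.hub_targets)})")

pca = pca_basal(bundle.expression)
print("\nvariance explained:", [round(v, 3) for v in pca.variance_ratio[:4]])

synergy = panel_summary(bundle.dose_response)["summary_score"]
for c in (1, 2, 3):
    r = correlate_component_with_phenotype(pca, synergy, component=c)
    print(f"  PC{c} vs synergy score: r = {r:+.3f}")
print("One component tracks the planted synergy axis; another tracks the hub factor.")

pos, neg = correlate_genes_with_component(bundle.expression, pca, component=2, cutoff=0.8)
print(f"\ngenes with |r| > 0.8 against PC2: {len(pos)} positive, {len(neg)} negative")
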