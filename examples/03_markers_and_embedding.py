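"""Factor-specific markers and the VscAI co-embedding.

Ranks genes within each factor by their share of the loading mass,
confirms candidates with the rank-sum filters, then places factors,
cells, and marker genes in one 2-D plane.
"""
import numpy as np

from scai import (find_factor_markers, fit_scai, generate_paired_dataset,
                  normalize_expression, vscai_embedding)
from scai.markers import rank_features

data, truth = generate_paired_dataset("discrete", n_cells=200, n_genes=300,
                                      n_loci=600, n_clusters=3, seed=3)
X1 = normalize_expression(data.X1)
model = fit_scai(X1, data.X2, K=3, seed=3)

fm = find_factor_markers(X1, model.W1, model.H, feature_ids=data.gene_ids)
for k in range(3):
    top = rank_features(model.W1, data.gene_ids, k).head(3)
    n_mark = int(fm.tables[k]["marker"].sum())
    print(f"factor {k}: {n_mark} marker genes; top scores "
          + ", ".join(f"{r.feature}={r.score:.4f}" for r in top.itertuples()))

marker_idx = [data.gene_ids.index(f) for k in range(3)
              for f in fm.markers(k)["feature"][:5]]
layout = vscai_embedding(model, gene_subset=marker_idx)
print(f"Sammon stress of the factor layout: {layout.stress:.2e} "
      "(0 means the inter-factor cosine distances are drawn exactly)")
print("factor coordinates (scaled to [0,1]):")
print(np.round(layout.C, 3))
print(f"cells and {len(marker_idx)} marker genes share this plane; each point "
      "is a loading-weighted barycenter of the factor coordinates")
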