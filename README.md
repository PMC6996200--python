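# scai

Joint analysis of parallel single-cell transcriptomic and epigenomic
profiles measured in the *same* cells (co-assays such as sci-CAR or
scM&T-seq). Single-cell chromatin accessibility and DNA methylation
matrices are extremely sparse and nearly binary, which defeats methods
that treat each cell's epigenomic profile at face value. This package
implements the scAI approach: it *aggregates* each cell's epigenomic
signal over similar cells — with the similarity learned jointly from
both data layers — while factorizing both matrices into a shared
low-dimensional representation.

## The model

Given a normalized expression matrix X₁ (p genes × n cells) and an
epigenomic matrix X₂ (q loci × n cells, binary), the method solves

```
min      α‖X₁ − W₁H‖²_F + ‖X₂(Z∘R) − W₂H‖²_F
W₁,W₂,H,Z ≥ 0
         + λ‖Z − HᵀH‖²_F + γ Σⱼ ‖H·ⱼ‖₁²
```

where W₁ (p×K) and W₂ (q×K) are gene and locus loadings, H (K×n) are
cell loadings, Z (n×n) is a learned cell–cell similarity matrix, and R
is a fixed binary mask drawn Bernoulli(s) that subsamples the similarity
entries so aggregation does not erase within-cluster heterogeneity.
`Z∘R` is column-normalized wherever it multiplies X₂, so the aggregated
profile X₂(Z∘R) of each cell is a convex combination of the profiles of
its (sampled) similar cells. Four multiplicative update rules minimize
the objective; defaults are s = 0.25, α = 1, λ = 10 000, γ = 1.

Downstream of the fit the package provides:

- **Clustering** — shared-nearest-neighbor graph on H + Leiden;
- **Markers** — gene/locus scores per factor, z-score gating, rank-sum
  confirmation; two-part likelihood-ratio test for cluster markers;
  Wilcoxon differential accessibility on aggregated profiles;
- **VscAI co-embedding** — factors by Sammon mapping of cosine
  distances, cells/genes/loci as power-weighted barycenters of the
  factor coordinates;
- **Regulatory links** — perturbation-based correlations between marker
  genes and loci within 500 kb of the TSS, TF assignment by nonnegative
  least squares, validation by fold enrichment against a TF–target
  reference;
- **Synthetic data** — a paired-matrix generator with planted cluster
  or trajectory structure, modality-missing clusters, tunable sparsity,
  noise and imbalance, retaining ground truth and the pre-dropout bulk
  signal;
- **Evaluation** — NMI, loading-recovery AUC, batch-mixing entropy,
  silhouette, false-positive differential-accessibility rate.

## Worked example

```python
from scai import (cluster_cells, fit_scai, generate_paired_dataset, nmi,
                  normalize_expression)

data, truth = generate_paired_dataset("discrete", n_cells=300, n_genes=500,
                                      n_loci=1000, n_clusters=5, seed=1)
X1 = normalize_expression(data.X1)
model = fit_scai(X1, data.X2, K=5, seed=1)
result = cluster_cells(model.H, k=20, resolution=1.0, seed=1)
print(result.n_clusters, nmi(result.labels, truth.labels))
```

Running `python examples/01_fit_and_cluster.py` (this pipeline) prints:

```
generated 500 genes x 300 cells (zero fraction 0.90) and 1000 loci (zero fraction 0.97)
fit converged after 22 iterations; objective 24054.4 -> 18957.9
5 clusters found; NMI vs planted labels = 1.000
```

The objective value falls monotonically across iterations; the five
planted subpopulations are recovered exactly (normalized mutual
information 1.0) even though the accessibility matrix is 97% zeros.
The other scripts in `examples/` walk through aggregation and
differential accessibility, markers and the co-embedding, regulatory
link inference, and rank selection, each printing the numbers it
computes with a line on what they mean.

A thin CLI mirrors the library:

```sh
scai simulate --scenario discrete --cells 300 --seed 1 --out data/
scai fit --data-dir data/ -k 5 --seed 1 --out model/
scai cluster --model-dir model/ --out labels.tsv
scai markers --model-dir model/ --data-dir data/ --out markers.tsv
scai embed --model-dir model/ --out layout.tsv
```

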