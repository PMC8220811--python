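# drgcn

Network-informed metastasis prediction from tumor gene expression.

Bulk RNA-seq expression carries a signal about whether a tumor will
metastasize, but at tens of thousands of genes per sample and a few hundred
samples per cohort, classifiers need prior knowledge to find it. `drgcn`
injects two priors — a **directed gene–gene regulation network** and a binary
**gene–cancer-type association matrix** — by diffusing the associations over
the network with a graph-convolution rule, then weighting each sample's
expression by the diffused gene–cancer weights and classifying the resulting
"expression images" with a small CNN.

## The model

Let `A` be the binary G × G adjacency (`A[i,j] = 1`: gene *i* regulates gene
*j*) and `H_0` the binary G × K gene–cancer association matrix. The diffused
weight matrix is produced by L layers (default 2) of

    H_{l+1} = σ( D̃⁻¹ Ã H_l ),     Ã = max(A, I)

where `D̃` is the diagonal degree matrix of `Ã` — in-degree by default on
directed graphs, with a signed `−1/|E|` fallback that keeps `D̃` full rank on
raw networks with degree-0 nodes — and σ is the identity (all genes weighted
equally; the rule is pure linear diffusion). On an undirected network this is
exactly the random-walk normalization `D⁻¹Ã`. Weight placed on a gene spreads
to its regulators, one reverse-edge hop per layer.

Each sample's feature slice is then `X[s, 0, g, k] = expr[g, s] · Ŵ[g, k]`,
an `(m, 1, G, K)` tensor fed to a CNN: seven Conv2D + LeakyReLU(0.1) blocks,
flatten, batch norm, dense + dropout, dense softmax; categorical
cross-entropy with Adam. Performance is 10-fold cross-validated AUROC and
AUPRC with metastasis as the positive class. Binary metastasis labels come
from TCGA-CDR-style clinical fields through a documented rule cascade
(metastatic status / metastasis event / event site; tumor-free controls;
everything else excluded with a reason) followed by retention of the
longest-followed 70% of non-metastasis cases by progression-free-interval
time. Details and design rationale: [docs/methods.md](docs/methods.md).

The CNN, its backpropagation and the diffusion operator are implemented in
numpy inside this package and are bit-deterministic under a seed; standard
formats and metrics go through pandas, networkx and scikit-learn.

## Worked example

Everything below runs from a seeded synthetic cohort — no downloads. The
generator plants a metastasis-dependent log-scale expression shift on the
network neighborhoods of each cancer's associated genes (see
`drgcn.simulate`).

```python
from drgcn import (SyntheticSpec, gen_network, gen_gene_cancer,
                   gen_expression_cohort, extract_weights, PropagationConfig,
                   weight_expression, CNNConfig, cross_validate)

spec = SyntheticSpec(n_genes=200, n_samples_per_cancer=40, seed=7)
network = gen_network(spec)
gene_cancer = gen_gene_cancer(spec, network)
expr, labels, _ = gen_expression_cohort(spec, network, gene_cancer)

weights = extract_weights(network, gene_cancer, PropagationConfig(n_layers=2))
print(f"network: {network.n_genes} genes, {network.n_edges} edges")
print(f"raw weight support: {int((gene_cancer.values.sum(axis=1) > 0).sum())} genes; "
      f"diffused: {int((weights.values.sum(axis=1) > 0).sum())} genes")

tensor = weight_expression(expr, weights)
print(f"feature tensor: {tensor.values.shape}")

result = cross_validate(tensor, labels, CNNConfig(epochs=20, seed=7), k=5, seed=7)
print(f"fold AUROC: {[round(a, 3) for a in result.fold_auroc]}")
print(f"mean AUROC {result.mean_auroc:.4f}, mean AUPRC {result.mean_auprc:.4f}")
```

Output:

```
network: 200 genes, 979 edges
raw weight support: 30 genes; diffused: 195 genes
feature tensor: (120, 1, 200, 3)
fold AUROC: [0.95, 0.965, 0.963, 0.814, 0.916]
mean AUROC 0.9216, mean AUPRC 0.8848
```

Reading it: the 30 seed genes (10 per cancer type) spread their weight to 195
of 200 genes after two diffusion layers; the 120-sample cohort becomes a
(120, 1, 200, 3) tensor; 5-fold CV recovers the planted signal at mean AUROC
0.92 against a 0.5 chance baseline (AUPRC baseline = prevalence 0.4).

The same pipeline is available from the shell:

```bash
drgcn simulate --seed 7 --out data/
drgcn label    --clinical data/clinical.tsv --fraction 0.7 \
               --out labels.tsv --report excluded.tsv
drgcn diffuse  --network data/network.tsv --gene-cancer data/gene_cancer.tsv \
               --layers 2 --norm in --out weights.tsv
drgcn features --expr data/expr.tsv --weights weights.tsv --out features.npz
drgcn evaluate --features features.npz --labels data/truth/labels.tsv \
               --folds 10 --seed 7 --out results/
```

or end-to-end via `drgcn run-all --config pipeline.yaml`, which writes a
per-stage manifest (seeds plus content hashes) so reruns are verifiably
identical.

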