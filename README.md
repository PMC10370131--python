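# ctxppi — cell-type-contextualized protein representations

Most protein embedding methods are context-free: one vector per
protein, regardless of where the protein acts. `ctxppi` instead learns
one representation per (protein, cell type) pair by message passing
over cell-type-specific protein interaction networks coupled to a
metagraph of cell-cell communication, cell-tissue provenance and the
tissue hierarchy. It is aimed at computational biologists who want
context-resolved protein embeddings for tasks where the cell type
matters — most prominently ranking candidate therapeutic targets per
cell type.

## What it computes

Given a gene×cell count matrix with cell-type/tissue annotations, a
reference interactome, a ligand-receptor significance table and a
tissue ontology, the pipeline:

1. calls each cell type's **activated genes** with a repeated
   subsampled one-sided Wilcoxon rank-sum screen (genes kept when they
   land in the top *K* in ≥ 90% of iterations) and induces the
   **context network** as the largest connected component of the
   reference interactome on those genes;
2. trains a two-layer multi-scale attention network. Per layer, GATv2
   attention inside each context network
   (score `a_r^T LeakyReLU(W_l h_u + W_r h_v)`), learned-importance
   pooling of proteins into their cell-type node
   (`γ_{c,u} = softmax_u q^T tanh h_u`), per-edge-type attention over
   the metagraph combined by shared semantic weights β, and a γ-scaled
   write-back of the cell-type embedding onto each protein;
3. optimizes, with a diagonal bilinear decoder
   `p(u,v) = σ(Σ_k z_u[k] r_i[k] z_v[k])`,

   `L = θ·L_ppi + λ·L_cellid + (1−θ)·(L_cc + L_ct) + (L_tt + L_tc)`

   — self-supervised link prediction at all three scales plus a center
   loss pulling each protein toward its cell type's center
   (λ = 0.1, two learning rates: 0.01 for the model, 0.1 for the
   centers);
4. fine-tunes an MLP head on the frozen embeddings for binary target
   labels, with leakage-free identity-level splits, and ranks cell-type
   contexts by APR@K on held-out proteins.

A synthetic-data module (`ctxppi.synthgen`) generates count atlases
with planted activated genes, stochastic-block-model context networks
with shared proteins, a random tissue tree and planted target labels,
so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from ctxppi import ContextualProteinModel, TargetPrioritizationModel, TrainConfig
from ctxppi.synthgen import SyntheticGraphSpec, gen_multiscale_graph, gen_target_labels

data = gen_multiscale_graph(SyntheticGraphSpec(seed=7))   # 3 contexts x ~200 proteins
config = TrainConfig(d_in=256, epochs=100)                # published defaults otherwise
results = ContextualProteinModel(data.contexts, data.metagraph, config).fit(seed=7)
print(results.summary())

sg = results.similarity_gap()
hr = results.hierarchy_retrieval(ontology_edges=data.ontology_edges, seed=7)
print("held-out link AUROC: %.3f" % results.test_auroc())
print("median cosine, same vs different context: %.3f / %.3f"
      % (sg["median_within"], sg["median_cross"]))
print("tissue-hierarchy Spearman rho: %.3f (shuffled null %.3f)"
      % (hr["rho"], np.mean(hr["null_rhos"])))

labels = gen_target_labels(data, ["C0"], n_pos=20, n_neg=60, seed=7)
ft = TargetPrioritizationModel(results.embeddings, labels.labels).fit(seed=0)
print(ft.summary())
```

prints

```
Contextual protein embedding model
==================================
contexts: 3   protein nodes: 600   identities: 471
metagraph: 3 cell types, 13 tissues (cc=3, ct=3, tt=12)
architecture: d_in=256 d_out=16 heads=8 layers=2 dropout=0.6
objective: theta=0.5 lambda=0.1
epochs: 100   best epoch: 96
best val AUROC: 0.7056   val CH score: 891.8
final total loss: 2.1501

held-out link AUROC: 0.717
median cosine, same vs different context: 0.769 / -0.375
tissue-hierarchy Spearman rho: 0.164 (shuffled null 0.026)

Target prioritization results
=============================
labeled proteins: 80 (20 positive)
test rows: 24

context ranking by APR@5:
  C0           0.5833
  C2           0.5000
  C1           0.3333
```

Reading this: protein embeddings from the same cell type are far more
similar than those from different cell types (0.769 vs −0.375 median
cosine); held-out protein-protein edges are predicted at AUROC 0.717,
close to the generative block-oracle ceiling of this synthetic network
(~0.74, see `docs/methods.md`); tissue embeddings recover the ontology's
distance structure zero-shot (ρ positive, shuffled-hierarchy null near
0); and the context carrying the planted target community (`C0`) ranks
first for target prioritization. Hierarchy ρ varies noticeably across
single seeds — multi-seed averages (as in the reproduction script
below) are more stable.

A thin CLI mirrors the stages:
`ctxppi synth | construct | train | finetune | evaluate` (see
`ctxppi --help`).

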