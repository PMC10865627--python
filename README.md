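# brainlink

Predicting gene–disease associations for brain disorders by fusing
heterogeneous brain networks — functional connectivity of brain parcels and
regions, gene expression across brain sites, and transcription-factor (TF)
regulatory networks — into a single biologically meaningful gene–gene
similarity network, and scoring candidate gene–disease links with a
Chebyshev spectral graph convolutional network (GCN).

The package is aimed at computational biologists studying network-based gene
prioritization: it provides the full pipeline (network I/O, heterograph
assembly, dual-channel fusion, spectral GCN, edge cross-validation) together
with a seeded synthetic multi-network generator with planted community
structure, so every stage is testable without any external data download.

## The model

**Heterographs.** Two square symmetric block adjacencies are assembled from
eleven typed networks:

    A_GPR = [[M_GG, M_GP, M_GR],          A_GTR = [[M_GG, M_GT, M_GR],
             [M_GP', M_PP, M_PR],                  [M_GT', M_TT, M_TR],
             [M_GR', M_PR', M_RR]]                 [M_GR', M_TR', M_RR]]

over genes/parcels/regions and genes/TFs/regions respectively (primes denote
transposes).

**Dual-channel fusion.** Each heterograph's rows pass through an independent
3-layer channel z = w3·α(w2·α(w1·x + b1) + b2) + b3 (α = ReLU) with a linear
decoder reconstructing the input; per-gene latents are converted to
probability rows P = softmax(z) and the joint loss

    L_fusion = MSE_GPR + MSE_GTR + λ · D_KL(P_GPR ‖ P_GTR)

aligns the two views in a common subspace while the reconstruction terms
anchor each latent to its own topology.  Gene-block and context-block
latents are cross-multiplied, reduced in a shared truncated-SVD basis, and
the product Z_G = Z_G-PR · Z_G-TR' — symmetrized, min–max scaled, diagonal
zeroed and top-q sparsified — is the enhanced functional-connectivity (eBFC)
gene network.

**Spectral GCN.** The eBFC gene network, the disease–disease similarity
network and the known gene–disease associations form the combined adjacency
A over N_G + N_D nodes.  Node features (gene expression; binary disease
genotypes) are compressed to a common width by per-class stacked
autoencoders, then filtered per layer by

    g_θ * X = Σ_{k=0..K} θ_k T_k(L̃) X,   L̃ = 2L/λ_max − I,

with T_k the Chebyshev polynomials of the symmetric normalized Laplacian L
(computed by the three-term recursion, no eigendecomposition; a first-order
"simplified" propagation mode is also provided).  Gene and disease
embeddings are concatenated per candidate pair and scored by an MLP with a
sigmoid output; training minimizes binary cross-entropy over known
associations and sampled non-edges.

**Evaluation.** Five-fold cross-validation over positive edges with 1:1
sampled negatives, fresh negatives at test time, a hard-failing leakage
audit, and AUC / AUPR / ACC / PRE / REC / F1.

## Worked example

```sh
brainlink simulate --seed 7 --out suite      # 11 networks + 2 feature matrices
brainlink evaluate --suite suite --out eval --seed 7
cat eval/metrics.tsv
```

prints (numbers are deterministic for the given seed):

```
INFO wrote suite (11 networks) to suite
INFO mean AUC 0.9156 AUPR 0.9122 over 5 folds
fold  auc     aupr    acc     pre     rec     f1      n_pos  n_neg
0     0.8772  0.8354  0.8250  0.8000  0.8667  0.8320  60     60
...
mean  0.9156  0.9122  0.8700  0.8659  0.8833  0.8731  300    300
```

The suite plants 5 gene communities tied to 5 disease groups (300 known
associations over 100 genes × 15 diseases); a mean held-out AUC of 0.92
means the pipeline recovers the planted community↔group structure from the
fused networks.  `brainlink ablate` runs the noGPR / noGTR single-channel
variants for comparison, and `brainlink simulate --shuffled` generates the
degree-balanced negative control on which the same pipeline scores at
chance (AUC ≈ 0.5).

`brainlink train` fits a model on all known associations and `brainlink
predict --disease <id>` writes a ranked gene list for one disease.

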