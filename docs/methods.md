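# Methods

This note documents the modelling choices, numerical conventions and known
limitations of the pipeline.  It is the authoritative record of every point
where the underlying method description left a decision open and of the
design the package adopted.

## Problem setting

Gene–disease association prediction is cast as link prediction on a
bipartite gene/disease graph embedded in a larger heterogeneous system:
genes are connected to brain parcels and regions through expression, to
transcription factors (TFs) through regulation, and to each other through
co-regulation; diseases are connected to each other through similarity.
The premise is that genes whose expression profile across brain space *and*
whose regulatory context are both similar tend to be implicated in the same
diseases, so fusing the two views should rank candidate genes better than
either view alone.

## Fusion stage

### Channels and loss

Each of the two heterographs (A_GPR over genes/parcels/regions, A_GTR over
genes/TFs/regions) is embedded row-wise by an independent 3-layer
feed-forward channel (input → 512 → 128 → latent, ReLU hidden activations);
a gene's input vector is its full adjacency row.  Per-gene probability rows
are obtained by a softmax over latent dimensions — the method text never
defines the "distributions" entering the KL term, and the row softmax is the
simplest construction that makes the divergence well-defined and
differentiable.  The KL divergence is averaged over gene rows and, by
default, taken in the printed asymmetric direction D_KL(P_GPR ‖ P_GTR); a
`symmetric_kl` flag enables the symmetrized variant.

The KL term alone has a degenerate global optimum: both channels emit
constant rows, all distributions become uniform, and the divergence
vanishes while every trace of graph structure is destroyed (we observed
exactly this during development — the fused network's within-community edge
mass fell to chance).  Each channel therefore also reconstructs its own
input rows through a linear decoder, and the training loss is

    MSE_GPR + MSE_GTR + kl_weight · D_KL,    kl_weight default 1.

Reconstruction anchors each latent space to its view's topology;
the KL term aligns the two.  Training is full-batch RMSProp (momentum-free
adaptive step), learning rate 1e-3, 300 epochs, latent width 32; a single
integer seed drives initialization, so runs are bit-reproducible.

### From latents to the fused gene network

The published equations for this step are circular as printed (the gene
representation appears on both sides); the package reads them as: each
channel's gene-block latent is multiplied with its context-block latent
(parcels+regions, or TFs+regions), each product is reduced to
`cross_dim` = 16 columns, and the final gene–gene matrix is the product of
the two reduced maps.

Two numerical points matter here:

* **Shared reduction basis.**  Reducing each product with its own truncated
  SVD yields two maps expressed in unrelated (arbitrarily rotated) bases,
  and their product is then meaningless; at some seeds the resulting
  network was at chance purity.  The pipeline instead computes one left
  singular basis from the column-concatenation of both products and scales
  each basis column by its strength in each view.  The fused matrix is then
  U diag(s_GPR · s_GTR) U', a consensus spectrum: a component contributes
  only as much as *both* views support it.  The standalone `cross_map`
  operation retains the per-product SVD (with a deterministic sign
  convention: the largest-magnitude entry of each singular vector is made
  positive) when no basis is supplied.
* **Column centering.**  The leading singular component of a nonnegative
  product is essentially the column-mean direction and carries no
  discriminative information; left in place it dominates the spectrum and
  flattens the fused network.  The pipeline removes each context column's
  mean across genes before the reduction (`center=True`; off by default at
  the operation level, where exact-reconstruction contracts apply).

Normalization of the fused matrix follows a fixed, recorded sequence:
symmetrize by (M + M')/2, min–max scale to [0, 1], zero the diagonal, keep
the top-q fraction of off-diagonal entries (q default 0.15).  Every step is
appended to `normalization_record`.

### Ablations

`noGPR` / `noGTR` drop one heterograph.  With a single channel the KL
subspace objective is undefined, so the remaining channel trains on
reconstruction alone and the gene network degenerates to Z·Z' of its
reduced map.  The ablation therefore removes both the second view and the
joint alignment — which is what the variant is meant to measure.

## GCN stage

* **Node features.**  Gene expression across brain sites and binary disease
  genotype indicators are compressed to a common width C_SAE (default 32,
  tied to the hidden width) by per-class one-hidden-layer autoencoders with
  ReLU encoders, trained on reconstruction MSE *before* GCN training (not
  jointly; the method text is silent and pre-training keeps one owner per
  objective).
* **Spectral operator.**  L = I − D^{-1/2} A D^{-1/2} with D^{-1/2} zero on
  isolated nodes; λ_max from a 100-step power iteration (tolerance 1e-6) or
  pinned to 2.0 via config.
* **Chebyshev mode (default).**  Per layer, Σ_k θ_k T_k(L̃) X W with scalar
  coefficients θ_k (matching the printed θ ∈ R^K, rather than ChebNet's
  per-order weight matrices), K = 4, two layers, final layer linear.  θ is
  initialized at the first-order low-pass filter (θ0 = 0.5, θ1 = −0.5,
  higher orders 0), which equals the renormalized smoothing operator at
  λ_max = 2.  With a neutral equal-weight initialization the filter acts as
  a near-identity kernel and the model memorizes training edges instead of
  propagating; the low-pass start keeps the smoothing inductive bias while
  leaving all orders learnable.
* **Simplified mode.**  ReLU(D^{-1/2}(I + A)D^{-1/2} X W) with degrees taken
  from A alone — exactly the printed convention, where the identity term is
  added to the adjacency but not to the degrees.  A `renorm_trick` flag
  switches to degrees of I + A.  Degree-zero nodes keep an identity row so
  isolated nodes retain their own signal.
* **Head and loss.**  Pair embedding by concatenation (width 2H), one ReLU
  hidden layer of width H, sigmoid output.  The printed cross-entropy lacks
  a minus sign (it is the log-likelihood); the package minimizes the
  standard negated form, with scores clipped to [1e-12, 1 − 1e-12] in the
  public loss.
* **Training.**  Full-batch Adam at the grid learning rate 4e-4, dropout
  0.3 applied to layer inputs and the MLP hidden layer (inverted scaling,
  off at inference), decoupled per-step weight decay 5e-4 on weight
  matrices (coupled L2 through Adam was measured to have no effect), 600
  epochs.  Dropout masks and initialization come from one seeded stream;
  identical seeds give identical loss histories.

Hyperparameter defaults were selected by five-fold cross-validation on the
synthetic suite — the same tuning protocol the method prescribes — within
the documented grids (L ∈ {2,4,6,8}·1e-4, H ∈ {16,32,64,128},
D ∈ {0.01,0.05,0.1,0.3}, K ∈ {2..5}, E ∈ {200,600,1000,2000}).  The
grid-best values reported for the full-scale real data (H = 64, D = 0.05,
E = 1000) remain available through configuration; at the 100-gene toy scale
they over-memorize, and H = 32 / D = 0.3 / E = 600 generalize better.
`strict=True` (default) rejects values outside the grids.

## Cross-validation protocol

Positive edges are shuffled and split into k = 5 disjoint folds.  Per fold:
training uses the other folds' positives plus an equal number of uniformly
sampled non-edges; the propagation graph's gene–disease block is rebuilt
from training positives only, so held-out edges never influence message
passing; test scoring uses the held-out positives against freshly sampled
non-edges disjoint from everything seen in training.  A set-intersection
audit (fold disjointness, negative/positive disjointness, isolation of any
pre-isolated case-study edges) runs on every fold and raises on violation.
Fusion runs once per cross-validation call — it never sees gene–disease
edges, so there is nothing to mask.

Metrics: AUC by the Mann–Whitney rank convention (ties credited 1/2); AUPR
by step-wise precision–recall integration from the highest score down with
tied scores grouped; ACC/PRE/REC/F1 at threshold 0.5, precision defined as
0 (with a warning) when nothing is predicted positive.  Both ranking
metrics are verified against brute-force oracles in the tests.

## Synthetic suite

The generator emulates the structural assumptions the method exploits, at a
scale (100 genes, 10 TFs, 8 parcels, 12 regions, 15 diseases, 5
communities) where full end-to-end runs take seconds on one CPU.

**Factorized communities.**  Each gene community c is the intersection of
an *expression module* v1(c) = c div 2 and a *regulatory module*
v2(c) = ((c+1) mod 5) div 2; for 5 communities the pair (v1, v2) is unique.
Expression-side networks (parcel/region loadings, gene–parcel, gene–region,
parcel–parcel, region–region, and the gene feature profile over brain
sites) are driven by v1; regulatory-side networks (TF→target wiring, TF–TF
target-overlap similarity, weak gene–gene co-regulation) are driven by v2.
Parcels carry sharp module loadings (0.8) while regions are deliberately
coarse (0.45), reflecting that fine spatial units are more module-specific;
TF–region activity is unstructured.  Consequently each heterograph view
resolves only a coarsening of the communities and fusing both views is
required to separate all five — the property the ablation comparison needs.
Diseases are grouped (dense within-group similarity, sparse across) and
each disease draws 20 gene links, each from its matched community with
probability `association_strength` = 0.9 and uniformly elsewhere otherwise.
Gene features add Gaussian noise (σ = 1.0) to the module profile; disease
features are exact binary indicators of group-linked variant columns.

**Negative control.**  `shuffled=True` replaces the planted associations
with a degree-balanced uniform assignment (each gene receives exactly
links·n_diseases/n_genes = 3 links).  A literal label permutation would
preserve a learnable (mis)mapping, and uneven gene degrees alone push
held-out AUC systematically *below* 0.5 (held-out positives preferentially
involve genes the model specialized toward other diseases).  The balanced
uniform control removes both effects and isolates the question the control
is for: does the pipeline hallucinate structure where none exists?

**What the suite does and does not show.**  Passing the planted-recovery
and null checks shows the pipeline can extract a multi-view community
signal and does not invent one; it does not show anything about real
effect sizes, degree distributions, or the noise structure of measured
brain or genomic data, all of which the generator deliberately idealizes.

## Measured behaviour at the default conditions

All runs are deterministic given the seed.  At seeds {7, 17, 27}, five-fold
cross-validation gives mean held-out AUC 0.902 (full model), 0.896 (noGPR),
0.864 (noGTR), and 0.475 for the shuffle null — values the acceptance tests
recompute.  The noGTR deficit (loss of the regulatory view) is robust; the
noGPR deficit is small and seed-dependent at this scale, because the
remaining GTR view still contains the shared gene–region block and the gene
features still carry the expression modules, so most of the expression
signal survives the ablation.  This mirrors the asymmetry in which view is
more dispensable, but the noGPR direction should not be over-interpreted at
toy scale.

## Known limitations

* All neural components run on an in-package reverse-mode autodiff over
  numpy; it is exact (gradient-checked) but makes no attempt at large-scale
  performance.  Default scales (≤ a few thousand genes) run on one CPU.
* The fused-network construction assumes the two channels' products share
  dominant left structure; the shared-basis reduction makes this robust at
  the tested scales but very weak views could still under-weight real
  components.
* Real printed association scores and full-scale metrics depend on external
  data sources and are out of scope; nothing in the package attempts to
  reproduce them.
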