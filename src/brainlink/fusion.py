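"""Dual-channel topological-semantics extraction and gene-network fusion.

Two independent 3-layer feed-forward channels embed the rows of the two
heterogeneous adjacencies (A_GPR over genes/parcels/regions and A_GTR over
genes/TFs/regions).  Per-gene latent vectors are turned into probability
distributions by a row softmax, and the channels are jointly optimized to
minimize the KL divergence between the two gene distributions, aligning the
two views in a common subspace.  Each channel additionally reconstructs its
own input rows through a linear decoder (mean-squared error): the KL term
alone has a degenerate optimum at constant outputs, so the reconstruction
term is what anchors each latent space to its view's topology while the KL
term aligns the two — the channels perform dimensionality reduction, not
just matching.  The aligned gene-block and context-block
latents are cross-multiplied and reduced by truncated SVD, and the product
of the two reduced maps — symmetrized, min-max scaled, diagonal-zeroed and
optionally top-q sparsified — is the enhanced functional-connectivity gene
network handed to the graph convolutional stage.

The distribution construction (row softmax over latent dimensions, KL
averaged over gene rows) and the choice of truncated SVD for the dimension
reduction are package conventions; both are recorded in docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .hetero import AssemblyError, HeteroAdjacency, block_slice


@dataclass
class ChannelParams:
    """Weights/biases of one 3-layer extraction channel (z = w3 a(w2 a(w1 x + b1) + b2) + b3)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray

    @property
    def layer_dims(self) -> list[int]:
        return [self.w1.shape[0], self.w1.shape[1], self.w2.shape[1], self.w3.shape[1]]

    def validate(self) -> None:
        if self.w1.shape[1] != self.w2.shape[0] or self.w2.shape[1] != self.w3.shape[0]:
            raise ValueError("channel layer shapes do not chain")
        for arr in (self.w1, self.b1, self.w2, self.b2, self.w3, self.b3):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite channel parameter")


@dataclass
class FusionConfig:
    latent_dim: int = 32
    hidden_dims: tuple[int, int] = (512, 128)
    learning_rate: float = 1e-3
    epochs: int = 300
    seed: int = 0
    symmetric_kl: bool = False
    kl_weight: float = 1.0
    cross_dim: int = 16
    top_q: float = 0.15


@dataclass
class FusionModel:
    channel_gpr: ChannelParams | None
    channel_gtr: ChannelParams | None
    latent_dim: int
    rng_seed: int
    loss_history: list[float] = field(default_factory=list)
    kl_history: list[float] = field(default_factory=list)
    decoder_gpr: tuple[np.ndarray, np.ndarray] | None = None
    decoder_gtr: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class EBFCNetwork:
    """Fused gene-gene similarity network with its normalization provenance."""

    gene_ids: list[str]
    matrix: np.ndarray
    normalization_record: list[str]


def init_channel(input_dim: int, config: FusionConfig, rng: np.random.Generator) -> ChannelParams:
    """Glorot-uniform initialization of one channel."""
    dims = [input_dim, *config.hidden_dims, config.latent_dim]

    def glorot(n_in, n_out):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    return ChannelParams(
        w1=glorot(dims[0], dims[1]), b1=np.zeros(dims[1]),
        w2=glorot(dims[1], dims[2]), b2=np.zeros(dims[2]),
        w3=glorot(dims[2], dims[3]), b3=np.zeros(dims[3]),
    )


def channel_forward(x: np.ndarray, params: ChannelParams) -> np.ndarray:
    """Row-wise 3-layer forward pass with ReLU hidden activations."""
    params.validate()
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1] != params.w1.shape[0]:
        raise ValueError(
            f"input width {x.shape[1]} != channel input dim {params.w1.shape[0]}"
        )
    h1 = np.maximum(x @ params.w1 + params.b1, 0.0)
    h2 = np.maximum(h1 @ params.w2 + params.b2, 0.0)
    z = h2 @ params.w3 + params.b3
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite output in channel layer 3")
    return z


def feature_distribution(Z: np.ndarray) -> np.ndarray:
    """Row softmax over latent dimensions: each gene gets a probability
    vector over the latent axes."""
    Z = np.asarray(Z, dtype=np.float64)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite latent input")
    e = np.exp(Z - Z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Mean over rows of sum_i P_i log(P_i / Q_i), in nats."""
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {Q.shape}")
    if np.any(Q <= 0) or np.any(P < 0):
        raise ValueError("distributions must be strictly positive in Q, nonnegative in P")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * (np.log(P) - np.log(Q)), 0.0)
    return float(terms.sum(axis=1).mean())


def _channel_vars(params: ChannelParams) -> dict[str, ad.Var]:
    return {k: ad.parameter(getattr(params, k)) for k in ("w1", "b1", "w2", "b2", "w3", "b3")}


def _forward_vars(x: ad.Var, p: dict[str, ad.Var]) -> ad.Var:
    h1 = ad.relu(ad.add(ad.matmul(x, p["w1"]), p["b1"]))
    h2 = ad.relu(ad.add(ad.matmul(h1, p["w2"]), p["b2"]))
    return ad.add(ad.matmul(h2, p["w3"]), p["b3"])


def _kl_var(Zp: ad.Var, Zq: ad.Var) -> ad.Var:
    P = ad.softmax_rows(Zp)
    Q = ad.softmax_rows(Zq)
    per = ad.mul(P, ad.sub(ad.log(P), ad.log(Q)))
    n = Zp.value.shape[0]
    return ad.mul(ad.ssum(per), ad.constant(1.0 / n))


def _init_decoder(
    config: FusionConfig, out_dim: int, rng: np.random.Generator
) -> tuple[ad.Var, ad.Var]:
    lim = np.sqrt(6.0 / (config.latent_dim + out_dim))
    return (
        ad.parameter(rng.uniform(-lim, lim, size=(config.latent_dim, out_dim))),
        ad.parameter(np.zeros(out_dim)),
    )


def _recon_var(Z: ad.Var, dec: tuple[ad.Var, ad.Var], X: ad.Var) -> ad.Var:
    diff = ad.sub(ad.add(ad.matmul(Z, dec[0]), dec[1]), X)
    return ad.smean(ad.mul(diff, diff))


def fit_fusion(
    A_GPR: HeteroAdjacency, A_GTR: HeteroAdjacency, config: FusionConfig
) -> FusionModel:
    """Jointly train both channels: per-view reconstruction + KL alignment.

    Each channel consumes the rows of its own heterograph (a gene's input is
    its full adjacency row), reconstructs them through a linear decoder, and
    the KL term compares the two per-gene softmax distributions.  Total loss
    is MSE_GPR + MSE_GTR + kl_weight * D_KL.  Full-batch momentum-free
    adaptive-step descent; the run is bit-reproducible given ``config.seed``.
    """
    if A_GPR.vocabs.get("G") != A_GTR.vocabs.get("G"):
        raise AssemblyError("gene vocabularies of the two heterographs disagree")
    n_genes = len(A_GPR.vocabs["G"])
    rng = np.random.default_rng(config.seed)
    ch_p = init_channel(A_GPR.side, config, rng)
    ch_t = init_channel(A_GTR.side, config, rng)

    Xp = ad.constant(A_GPR.matrix.toarray()[:n_genes])
    Xt = ad.constant(A_GTR.matrix.toarray()[:n_genes])
    vars_p = _channel_vars(ch_p)
    vars_t = _channel_vars(ch_t)
    dec_p = _init_decoder(config, A_GPR.side, rng)
    dec_t = _init_decoder(config, A_GTR.side, rng)
    params = (
        list(vars_p.values()) + list(vars_t.values()) + [*dec_p, *dec_t]
    )
    opt = ad.RMSProp(params, lr=config.learning_rate)

    history: list[float] = []
    kl_history: list[float] = []
    for _ in range(config.epochs):
        opt.zero_grad()
        Zp = _forward_vars(Xp, vars_p)
        Zt = _forward_vars(Xt, vars_t)
        kl = _kl_var(Zp, Zt)
        if config.symmetric_kl:
            kl = ad.mul(ad.add(kl, _kl_var(Zt, Zp)), ad.constant(0.5))
        loss = ad.add(
            ad.add(_recon_var(Zp, dec_p, Xp), _recon_var(Zt, dec_t, Xt)),
            ad.mul(kl, ad.constant(config.kl_weight)),
        )
        val = float(loss.value)
        if not np.isfinite(val):
            raise FloatingPointError("fusion loss diverged to non-finite value")
        history.append(val)
        kl_history.append(float(kl.value))
        loss.backward()
        opt.step()

    for dst, src in ((ch_p, vars_p), (ch_t, vars_t)):
        for k, v in src.items():
            setattr(dst, k, v.value)
    return FusionModel(
        channel_gpr=ch_p,
        channel_gtr=ch_t,
        latent_dim=config.latent_dim,
        rng_seed=config.seed,
        loss_history=history,
        kl_history=kl_history,
        decoder_gpr=(dec_p[0].value, dec_p[1].value),
        decoder_gtr=(dec_t[0].value, dec_t[1].value),
    )


def fit_single_channel(
    H: HeteroAdjacency, config: FusionConfig
) -> tuple[ChannelParams, list[float]]:
    """Train one channel on reconstruction alone (the ablation variants:
    without a second view there is no KL term to align against)."""
    n_genes = len(H.vocabs["G"])
    rng = np.random.default_rng(config.seed)
    ch = init_channel(H.side, config, rng)
    X = ad.constant(H.matrix.toarray()[:n_genes])
    vars_c = _channel_vars(ch)
    dec = _init_decoder(config, H.side, rng)
    opt = ad.RMSProp(list(vars_c.values()) + [*dec], lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        opt.zero_grad()
        Z = _forward_vars(X, vars_c)
        loss = _recon_var(Z, dec, X)
        val = float(loss.value)
        if not np.isfinite(val):
            raise FloatingPointError("fusion loss diverged to non-finite value")
        history.append(val)
        loss.backward()
        opt.step()
    for k, v in vars_c.items():
        setattr(ch, k, v.value)
    return ch, history


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry of each column
    is made positive."""
    U = U.copy()
    for k in range(U.shape[1]):
        pivot = np.argmax(np.abs(U[:, k]))
        if U[pivot, k] < 0:
            U[:, k] = -U[:, k]
    return U


def cross_map(
    Z_gene_block: np.ndarray,
    Z_context_block: np.ndarray,
    target_dim: int,
    basis: np.ndarray | None = None,
    center: bool = False,
) -> np.ndarray:
    """Reduce the gene-by-context latent product to ``target_dim`` columns.

    Computes Z_G . Z_context^T followed by a rank-``target_dim`` truncated
    SVD projection (U_d scaled by the singular values), with a deterministic
    sign convention (largest-magnitude entry of each left singular vector
    positive).

    When ``basis`` (an orthonormal genes-by-target_dim matrix) is supplied,
    the product is reduced in that shared basis instead of its own left
    singular vectors, with column k scaled by the component strength
    ||M^T u_k||.  The two reduced maps of the fusion pipeline are built in
    one shared basis so that their product weights every component by its
    strength in *both* views; independent per-product bases are arbitrary
    rotations of one another and make the product meaningless.

    ``center=True`` removes each context column's mean across genes before
    the reduction, discarding the non-discriminative rank-1 mean component
    that otherwise dominates the spectrum of a nonnegative product.
    """
    Zg = np.asarray(Z_gene_block, dtype=np.float64)
    Zc = np.asarray(Z_context_block, dtype=np.float64)
    if Zg.shape[1] != Zc.shape[1]:
        raise ValueError("latent dimensions of gene and context blocks differ")
    M = Zg @ Zc.T
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    if target_dim < 1 or target_dim > min(M.shape):
        raise ValueError(
            f"target_dim {target_dim} outside [1, {min(M.shape)}]"
        )
    if basis is not None:
        if basis.shape != (M.shape[0], target_dim):
            raise ValueError("basis shape must be (n_genes, target_dim)")
        strengths = np.linalg.norm(M.T @ basis, axis=0)
        return basis * strengths
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    U = _fix_signs(U[:, :target_dim])
    return U * S[:target_dim]


def shared_basis(
    Z_gene_p: np.ndarray,
    Z_ctx_p: np.ndarray,
    Z_gene_t: np.ndarray,
    Z_ctx_t: np.ndarray,
    target_dim: int,
    center: bool = False,
) -> np.ndarray:
    """Joint left singular basis of the column-concatenated view products."""
    Mp = np.asarray(Z_gene_p) @ np.asarray(Z_ctx_p).T
    Mt = np.asarray(Z_gene_t) @ np.asarray(Z_ctx_t).T
    M = np.concatenate([Mp, Mt], axis=1)
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    if target_dim < 1 or target_dim > min(M.shape):
        raise ValueError(f"target_dim {target_dim} outside [1, {min(M.shape)}]")
    U, _, _ = np.linalg.svd(M, full_matrices=False)
    return _fix_signs(U[:, :target_dim])


def ebfc_network(
    Z_G_PR: np.ndarray,
    Z_G_TR: np.ndarray,
    gene_ids: list[str],
    top_q: float = 0.05,
) -> EBFCNetwork:
    """Fuse the two reduced gene maps into the normalized gene network.

    Raw matrix Z_G-PR . Z_G-TR^T, then: symmetrize by (M + M^T)/2, min-max
    scale to [0,1], zero the diagonal, and keep the top-q fraction of
    off-diagonal entries.  Every step is appended to normalization_record.
    """
    Zp = np.asarray(Z_G_PR, dtype=np.float64)
    Zt = np.asarray(Z_G_TR, dtype=np.float64)
    if Zp.shape != Zt.shape or Zp.shape[0] != len(gene_ids):
        raise ValueError("reduced maps must share gene rows and latent columns")
    if not 0.0 < top_q <= 1.0:
        raise ValueError("top_q must be in (0, 1]")
    record = []
    M = Zp @ Zt.T
    record.append("raw = Z_G-PR . Z_G-TR^T")
    M = 0.5 * (M + M.T)
    record.append("symmetrized: (M + M^T)/2")
    lo, hi = M.min(), M.max()
    M = (M - lo) / (hi - lo) if hi > lo else np.zeros_like(M)
    record.append(f"min-max scaled to [0,1] (min={lo:.6g}, max={hi:.6g})")
    np.fill_diagonal(M, 0.0)
    record.append("diagonal zeroed")
    if top_q < 1.0:
        off = M[~np.eye(M.shape[0], dtype=bool)]
        thr = float(np.quantile(off, 1.0 - top_q))
        M = np.where(M >= thr, M, 0.0)
        record.append(f"top-q sparsified (q={top_q}, threshold={thr:.6g})")
    return EBFCNetwork(gene_ids=list(gene_ids), matrix=M, normalization_record=record)


def fused_gene_network(
    A_GPR: HeteroAdjacency | None,
    A_GTR: HeteroAdjacency | None,
    config: FusionConfig,
    variant: str = "full",
) -> tuple[EBFCNetwork, FusionModel | None]:
    """End-to-end fusion stage, with the two single-channel ablations.

    variant="full": joint reconstruction + KL training, then
    Z_G-PR . Z_G-TR^T.
    variant="noGPR"/"noGTR": the remaining channel trains on reconstruction
    alone (no second view to align against) and the gene network degenerates
    to Z . Z^T of its reduced map.
    """
    if variant == "full":
        if A_GPR is None or A_GTR is None:
            raise ValueError("full variant requires both heterographs")
        model = fit_fusion(A_GPR, A_GTR, config)
        Zp_all = channel_forward(A_GPR.matrix.toarray(), model.channel_gpr)
        Zt_all = channel_forward(A_GTR.matrix.toarray(), model.channel_gtr)
        n_g = len(A_GPR.vocabs["G"])
        basis = shared_basis(
            Zp_all[:n_g], Zp_all[n_g:], Zt_all[:n_g], Zt_all[n_g:],
            config.cross_dim, center=True,
        )
        Z_G_PR = cross_map(Zp_all[:n_g], Zp_all[n_g:], config.cross_dim,
                           basis=basis, center=True)
        Z_G_TR = cross_map(Zt_all[:n_g], Zt_all[n_g:], config.cross_dim,
                           basis=basis, center=True)
        net = ebfc_network(Z_G_PR, Z_G_TR, A_GPR.vocabs["G"], top_q=config.top_q)
        return net, model
    if variant in ("noGPR", "noGTR"):
        H = A_GTR if variant == "noGPR" else A_GPR
        if H is None:
            raise ValueError(f"variant {variant} requires the remaining heterograph")
        ch, history = fit_single_channel(H, config)
        Z_all = channel_forward(H.matrix.toarray(), ch)
        n_g = len(H.vocabs["G"])
        Z = cross_map(Z_all[:n_g], Z_all[n_g:], config.cross_dim, center=True)
        net = ebfc_network(Z, Z, H.vocabs["G"], top_q=config.top_q)
        model = FusionModel(
            channel_gpr=None if variant == "noGPR" else ch,
            channel_gtr=ch if variant == "noGPR" else None,
            latent_dim=config.latent_dim,
            rng_seed=config.seed,
            loss_history=history,
        )
        return net, model
    raise ValueError(f"unknown fusion variant {variant!r}")


def save_fusion_model(model: FusionModel, prefix) -> None:
    """Checkpoint to a single .npz plus JSON manifest."""
    prefix = Path(prefix)
    arrays = {}
    for name, ch in (("gpr", model.channel_gpr), ("gtr", model.channel_gtr)):
        if ch is None:
            continue
        for k in ("w1", "b1", "w2", "b2", "w3", "b3"):
            arrays[f"{name}_{k}"] = getattr(ch, k)
    np.savez(str(prefix) + ".npz", **arrays)
    manifest = {
        "latent_dim": model.latent_dim,
        "rng_seed": model.rng_seed,
        "n_epochs": len(model.loss_history),
        "final_loss": model.loss_history[-1] if model.loss_history else None,
        "channels": [n for n, c in (("gpr", model.channel_gpr), ("gtr", model.channel_gtr)) if c],
    }
    (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(manifest, indent=1))
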