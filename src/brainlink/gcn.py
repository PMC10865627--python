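"""Spectral graph convolution over the combined gene/disease graph.

Node features (gene expression across brain sites; disease pathogenic-variant
genotypes) are first compressed to a common width by per-class stacked
autoencoders.  A Chebyshev-polynomial graph filter

    g_theta * X = sum_{k=0..K} theta_k T_k(L~) X,   L~ = 2 L / lambda_max - I

is applied per layer via the three-term recursion (no eigendecomposition);
the ``simplified`` mode instead uses the first-order propagation
ReLU(D^{-1/2} (I + A) D^{-1/2} X W) where, as in the printed convention this
package follows, the degrees come from A alone (a ``renorm_trick`` flag
switches to degrees of I + A).  Gene and disease embeddings are concatenated
per candidate pair and scored by a small MLP with a sigmoid output; training
minimizes binary cross-entropy over positive and sampled negative edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .hetero import HeteroAdjacency

HYPER_GRIDS = {
    "learning_rate": (0.0002, 0.0004, 0.0006, 0.0008),
    "hidden": (16, 32, 64, 128),
    "dropout": (0.01, 0.05, 0.1, 0.3),
    "K": (2, 3, 4, 5),
    "epochs": (200, 600, 1000, 2000),
}


@dataclass
class GCNHyper:
    learning_rate: float = 0.0004
    hidden: int = 32
    dropout: float = 0.3
    K: int = 4
    epochs: int = 600
    n_layers: int = 2
    # decoupled per-step multiplicative decay of weight matrices (not
    # biases/theta); decoupling is required for decay to bite under Adam
    weight_decay: float = 5e-4
    mode: str = "chebyshev"  # or "simplified"
    renorm_trick: bool = False
    lambda_max: float | None = None  # None -> power iteration
    c_sae: int = 32
    sae_epochs: int = 200
    sae_lr: float = 1e-3

    def check_grid(self, strict: bool = True) -> None:
        if not strict:
            return
        for name in ("learning_rate", "hidden", "dropout", "K", "epochs"):
            if getattr(self, name) not in HYPER_GRIDS[name]:
                raise ValueError(
                    f"hyperparameter {name}={getattr(self, name)} outside the "
                    f"documented grid {HYPER_GRIDS[name]}"
                )


# ---------------------------------------------------------------------------
# Stacked autoencoders


@dataclass
class SAEParams:
    """One-hidden-layer encoder/decoder per node class; ReLU encoder output."""

    c_sae: int
    encoders: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    decoders: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def train_sae(
    features_by_class: dict[str, np.ndarray],
    c_sae: int,
    epochs: int = 200,
    lr: float = 1e-3,
    seed: int = 0,
) -> tuple[SAEParams, dict[str, list[float]]]:
    """Train one autoencoder per node class on reconstruction MSE."""
    rng = np.random.default_rng(seed)
    params = SAEParams(c_sae=c_sae)
    histories: dict[str, list[float]] = {}
    for cls in sorted(features_by_class):
        X = np.asarray(features_by_class[cls], dtype=np.float64)
        d = X.shape[1]
        lim_e = np.sqrt(6.0 / (d + c_sae))
        We = ad.parameter(rng.uniform(-lim_e, lim_e, size=(d, c_sae)))
        be = ad.parameter(np.zeros(c_sae))
        Wd = ad.parameter(rng.uniform(-lim_e, lim_e, size=(c_sae, d)))
        bd = ad.parameter(np.zeros(d))
        Xv = ad.constant(X)
        opt = ad.Adam([We, be, Wd, bd], lr=lr)
        hist: list[float] = []
        for _ in range(epochs):
            opt.zero_grad()
            H = ad.relu(ad.add(ad.matmul(Xv, We), be))
            R = ad.add(ad.matmul(H, Wd), bd)
            diff = ad.sub(R, Xv)
            loss = ad.smean(ad.mul(diff, diff))
            hist.append(float(loss.value))
            loss.backward()
            opt.step()
        params.encoders[cls] = (We.value, be.value)
        params.decoders[cls] = (Wd.value, bd.value)
        histories[cls] = hist
    return params, histories


def sae_encode(features: np.ndarray, params: SAEParams, node_class: str) -> np.ndarray:
    """Encode one class's raw features to the shared C_SAE width."""
    X = np.asarray(features, dtype=np.float64)
    We, be = params.encoders[node_class]
    if X.shape[1] != We.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} != encoder input dim {We.shape[0]}"
        )
    return np.maximum(X @ We + be, 0.0)


# ---------------------------------------------------------------------------
# Spectral operator


@dataclass
class SpectralOperator:
    adjacency: sp.csr_matrix
    degrees: np.ndarray
    laplacian: sp.csr_matrix
    lambda_max: float


def normalized_laplacian(
    A, lambda_max: float | None = None, power_iters: int = 100, tol: float = 1e-6
) -> SpectralOperator:
    """L = I - D^{-1/2} A D^{-1/2}; isolated nodes get an identity row.

    lambda_max defaults to a 100-step power iteration on L (or can be pinned,
    typically to 2.0).
    """
    A = A.tocsr() if sp.issparse(A) else sp.csr_matrix(np.asarray(A, dtype=np.float64))
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (abs(A - A.T)).max() > 1e-12:
        raise ValueError("adjacency must be symmetric")
    deg = np.asarray(A.sum(axis=1)).ravel()
    dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    Dinv = sp.diags(dinv)
    L = sp.identity(A.shape[0], format="csr") - Dinv @ A @ Dinv
    L = sp.csr_matrix(L)
    if lambda_max is None:
        rng = np.random.default_rng(0)
        v = rng.standard_normal(A.shape[0])
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(power_iters):
            w = L @ v
            nw = np.linalg.norm(w)
            if nw == 0.0:
                lam = 0.0
                break
            v_new = w / nw
            lam_new = float(v_new @ (L @ v_new))
            if abs(lam_new - lam) < tol:
                lam = lam_new
                break
            v, lam = v_new, lam_new
        lambda_max = max(lam, 1e-12)
    return SpectralOperator(adjacency=A, degrees=deg, laplacian=L,
                            lambda_max=float(lambda_max))


def chebyshev_filter(op: SpectralOperator, X: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """sum_k theta_k T_k(L~) X via the three-term recursion."""
    if op.lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    theta = np.asarray(theta, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    Lt = (2.0 / op.lambda_max) * op.laplacian - sp.identity(op.laplacian.shape[0])
    T_prev, T_cur = X, None
    out = theta[0] * X
    for k in range(1, len(theta)):
        if k == 1:
            T_cur = Lt @ X
        else:
            T_prev, T_cur = T_cur, 2.0 * (Lt @ T_cur) - T_prev
        out = out + theta[k] * T_cur
    return np.asarray(out)


# ---------------------------------------------------------------------------
# GCN model


@dataclass
class ConvLayer:
    theta: np.ndarray  # (K+1,) Chebyshev coefficients (unused in simplified mode)
    W: np.ndarray
    b: np.ndarray


@dataclass
class GCNModel:
    mode: str
    hyper: GCNHyper
    conv_layers: list[ConvLayer]
    mlp_W1: np.ndarray
    mlp_b1: np.ndarray
    mlp_Wout: np.ndarray
    mlp_bout: np.ndarray
    seed: int = 0


def init_gcn(n_features: int, hyper: GCNHyper, seed: int = 0) -> GCNModel:
    rng = np.random.default_rng(seed)

    def glorot(n_in, n_out):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out))

    # theta starts at the first-order low-pass filter (I - L~)/2, i.e. the
    # renormalized smoothing operator; higher orders are learned from zero.
    theta0 = np.zeros(hyper.K + 1)
    theta0[0], theta0[1] = 0.5, -0.5
    layers = []
    d_in = n_features
    for _ in range(hyper.n_layers):
        layers.append(
            ConvLayer(
                theta=theta0.copy(),
                W=glorot(d_in, hyper.hidden),
                b=np.zeros(hyper.hidden),
            )
        )
        d_in = hyper.hidden
    return GCNModel(
        mode=hyper.mode,
        hyper=hyper,
        conv_layers=layers,
        mlp_W1=glorot(2 * hyper.hidden, hyper.hidden),
        mlp_b1=np.zeros(hyper.hidden),
        mlp_Wout=glorot(hyper.hidden, 1),
        mlp_bout=np.zeros(1),
        seed=seed,
    )


def _propagation_mats(A, hyper: GCNHyper) -> list[np.ndarray]:
    """Dense operator(s) applied per layer: T_k(L~) stack (chebyshev) or the
    single first-order propagation matrix (simplified)."""
    A = A.tocsr() if sp.issparse(A) else sp.csr_matrix(np.asarray(A, dtype=np.float64))
    n = A.shape[0]
    if hyper.mode == "chebyshev":
        op = normalized_laplacian(A, lambda_max=hyper.lambda_max)
        Lt = ((2.0 / op.lambda_max) * op.laplacian - sp.identity(n)).toarray()
        mats = [np.eye(n), Lt.copy()]
        for _ in range(2, hyper.K + 1):
            mats.append(2.0 * Lt @ mats[-1] - mats[-2])
        return mats[: hyper.K + 1]
    if hyper.mode == "simplified":
        IA = sp.identity(n, format="csr") + A
        base = IA if hyper.renorm_trick else A
        deg = np.asarray(base.sum(axis=1)).ravel()
        # degree-zero nodes keep their self signal (identity row)
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 1.0)
        P = sp.diags(dinv) @ IA @ sp.diags(dinv)
        return [np.asarray(P.todense())]
    raise ValueError(f"unknown GCN mode {hyper.mode!r}")


def _conv_stack_vars(
    mats_c: list[ad.Var],
    Xv: ad.Var,
    layer_vars: list[dict[str, ad.Var]],
    mode: str,
    dropout_masks: list[np.ndarray] | None,
) -> ad.Var:
    H = Xv
    n_layers = len(layer_vars)
    for li, lv in enumerate(layer_vars):
        if dropout_masks is not None:
            H = ad.mul(H, ad.constant(dropout_masks[li]))
        if mode == "chebyshev":
            S = None
            for k, Tk in enumerate(mats_c):
                term = ad.matmul(Tk, H)
                term = ad.scale(term, lv["theta"][k])
                S = term if S is None else ad.add(S, term)
        else:
            S = ad.matmul(mats_c[0], H)
        Z = ad.add(ad.matmul(S, lv["W"]), lv["b"])
        H = ad.relu(Z) if li < n_layers - 1 else Z
    return H


def gcn_forward(
    A, X: np.ndarray, model: GCNModel, n_genes: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Inference forward pass (dropout off); returns (H_G, H_D)."""
    if isinstance(A, HeteroAdjacency):
        if A.block_order != ["G", "D"]:
            raise ValueError("expected a [G,D] heterograph")
        n_genes = A.class_sizes[0]
        A = A.matrix
    elif n_genes is None or n_genes < 0:
        raise ValueError("n_genes required when A is a raw matrix")
    X = np.asarray(X, dtype=np.float64)
    mats = _propagation_mats(A, model.hyper)
    H = X
    n_layers = len(model.conv_layers)
    for li, layer in enumerate(model.conv_layers):
        if model.mode == "chebyshev":
            S = sum(layer.theta[k] * (mats[k] @ H) for k in range(len(mats)))
        else:
            S = mats[0] @ H
        Z = S @ layer.W + layer.b
        H = np.maximum(Z, 0.0) if li < n_layers - 1 else Z
        if not np.all(np.isfinite(H)):
            raise FloatingPointError(f"non-finite activations in conv layer {li}")
    return H[:n_genes], H[n_genes:]


def pair_embed(
    H_G: np.ndarray, H_D: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Concatenate gene and disease embeddings per candidate pair."""
    H_G = np.asarray(H_G, dtype=np.float64)
    H_D = np.asarray(H_D, dtype=np.float64)
    if len(pairs) == 0:
        return np.zeros((0, H_G.shape[1] + H_D.shape[1]))
    gi = np.array([p[0] for p in pairs])
    di = np.array([p[1] for p in pairs])
    if gi.min() < 0 or gi.max() >= H_G.shape[0] or di.min() < 0 or di.max() >= H_D.shape[0]:
        raise IndexError("pair index out of range")
    return np.concatenate([H_G[gi], H_D[di]], axis=1)


def score_pairs(H_GD: np.ndarray, model: GCNModel) -> np.ndarray:
    """Sigmoid association scores from the MLP head; strictly in (0,1)."""
    H_GD = np.asarray(H_GD, dtype=np.float64)
    if H_GD.shape[1] != model.mlp_W1.shape[0]:
        raise ValueError(
            f"pair embedding width {H_GD.shape[1]} != MLP input {model.mlp_W1.shape[0]}"
        )
    h = np.maximum(H_GD @ model.mlp_W1 + model.mlp_b1, 0.0)
    z = (h @ model.mlp_Wout + model.mlp_bout).ravel()
    return 1.0 / (1.0 + np.exp(-z))


def bce_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Summed binary cross-entropy with scores clipped to [eps, 1-eps]."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    s = np.clip(scores, eps, 1.0 - eps)
    return float(-np.sum(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)))


def predict_scores(
    model: GCNModel, A, X: np.ndarray, pairs: list[tuple[int, int]], n_genes: int | None = None
) -> np.ndarray:
    """Score (gene_index, disease_index) pairs with a trained model."""
    H_G, H_D = gcn_forward(A, X, model, n_genes)
    return score_pairs(pair_embed(H_G, H_D, pairs), model)


def train(
    graph: HeteroAdjacency,
    X: np.ndarray,
    train_pos_edges: list[tuple[int, int]],
    train_neg_edges: list[tuple[int, int]],
    hyper: GCNHyper,
    seed: int = 0,
    strict: bool = True,
) -> tuple[GCNModel, list[float]]:
    """Full-batch end-to-end training under binary cross-entropy.

    Edges are (gene_index, disease_index) pairs.  Dropout masks and parameter
    initialization are drawn from a single seeded stream, so runs are
    bit-reproducible.  Returns the trained model and the per-epoch loss
    history (the summed cross-entropy of Eq.-style sigmoid scores).
    """
    hyper.check_grid(strict=strict)
    if len(train_pos_edges) == 0:
        raise ValueError("empty positive edge set")
    if set(train_pos_edges) & set(train_neg_edges):
        raise ValueError("positive and negative edge sets overlap")
    n_genes = graph.class_sizes[graph.block_order.index("G")]
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != graph.side:
        raise ValueError("feature rows must equal graph size")

    rng = np.random.default_rng(seed)
    model = init_gcn(X.shape[1], hyper, seed=seed)
    mats = _propagation_mats(graph.matrix, hyper)
    mats_c = [ad.constant(m) for m in mats]
    Xv = ad.constant(X)

    layer_vars = []
    params: list[ad.Var] = []
    decayed: list[ad.Var] = []
    for layer in model.conv_layers:
        lv = {
            "theta": [ad.parameter(t) for t in layer.theta],
            "W": ad.parameter(layer.W),
            "b": ad.parameter(layer.b),
        }
        if hyper.mode == "chebyshev":
            params.extend(lv["theta"])
        params.extend([lv["W"], lv["b"]])
        decayed.append(lv["W"])
        layer_vars.append(lv)
    W1 = ad.parameter(model.mlp_W1)
    b1 = ad.parameter(model.mlp_b1)
    Wout = ad.parameter(model.mlp_Wout)
    bout = ad.parameter(model.mlp_bout)
    params.extend([W1, b1, Wout, bout])
    decayed.extend([W1, Wout])
    opt = ad.Adam(params, lr=hyper.learning_rate)

    pairs = list(train_pos_edges) + list(train_neg_edges)
    gi = np.array([p[0] for p in pairs])
    di = np.array([n_genes + p[1] for p in pairs])
    labels = np.concatenate(
        [np.ones(len(train_pos_edges)), np.zeros(len(train_neg_edges))]
    ).reshape(-1, 1)

    p_drop = hyper.dropout
    history: list[float] = []
    for epoch in range(hyper.epochs):
        opt.zero_grad()
        masks = [
            (rng.random(size=(X.shape[0], mdim)) >= p_drop) / (1.0 - p_drop)
            for mdim in [X.shape[1]] + [hyper.hidden] * (hyper.n_layers - 1)
        ]
        mlp_mask = (rng.random(size=(len(pairs), hyper.hidden)) >= p_drop) / (1.0 - p_drop)
        H = _conv_stack_vars(mats_c, Xv, layer_vars, hyper.mode, masks)
        Hgd = ad.concat_cols(ad.take_rows(H, gi), ad.take_rows(H, di))
        hidden = ad.relu(ad.add(ad.matmul(Hgd, W1), b1))
        hidden = ad.mul(hidden, ad.constant(mlp_mask))
        logits = ad.add(ad.matmul(hidden, Wout), bout)
        loss = ad.sigmoid_bce_with_logits(logits, labels)
        val = float(loss.value)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append(val)
        loss.backward()
        opt.step()
        if hyper.weight_decay > 0:
            for p in decayed:
                p.value *= 1.0 - hyper.weight_decay

    for layer, lv in zip(model.conv_layers, layer_vars):
        layer.theta = np.array([t.value for t in lv["theta"]])
        layer.W = lv["W"].value
        layer.b = lv["b"].value
    model.mlp_W1, model.mlp_b1 = W1.value, b1.value
    model.mlp_Wout, model.mlp_bout = Wout.value, bout.value
    return model, history


def model_arrays(model: GCNModel) -> dict[str, np.ndarray]:
    """Flatten model parameters for .npz checkpointing."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.conv_layers):
        arrays[f"conv{i}_theta"] = layer.theta
        arrays[f"conv{i}_W"] = layer.W
        arrays[f"conv{i}_b"] = layer.b
    arrays["mlp_W1"] = model.mlp_W1
    arrays["mlp_b1"] = model.mlp_b1
    arrays["mlp_Wout"] = model.mlp_Wout
    arrays["mlp_bout"] = model.mlp_bout
    return arrays


def model_from_arrays(arrays, hyper: GCNHyper) -> GCNModel:
    """Inverse of :func:`model_arrays`."""
    layers = []
    i = 0
    while f"conv{i}_W" in arrays:
        layers.append(ConvLayer(
            theta=np.asarray(arrays[f"conv{i}_theta"]),
            W=np.asarray(arrays[f"conv{i}_W"]),
            b=np.asarray(arrays[f"conv{i}_b"]),
        ))
        i += 1
    return GCNModel(
        mode=hyper.mode,
        hyper=hyper,
        conv_layers=layers,
        mlp_W1=np.asarray(arrays["mlp_W1"]),
        mlp_b1=np.asarray(arrays["mlp_b1"]),
        mlp_Wout=np.asarray(arrays["mlp_Wout"]),
        mlp_bout=np.asarray(arrays["mlp_bout"]),
    )
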