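"""Edge cross-validation, negative sampling and ranking metrics.

Positive gene-disease edges are shuffled and split into k disjoint folds;
each fold is held out in turn, the model is trained on the remaining
positives plus an equal number of sampled non-edges, and held-out positives
are scored against freshly sampled non-edges.  AUC uses the Mann-Whitney
convention (ties credited 1/2); AUPR is step-wise precision-recall
integration from the highest score down.  A leakage audit (fold
disjointness, negative/positive disjointness, case-study isolation) runs on
every cross-validation call and fails hard.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from . import gcn
from .fusion import FusionConfig, fused_gene_network
from .hetero import build_ebfc_dd_graph, hetero_from_networks
from .netio import Network
from .synthetic import Suite

Edge = tuple[int, int]


class LeakageError(RuntimeError):
    """Raised when the train/test audit detects overlapping edge sets."""


@dataclass
class MetricsRecord:
    auc: float
    aupr: float
    acc: float
    pre: float
    rec: float
    f1: float
    n_pos: int
    n_neg: int


@dataclass
class PipelineConfig:
    """Everything needed to run fusion + GCN + cross-validation."""

    fusion: FusionConfig = dataclasses.field(default_factory=FusionConfig)
    gcn: gcn.GCNHyper = dataclasses.field(default_factory=gcn.GCNHyper)
    variant: str = "full"  # or "noGPR" / "noGTR"
    neg_ratio: float = 1.0
    strict: bool = True


def kfold_split(pos_edges: list[Edge], k: int, seed: int) -> list[list[Edge]]:
    """Seeded shuffle then near-even partition into k disjoint folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(pos_edges):
        raise ValueError(f"k={k} exceeds number of positive edges {len(pos_edges)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos_edges))
    shuffled = [pos_edges[i] for i in order]
    return [
        [shuffled[i] for i in chunk]
        for chunk in np.array_split(np.arange(len(shuffled)), k)
    ]


def sample_negatives(
    adjacency_gd: np.ndarray,
    n: int,
    seed: int,
    forbidden: set[Edge] | frozenset[Edge] = frozenset(),
) -> list[Edge]:
    """n distinct (gene, disease) non-edges, none in ``forbidden``."""
    A = np.asarray(
        adjacency_gd.todense() if hasattr(adjacency_gd, "todense") else adjacency_gd
    )
    zi, zj = np.nonzero(A == 0)
    candidates = [
        (int(i), int(j)) for i, j in zip(zi, zj) if (int(i), int(j)) not in forbidden
    ]
    if n > len(candidates):
        raise ValueError(
            f"cannot sample {n} negatives from {len(candidates)} available non-edges"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in idx]


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsRecord:
    """AUC/AUPR plus thresholded ACC, PRE, REC, F1."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC/AUPR undefined with a single class")

    # Mann-Whitney AUC: ties credited 1/2 via average ranks
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # step-wise PR integration from the highest score down, grouping ties
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    tp = fp = 0
    prev_rec = 0.0
    aupr = 0.0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        rec_i = tp / n_pos
        prec_i = tp / (tp + fp)
        aupr += (rec_i - prev_rec) * prec_i
        prev_rec = rec_i
        i = j

    pred = scores >= threshold
    tp_h = int(np.sum(pred & (labels == 1)))
    fp_h = int(np.sum(pred & (labels == 0)))
    fn_h = n_pos - tp_h
    acc = float(np.mean(pred == (labels == 1)))
    if tp_h + fp_h == 0:
        warnings.warn("no predicted positives at threshold; precision set to 0")
        pre = 0.0
    else:
        pre = tp_h / (tp_h + fp_h)
    rec = tp_h / (tp_h + fn_h) if (tp_h + fn_h) else 0.0
    f1 = 2 * pre * rec / (pre + rec) if (pre + rec) > 0 else 0.0
    return MetricsRecord(
        auc=float(auc), aupr=float(aupr), acc=acc, pre=float(pre),
        rec=float(rec), f1=float(f1), n_pos=n_pos, n_neg=n_neg,
    )


def per_entity_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    entity_ids: list,
    threshold: float = 0.5,
) -> tuple[dict, list]:
    """Per-disease metric breakdown; single-class entities are reported as
    skipped rather than silently dropped."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    ids = np.asarray(entity_ids)
    records: dict = {}
    skipped: list = []
    for eid in sorted(set(entity_ids), key=str):
        mask = ids == eid
        sub_labels = labels[mask]
        if sub_labels.min() == sub_labels.max():
            skipped.append(eid)
            continue
        records[eid] = compute_metrics(scores[mask], sub_labels, threshold)
    return records, skipped


def isolate_case_study(
    pos_edges: list[Edge],
    target_diseases: list[int],
    n_per_disease: int,
    seed: int,
) -> tuple[list[Edge], list[Edge]]:
    """Move n_per_disease seeded-random positives per target disease into an
    isolated set excluded from all fusion and training."""
    rng = np.random.default_rng(seed)
    isolated: list[Edge] = []
    iso_set: set[Edge] = set()
    for d in target_diseases:
        owned = [e for e in pos_edges if e[1] == d]
        if len(owned) < n_per_disease:
            raise ValueError(
                f"disease {d} has only {len(owned)} positives, "
                f"need {n_per_disease}"
            )
        idx = rng.choice(len(owned), size=n_per_disease, replace=False)
        chosen = [owned[i] for i in idx]
        isolated.extend(chosen)
        iso_set.update(chosen)
    remaining = [e for e in pos_edges if e not in iso_set]
    return isolated, remaining


def _audit(
    folds: list[list[Edge]],
    train_pos: list[Edge],
    test_pos: list[Edge],
    train_neg: list[Edge],
    test_neg: list[Edge],
    isolated: set[Edge],
    all_pos: set[Edge],
) -> None:
    sets = {
        "train_pos": set(train_pos),
        "test_pos": set(test_pos),
        "train_neg": set(train_neg),
        "test_neg": set(test_neg),
    }
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if sets[a] & sets[b]:
                raise LeakageError(f"{a} and {b} overlap")
    for name in ("train_neg", "test_neg"):
        if sets[name] & all_pos:
            raise LeakageError(f"{name} intersects known positives")
        if sets[name] & isolated:
            raise LeakageError(f"{name} intersects isolated case-study edges")
    for name, s in sets.items():
        if s & isolated:
            raise LeakageError(f"{name} intersects isolated case-study edges")
    seen: set[Edge] = set()
    for f in folds:
        fs = set(f)
        if fs & seen:
            raise LeakageError("folds are not pairwise disjoint")
        seen |= fs


def mean_record(records: list[MetricsRecord]) -> MetricsRecord:
    return MetricsRecord(
        auc=float(np.mean([r.auc for r in records])),
        aupr=float(np.mean([r.aupr for r in records])),
        acc=float(np.mean([r.acc for r in records])),
        pre=float(np.mean([r.pre for r in records])),
        rec=float(np.mean([r.rec for r in records])),
        f1=float(np.mean([r.f1 for r in records])),
        n_pos=int(sum(r.n_pos for r in records)),
        n_neg=int(sum(r.n_neg for r in records)),
    )


def _masked_gd_network(template: Network, train_pos: list[Edge]) -> Network:
    genes, diseases = template.row_nodes, template.col_nodes
    edges = {(genes[g], diseases[d]): 1.0 for g, d in train_pos}
    return Network(kind="G-D", row_nodes=list(genes), col_nodes=list(diseases),
                   edges=edges)


def cross_validate(
    suite: Suite,
    config: PipelineConfig | None = None,
    k: int = 5,
    seed: int = 7,
    isolated_edges: list[Edge] | None = None,
) -> tuple[list[MetricsRecord], MetricsRecord]:
    """Full pipeline under k-fold edge cross-validation.

    Fusion runs once per call (it never sees gene-disease edges); for each
    fold the [G,D] graph is rebuilt with the training positives only, the
    GCN is trained on training positives plus 1:1 sampled negatives, and the
    held-out positives are scored against fresh negatives.
    """
    config = config or PipelineConfig()
    networks = suite.networks
    A_GPR = hetero_from_networks(networks, ["G", "P", "R"])
    A_GTR = hetero_from_networks(networks, ["G", "T", "R"])
    fus_cfg = replace(config.fusion, seed=seed)
    ebfc, _ = fused_gene_network(
        None if config.variant == "noGPR" else A_GPR,
        None if config.variant == "noGTR" else A_GTR,
        fus_cfg,
        variant=config.variant,
    )

    gd = networks["G-D"]
    if ebfc.gene_ids != gd.row_nodes:
        raise ValueError("gene vocabulary mismatch between fusion output and G-D")
    gene_pos = {n: i for i, n in enumerate(gd.row_nodes)}
    dis_pos = {n: i for i, n in enumerate(gd.col_nodes)}
    pos_edges = sorted((gene_pos[u], dis_pos[v]) for (u, v) in gd.edges)
    isolated = set(isolated_edges or [])
    pos_edges = [e for e in pos_edges if e not in isolated]
    all_pos = set(pos_edges) | isolated

    n_g, n_d = len(gd.row_nodes), len(gd.col_nodes)
    adj_gd = np.zeros((n_g, n_d))
    for g, d in all_pos:
        adj_gd[g, d] = 1.0

    hyper = config.gcn
    sae_params, _ = gcn.train_sae(
        {"G": suite.gene_features.values, "D": suite.disease_features.values},
        c_sae=hyper.c_sae,
        epochs=hyper.sae_epochs,
        lr=hyper.sae_lr,
        seed=seed,
    )
    X = np.vstack([
        gcn.sae_encode(suite.gene_features.values, sae_params, "G"),
        gcn.sae_encode(suite.disease_features.values, sae_params, "D"),
    ])

    folds = kfold_split(pos_edges, k, seed)
    records: list[MetricsRecord] = []
    for fi in range(k):
        test_pos = folds[fi]
        train_pos = [e for fj, f in enumerate(folds) if fj != fi for e in f]
        fold_seed = (seed * 1009 + 17 * fi) % (2**31)
        train_neg = sample_negatives(
            adj_gd, int(round(config.neg_ratio * len(train_pos))),
            seed=fold_seed, forbidden=all_pos,
        )
        test_neg = sample_negatives(
            adj_gd, len(test_pos),
            seed=fold_seed + 1, forbidden=all_pos | set(train_neg),
        )
        _audit(folds, train_pos, test_pos, train_neg, test_neg, isolated, all_pos)
        graph = build_ebfc_dd_graph(
            ebfc.matrix, gd.row_nodes, networks["D-D"],
            _masked_gd_network(gd, train_pos),
        )
        model, _ = gcn.train(
            graph, X, train_pos, train_neg, hyper,
            seed=fold_seed + 2, strict=config.strict,
        )
        eval_pairs = list(test_pos) + list(test_neg)
        scores = gcn.predict_scores(model, graph, X, eval_pairs)
        labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
        records.append(compute_metrics(scores, labels))
    return records, mean_record(records)


def write_metrics(records: list[MetricsRecord], mean: MetricsRecord, prefix) -> None:
    """TSV (one row per fold + mean) and JSON exports."""
    from pathlib import Path

    prefix = Path(prefix)
    cols = ["auc", "aupr", "acc", "pre", "rec", "f1", "n_pos", "n_neg"]
    lines = ["fold\t" + "\t".join(cols)]
    for i, r in enumerate(records):
        lines.append(f"{i}\t" + "\t".join(str(getattr(r, c)) for c in cols))
    lines.append("mean\t" + "\t".join(str(getattr(mean, c)) for c in cols))
    Path(str(prefix) + ".tsv").write_text("\n".join(lines) + "\n")
    payload = {
        "folds": [dataclasses.asdict(r) for r in records],
        "mean": dataclasses.asdict(mean),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(payload, indent=1))


def fit_full_model(
    suite: Suite, config: PipelineConfig | None = None, seed: int = 7
) -> dict:
    """Train on all known associations (no holdout) for downstream ranking."""
    config = config or PipelineConfig()
    networks = suite.networks
    A_GPR = hetero_from_networks(networks, ["G", "P", "R"])
    A_GTR = hetero_from_networks(networks, ["G", "T", "R"])
    ebfc, _ = fused_gene_network(
        None if config.variant == "noGPR" else A_GPR,
        None if config.variant == "noGTR" else A_GTR,
        replace(config.fusion, seed=seed),
        variant=config.variant,
    )
    gd = networks["G-D"]
    gene_pos = {n: i for i, n in enumerate(gd.row_nodes)}
    dis_pos = {n: i for i, n in enumerate(gd.col_nodes)}
    pos_edges = sorted((gene_pos[u], dis_pos[v]) for (u, v) in gd.edges)
    adj_gd = np.zeros((len(gd.row_nodes), len(gd.col_nodes)))
    for g, d in pos_edges:
        adj_gd[g, d] = 1.0
    hyper = config.gcn
    sae_params, _ = gcn.train_sae(
        {"G": suite.gene_features.values, "D": suite.disease_features.values},
        c_sae=hyper.c_sae, epochs=hyper.sae_epochs, lr=hyper.sae_lr, seed=seed,
    )
    X = np.vstack([
        gcn.sae_encode(suite.gene_features.values, sae_params, "G"),
        gcn.sae_encode(suite.disease_features.values, sae_params, "D"),
    ])
    negatives = sample_negatives(
        adj_gd, int(round(config.neg_ratio * len(pos_edges))),
        seed=seed, forbidden=set(pos_edges),
    )
    graph = build_ebfc_dd_graph(ebfc.matrix, gd.row_nodes, networks["D-D"], gd)
    model, history = gcn.train(
        graph, X, pos_edges, negatives, hyper, seed=seed, strict=config.strict
    )
    return {
        "ebfc": ebfc,
        "X": X,
        "model": model,
        "history": history,
        "graph": graph,
        "gene_ids": list(gd.row_nodes),
        "disease_ids": list(gd.col_nodes),
        "n_pos": len(pos_edges),
    }
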