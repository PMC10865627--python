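"""Seeded synthetic multi-network suites with planted community structure.

The generator emulates, at toy scale, the structural assumptions the method
exploits: genes shared across all networks, community-correlated regulation
and expression, diseases grouped by similarity, and gene-disease
associations concentrated between matched gene communities and disease
groups.  Eleven typed networks, a continuous gene-expression feature matrix
(community profile plus Gaussian noise) and a binary disease genotype
feature matrix are produced, together with a ground-truth record of every
assignment.  Identical configs yield byte-identical suites.

The two heterograph views are complementary by construction: each gene
community is the intersection of an *expression module* (which drives
parcel/region connectivity, gene-region and gene-parcel expression and the
site profile of the gene features) and a *regulatory module* (which drives
TF-target wiring and hence T-T similarity and gene-gene co-regulation).
Either view alone only resolves a coarsening of the communities, so fusing
both views is required to separate all communities — mirroring the role the
two heterographs play in the method.

The negative control (``shuffled=True``) replaces the planted gene-disease
associations with a degree-balanced uniform assignment: every gene receives
(almost) the same number of links and no community is preferred, so a model
trained on the control suite has nothing generalizable to learn — neither
community signal nor degree signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .netio import (
    UNIPARTITE_KINDS,
    FeatureMatrix,
    Network,
    build_network,
    read_edge_list,
    read_feature_matrix,
    write_edge_list,
    write_feature_matrix,
)


@dataclass
class SuiteConfig:
    n_genes: int = 100
    n_tfs: int = 10
    n_parcels: int = 8
    n_regions: int = 12
    n_diseases: int = 15
    n_sites: int = 30
    n_variants: int = 20
    n_communities: int = 5
    association_strength: float = 0.9
    links_per_disease: int = 20
    noise_sd: float = 1.0
    p_gt_in: float = 0.7
    p_gt_out: float = 0.05
    p_gg_in: float = 0.05
    p_gg_out: float = 0.02
    p_tr: float = 0.3
    p_dd_in: float = 0.8
    p_dd_out: float = 0.05
    loading_primary: float = 0.8
    loading_region: float = 0.45
    sim_threshold: float = 0.25
    seed: int = 7
    shuffled: bool = False

    def validate(self) -> None:
        if self.n_communities > min(self.n_genes, self.n_diseases):
            raise ValueError("n_communities exceeds min(n_genes, n_diseases)")
        if not 0.0 <= self.association_strength <= 1.0:
            raise ValueError("association_strength must lie in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("p_gt_in", "p_gt_out", "p_gg_in", "p_gg_out", "p_dd_in", "p_dd_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.links_per_disease > self.n_genes:
            raise ValueError("links_per_disease exceeds n_genes")


@dataclass
class Suite:
    config: SuiteConfig
    networks: dict[str, Network]
    gene_features: FeatureMatrix
    disease_features: FeatureMatrix
    ground_truth: dict = field(default_factory=dict)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_suite(config: SuiteConfig) -> Suite:
    """Generate the full eleven-network suite plus both feature matrices."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    C = config.n_communities

    genes = _ids("g", config.n_genes)
    tfs = _ids("t", config.n_tfs)
    parcels = _ids("p", config.n_parcels)
    regions = _ids("r", config.n_regions)
    diseases = _ids("d", config.n_diseases)

    gene_comm = np.arange(config.n_genes) % C
    dis_group = np.arange(config.n_diseases) % C
    variant_comm = np.arange(config.n_variants) % C

    # Each community c factorizes into an expression module v1(c) and a
    # regulatory module v2(c); the pair (v1, v2) identifies c (for C >= 3),
    # so neither view alone separates all communities.
    if C >= 3:
        comm_expr = np.arange(C) // 2
        comm_reg = ((np.arange(C) + 1) % C) // 2
    else:
        comm_expr = np.arange(C)
        comm_reg = np.arange(C)
    n_expr = int(comm_expr.max()) + 1
    n_reg = int(comm_reg.max()) + 1
    gene_expr = comm_expr[gene_comm]
    gene_reg = comm_reg[gene_comm]

    tf_module = np.arange(config.n_tfs) % n_reg
    region_primary = np.arange(config.n_regions) % n_expr
    parcel_module = np.arange(config.n_parcels) % n_expr
    parcel_region = np.arange(config.n_parcels) % config.n_regions
    site_primary = np.arange(config.n_sites) % n_expr

    # expression-module loading profiles: parcels are fine-grained and sharp,
    # regions are coarse spatial units that mix modules
    def _loadings(n_units, primary, peak):
        L = np.full((n_units, n_expr), (1.0 - peak) / max(n_expr - 1, 1))
        L[np.arange(n_units), primary] = peak
        return L

    load_parcel = _loadings(config.n_parcels, parcel_module, config.loading_primary)
    load = _loadings(config.n_regions, region_primary, config.loading_region)

    networks: dict[str, Network] = {}

    # G-T: TFs wired mostly to genes of their regulatory module
    gt_edges: dict[tuple[str, str], float] = {}
    targets: dict[int, set[int]] = {t: set() for t in range(config.n_tfs)}
    for t in range(config.n_tfs):
        for g in range(config.n_genes):
            p = config.p_gt_in if gene_reg[g] == tf_module[t] else config.p_gt_out
            if rng.random() < p:
                gt_edges[(genes[g], tfs[t])] = 1.0
                targets[t].add(g)
    networks["G-T"] = build_network("G-T", gt_edges, row_nodes=genes, col_nodes=tfs)

    # T-T: Jaccard overlap of target sets
    tt_edges: dict[tuple[str, str], float] = {}
    for a in range(config.n_tfs):
        for b in range(a + 1, config.n_tfs):
            union = targets[a] | targets[b]
            if not union:
                continue
            w = len(targets[a] & targets[b]) / len(union)
            if w > 0.0:
                tt_edges[(tfs[a], tfs[b])] = round(w, 6)
    networks["T-T"] = build_network("T-T", tt_edges, row_nodes=tfs)

    # G-G: weak co-regulation within regulatory modules plus background noise
    gg_edges: dict[tuple[str, str], float] = {}
    for a in range(config.n_genes):
        for b in range(a + 1, config.n_genes):
            p = config.p_gg_in if gene_reg[a] == gene_reg[b] else config.p_gg_out
            if rng.random() < p:
                gg_edges[(genes[a], genes[b])] = 1.0
    networks["G-G"] = build_network("G-G", gg_edges, row_nodes=genes)

    # R-R / P-P: loading-profile similarity above a threshold
    rr_edges: dict[tuple[str, str], float] = {}
    for a in range(config.n_regions):
        for b in range(a + 1, config.n_regions):
            w = float(load[a] @ load[b])
            if w >= config.sim_threshold:
                rr_edges[(regions[a], regions[b])] = round(w, 6)
    networks["R-R"] = build_network("R-R", rr_edges, row_nodes=regions)

    pp_edges: dict[tuple[str, str], float] = {}
    for a in range(config.n_parcels):
        for b in range(a + 1, config.n_parcels):
            w = float(load_parcel[a] @ load_parcel[b])
            if w >= config.sim_threshold:
                pp_edges[(parcels[a], parcels[b])] = round(w, 6)
    networks["P-P"] = build_network("P-P", pp_edges, row_nodes=parcels)

    # P-R: binary membership
    pr_edges = {
        (parcels[p], regions[parcel_region[p]]): 1.0 for p in range(config.n_parcels)
    }
    networks["P-R"] = build_network("P-R", pr_edges, row_nodes=parcels, col_nodes=regions)

    # T-R: TF activity in regions, unstructured (regulatory modules are not
    # aligned with the expression axis by construction)
    tr_edges: dict[tuple[str, str], float] = {}
    for t in range(config.n_tfs):
        for r in range(config.n_regions):
            if rng.random() < config.p_tr:
                tr_edges[(tfs[t], regions[r])] = round(float(rng.uniform(0.3, 1.0)), 6)
    networks["T-R"] = build_network("T-R", tr_edges, row_nodes=tfs, col_nodes=regions)

    # G-R / G-P: expression driven by expression-module loading, mildly noised
    gr_edges: dict[tuple[str, str], float] = {}
    for g in range(config.n_genes):
        for r in range(config.n_regions):
            w = float(load[r, gene_expr[g]] + rng.normal(0.0, 0.05))
            if w >= config.sim_threshold:
                gr_edges[(genes[g], regions[r])] = round(w, 6)
    networks["G-R"] = build_network("G-R", gr_edges, row_nodes=genes, col_nodes=regions)

    gp_edges: dict[tuple[str, str], float] = {}
    for g in range(config.n_genes):
        for p in range(config.n_parcels):
            w = float(load_parcel[p, gene_expr[g]] + rng.normal(0.0, 0.05))
            if w >= config.sim_threshold:
                gp_edges[(genes[g], parcels[p])] = round(w, 6)
    networks["G-P"] = build_network("G-P", gp_edges, row_nodes=genes, col_nodes=parcels)

    # D-D: dense within group, sparse across
    dd_edges: dict[tuple[str, str], float] = {}
    for a in range(config.n_diseases):
        for b in range(a + 1, config.n_diseases):
            p = config.p_dd_in if dis_group[a] == dis_group[b] else config.p_dd_out
            if rng.random() < p:
                dd_edges[(diseases[a], diseases[b])] = 1.0
    networks["D-D"] = build_network("D-D", dd_edges, row_nodes=diseases)

    # G-D: planted associations (or the degree-balanced null)
    gd_pairs: set[tuple[int, int]] = set()
    if config.shuffled:
        gd_pairs = _balanced_null_links(config, rng)
    else:
        for d in range(config.n_diseases):
            comm = dis_group[d]
            in_comm = np.flatnonzero(gene_comm == comm)
            out_comm = np.flatnonzero(gene_comm != comm)
            n_in = int(rng.binomial(config.links_per_disease, config.association_strength))
            n_in = min(n_in, len(in_comm))
            n_out = min(config.links_per_disease - n_in, len(out_comm))
            chosen = np.concatenate([
                rng.choice(in_comm, size=n_in, replace=False),
                rng.choice(out_comm, size=n_out, replace=False),
            ])
            gd_pairs.update((int(g), d) for g in chosen)
    gd_edges = {(genes[g], diseases[d]): 1.0 for g, d in gd_pairs}
    networks["G-D"] = build_network("G-D", gd_edges, row_nodes=genes, col_nodes=diseases)

    # gene features: expression-module profile over brain sites + Gaussian noise
    mu = np.where(site_primary[None, :] == gene_expr[:, None], 1.0, 0.2)
    gene_vals = mu + rng.normal(0.0, config.noise_sd, size=mu.shape)
    gene_features = FeatureMatrix(
        node_ids=genes,
        feature_ids=_ids("s", config.n_sites),
        values=np.round(gene_vals, 9),
    )

    # disease features: binary indicators of community-linked variant columns
    dis_vals = (variant_comm[None, :] == dis_group[:, None]).astype(float)
    disease_features = FeatureMatrix(
        node_ids=diseases, feature_ids=_ids("v", config.n_variants), values=dis_vals
    )

    ground_truth = {
        "gene_communities": gene_comm.tolist(),
        "gene_expression_modules": gene_expr.tolist(),
        "gene_regulatory_modules": gene_reg.tolist(),
        "disease_groups": dis_group.tolist(),
        "tf_modules": tf_module.tolist(),
        "region_primary": region_primary.tolist(),
        "parcel_region": parcel_region.tolist(),
        "planted_gd": sorted([int(g), int(d)] for g, d in gd_pairs),
        "shuffled": config.shuffled,
        "config": dataclasses.asdict(config),
    }
    return Suite(
        config=config,
        networks=networks,
        gene_features=gene_features,
        disease_features=disease_features,
        ground_truth=ground_truth,
    )


def _balanced_null_links(config: SuiteConfig, rng: np.random.Generator) -> set[tuple[int, int]]:
    """Uniform, near-regular gene-disease assignment (the negative control)."""
    total = config.n_diseases * config.links_per_disease
    for _ in range(100):
        pool: list[int] = []
        while len(pool) < total:
            pool.extend(rng.permutation(config.n_genes).tolist())
        pairs = set()
        ok = True
        for d in range(config.n_diseases):
            chunk = pool[d * config.links_per_disease : (d + 1) * config.links_per_disease]
            if len(set(chunk)) != len(chunk):
                ok = False
                break
            pairs.update((g, d) for g in chunk)
        if ok:
            return pairs
    raise RuntimeError("could not build a duplicate-free null assignment")


FILE_NAMES = {kind: kind.lower().replace("-", "_") + ".tsv" for kind in (
    "G-T", "T-T", "T-R", "G-G", "G-R", "R-R", "P-R", "P-P", "G-P", "D-D", "G-D",
)}


def suite_to_files(suite: Suite, directory) -> None:
    """Write the suite as TSV edge lists + feature CSVs + ground-truth JSON +
    a suite.yaml recording the config; re-readable with zero loss."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, net in suite.networks.items():
        write_edge_list(net, directory / FILE_NAMES[kind])
        # vocabularies may exceed ids seen in edges; record them
        (directory / (FILE_NAMES[kind] + ".rows")).write_text(
            "\n".join(net.row_nodes) + "\n"
        )
        (directory / (FILE_NAMES[kind] + ".cols")).write_text(
            "\n".join(net.col_nodes) + "\n"
        )
    write_feature_matrix(suite.gene_features, directory / "gene_features.csv")
    write_feature_matrix(suite.disease_features, directory / "disease_features.csv")
    (directory / "ground_truth.json").write_text(
        json.dumps(suite.ground_truth, indent=1, sort_keys=True)
    )
    (directory / "suite.yaml").write_text(
        yaml.safe_dump({"suite": dataclasses.asdict(suite.config)}, sort_keys=True)
    )


def load_suite(directory) -> Suite:
    directory = Path(directory)
    cfg_raw = yaml.safe_load((directory / "suite.yaml").read_text())["suite"]
    config = SuiteConfig(**cfg_raw)
    networks: dict[str, Network] = {}
    for kind, fname in FILE_NAMES.items():
        net = read_edge_list(directory / fname, kind)
        rows = (directory / (fname + ".rows")).read_text().split()
        cols = (directory / (fname + ".cols")).read_text().split()
        if kind in UNIPARTITE_KINDS:
            networks[kind] = build_network(kind, net.edges, row_nodes=rows)
        else:
            networks[kind] = build_network(kind, net.edges, row_nodes=rows, col_nodes=cols)
    gene_features = read_feature_matrix(directory / "gene_features.csv")
    disease_features = read_feature_matrix(directory / "disease_features.csv")
    ground_truth = json.loads((directory / "ground_truth.json").read_text())
    return Suite(
        config=config,
        networks=networks,
        gene_features=gene_features,
        disease_features=disease_features,
        ground_truth=ground_truth,
    )
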