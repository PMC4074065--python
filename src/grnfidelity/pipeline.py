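"""End-to-end orchestration of the two inference phases.

Phase 1: prepare the expression matrix, build per-gene subnetwork
ensembles, sample putative networks, pool edge statistics, attach
semantic similarity, compute fidelity scores and filter at each cutoff.

Phase 2: SOM co-clustering over the full gene set, cluster expansion of
the scaffold, re-scoring over the expanded population, filtering, and
cluster-product prioritisation.

All randomness flows from one master seed through named child streams,
so reruns are byte-identical and per-gene work is order-independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, expansion, fidelity, som, topology
from .ensemble import (
    SearchConfig,
    build_all_ensembles,
    edge_statistics,
    sample_networks,
)
from .expression import ExpressionMatrix, read_expression_tsv, scale_rows
from .fidelity import FilteredNetwork, ranked_table
from .netio import read_tsv_with_header, write_tsv_with_header
from .similarity import AnnotationSet, read_annotations

__all__ = ["PipelineConfig", "Phase1Result", "Phase2Result",
           "phase1", "phase2", "run_phase1", "run_phase2"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    # inference
    acceptance_threshold: float = 0.75
    k_max: int = 3
    ensemble_cap: int = 200
    attempt_budget: int = 1000
    n_networks: int = 1000
    # clustering
    som_runs: int = 200
    grid_min: int = 3
    grid_max: int = 50
    som_epochs: int = 50
    dispersion_cutoff: float = 0.20
    coincidence_threshold: float = 0.70
    # scoring
    weight: float = 1.0
    cutoffs: tuple[float, ...] = (2.0, 2.5, 3.0)
    max_cluster_product: int = 30
    # inputs
    expression: str | None = None
    annotations: str | None = None
    reference: str | None = None

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            k_max=self.k_max, ensemble_cap=self.ensemble_cap,
            attempt_budget=self.attempt_budget,
            acceptance_threshold=self.acceptance_threshold,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "cutoffs" in data:
            data["cutoffs"] = tuple(data["cutoffs"])
        return cls(**data)


def _child_seed(master: int, label: str) -> int:
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


@dataclass
class Phase1Result:
    ensembles: dict
    edge_stats: list
    records: list                       # scored FidelityRecords
    filtered: dict[float, FilteredNetwork] = field(default_factory=dict)


@dataclass
class Phase2Result:
    cocluster: som.CoClusterResult
    partition: som.ClusterPartition
    expanded: list
    network: FilteredNetwork
    prioritized: object                 # DataFrame


def phase1(m: ExpressionMatrix, ann: AnnotationSet,
           cfg: PipelineConfig) -> Phase1Result:
    if not m.scaled:
        m = scale_rows(m)
    ensembles = build_all_ensembles(m, cfg.search_config(),
                                    seed=_child_seed(cfg.seed, "ensembles"))
    nets = sample_networks(ensembles, cfg.n_networks,
                           seed=_child_seed(cfg.seed, "sampling"))
    stats = edge_statistics(nets)
    log.info("phase1: %d genes, %d directed edges called",
             m.n_genes, len(stats))
    records = fidelity.records_from_stats(stats, ann=ann)
    records = fidelity.score_records(records, w=cfg.weight)
    filtered = {c: fidelity.filter_network(records, c) for c in cfg.cutoffs}
    for c, net in filtered.items():
        log.info("phase1 cutoff %.2f: %d nodes / %d edges",
                 c, len(net.nodes), net.n_edges)
    return Phase1Result(ensembles=ensembles, edge_stats=stats,
                        records=records, filtered=filtered)


def phase2(scaffold: FilteredNetwork, full_matrix: ExpressionMatrix,
           ann: AnnotationSet, cfg: PipelineConfig,
           raw_matrix: ExpressionMatrix | None = None) -> Phase2Result:
    """Expand a scaffold over profile clusters of the full gene set.

    The dispersion pre-filter runs on the pre-scaling measurement scale
    when ``raw_matrix`` is given; scaffold genes are always retained for
    clustering so the expansion stays anchored.
    """
    disp_source = raw_matrix if raw_matrix is not None else full_matrix
    included, excluded = som.dispersion_filter(disp_source,
                                               cfg.dispersion_cutoff)
    keep = sorted(set(included) | set(scaffold.nodes))
    sub = full_matrix.subset(keep)
    # grid sizes scale with the gene pool so the cells-to-genes ratio
    # matches the study's regime (genes outnumber map nodes)
    grid_cap = max(cfg.grid_min, int(round(np.sqrt(sub.n_genes / 2))))
    cc = som.co_cluster(sub, n_runs=cfg.som_runs, grid_min=cfg.grid_min,
                        grid_max=min(cfg.grid_max, grid_cap),
                        n_epochs=cfg.som_epochs,
                        seed=_child_seed(cfg.seed, "som"))
    cc.excluded = [g for g in excluded if g not in set(scaffold.nodes)]
    part = som.partition(cc, cfg.coincidence_threshold)
    expanded = expansion.expand(scaffold, part, ann)
    net = expansion.rescore_and_filter(expanded, w=cfg.weight,
                                       cutoff=min(cfg.cutoffs))
    for r_i, r in enumerate(net.edges):     # attach cluster products
        net.edges[r_i] = fidelity.FidelityRecord(
            source=r.source, target=r.target, confidence=r.confidence,
            jaccard=r.jaccard, sign_call=r.sign_call,
            cluster_product=som.cluster_product((r.source, r.target), part),
            zc=r.zc, zj=r.zj, z_w=r.z_w)
    table = expansion.prioritize(net, cfg.max_cluster_product, part)
    log.info("phase2: %d clusters (%d singletons), %d expanded edges, "
             "%d retained", len(part.clusters), part.singleton_count,
             len(expanded), net.n_edges)
    return Phase2Result(cocluster=cc, partition=part, expanded=expanded,
                        network=net, prioritized=table)


def _load_inputs(cfg: PipelineConfig):
    if cfg.expression is None:
        raise ValueError("config.expression path is required")
    m = read_expression_tsv(cfg.expression)
    if not isinstance(m, ExpressionMatrix):
        from .expression import collapse_probesets

        m = collapse_probesets(m)
    m = scale_rows(m)
    ann = (read_annotations(cfg.annotations) if cfg.annotations
           else AnnotationSet())
    return m, ann


def run_phase1(cfg: PipelineConfig, outdir) -> Phase1Result:
    """File-level Phase 1: read inputs, infer, score, write artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, ann = _load_inputs(cfg)
    res = phase1(m, ann, cfg)
    h = cfg.config_hash()
    write_tsv_with_header(ranked_table(res.records),
                          outdir / "scored_edges.tsv", h)
    import pandas as pd

    stats_df = pd.DataFrame([{
        "source": s.source, "target": s.target, "confidence": s.confidence,
        "frac_activation": s.frac_activation,
        "frac_inhibition": s.frac_inhibition, "sign_call": s.sign_call,
    } for s in res.edge_stats])
    write_tsv_with_header(stats_df, outdir / "edge_stats.tsv", h)
    from .ensemble import ensembles_to_frame

    write_tsv_with_header(ensembles_to_frame(res.ensembles),
                          outdir / "ensembles.tsv", h)
    for c, net in res.filtered.items():
        write_tsv_with_header(ranked_table(net.edges),
                              outdir / f"network_z{c:g}.tsv", h)
    (outdir / "config.json").write_text(
        json.dumps(asdict(cfg), indent=2, default=str))
    return res


def run_phase2(cfg: PipelineConfig, outdir,
               scaffold_path=None) -> Phase2Result:
    """File-level Phase 2 from a written Phase 1 scaffold."""
    outdir = Path(outdir)
    scaffold_path = Path(scaffold_path or
                         outdir / f"network_z{min(cfg.cutoffs):g}.tsv")
    if not scaffold_path.exists():
        raise FileNotFoundError(f"missing scaffold artifact {scaffold_path}")
    h = cfg.config_hash()
    df, _found = read_tsv_with_header(scaffold_path, expect_hash=h)
    scaffold = FilteredNetwork(
        edges=[fidelity.FidelityRecord(
            source=row.source, target=row.target, confidence=row.confidence,
            jaccard=row.jaccard, sign_call=row.sign_call,
            zc=row.zc, zj=row.zj, z_w=row.z_w)
            for row in df.itertuples()],
        cutoff=min(cfg.cutoffs))
    m, ann = _load_inputs(cfg)
    res = phase2(scaffold, m, ann, cfg)
    import pandas as pd

    exp_df = pd.DataFrame([{
        "parent_source": e.parent_source, "parent_target": e.parent_target,
        "source": e.source, "target": e.target,
        "confidence": e.inherited_confidence, "jaccard": e.jaccard,
        "cluster_product": e.cluster_product,
    } for e in res.expanded])
    write_tsv_with_header(exp_df, outdir / "expanded_edges.tsv", h)
    write_tsv_with_header(ranked_table(res.network.edges),
                          outdir / "expanded_network.tsv", h)
    write_tsv_with_header(res.prioritized, outdir / "prioritized.tsv", h)
    from .netio import write_graphml, write_sif

    write_sif(res.network, outdir / "expanded_network.sif")
    write_graphml(res.network, outdir / "expanded_network.graphml")
    return res


def evaluate_against_reference(records, reference, genes,
                               cutoffs=(2.0, 2.5, 3.0)):
    """Convenience: undirected curves + enrichment for scored records."""
    scored = evaluation.to_undirected(
        [(r.source, r.target, r.z_w) for r in records])
    report = evaluation.curves(scored, reference, genes)
    sig = evaluation.significance_vs_cutoff(scored, reference, cutoffs, genes)
    return report, sig


def topology_by_cutoff(records, cutoffs):
    out = {}
    for c in cutoffs:
        net = fidelity.filter_network(records, c)
        if net.n_edges == 0:
            out[c] = None
            continue
        out[c] = topology.topology_report(net)
    return out
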