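"""Fidelity score: confidence and semantic similarity fused per edge.

Both the confidence metric (edge appearance frequency) and the Jaccard
semantic similarity are approximately log-normally distributed, so each
is z-scored over the current edge population and combined as

    Z_k(w) = Zc_k + w * Zj_k

where Zc_k is the z-score of log confidence and Zj_k the z-score of the
Jaccard index.  Only nonzero Jaccard values are z-scored; edges with zero
term overlap receive the sentinel min(Zj) - 1, keeping Zj centred while
still penalising semantically dissimilar pairs.  w weighs the
data-independent evidence; w = 0 ranks by confidence alone.

Z-scores are population statistics of the network under analysis, so
fidelity scores are comparable within one network but never across
networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FidelityRecord",
    "FilteredNetwork",
    "DegeneratePopulationError",
    "records_from_stats",
    "zscore_log_confidence",
    "zscore_jaccard",
    "fidelity",
    "score_records",
    "optimize_weight",
    "filter_network",
    "ranked_table",
]

DEFAULT_WEIGHT_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0)


class DegeneratePopulationError(ValueError):
    """Raised when an edge population cannot be z-scored (n < 2 or SD 0)."""


@dataclass(frozen=True)
class FidelityRecord:
    source: str
    target: str
    confidence: float
    jaccard: float
    sign_call: str = "unclear"
    cluster_product: int | None = None
    zc: float | None = None
    zj: float | None = None
    z_w: float | None = None


@dataclass
class FilteredNetwork:
    edges: list[FidelityRecord]
    cutoff: float

    @property
    def nodes(self) -> list[str]:
        seen = {g for r in self.edges for g in (r.source, r.target)}
        return sorted(seen)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self, directed: bool = False):
        import networkx as nx

        g = nx.DiGraph() if directed else nx.Graph()
        for r in self.edges:
            g.add_edge(r.source, r.target, confidence=r.confidence,
                       z_w=r.z_w, sign=r.sign_call)
        return g


def records_from_stats(edge_stats, similarity: dict[frozenset, float] | None = None,
                       ann=None) -> list[FidelityRecord]:
    """Join EdgeStat confidence with per-pair Jaccard similarity."""
    from .similarity import jaccard as _jac

    out = []
    for s in edge_stats:
        key = frozenset((s.source, s.target))
        if similarity is not None and key in similarity:
            j = similarity[key]
        elif ann is not None:
            j = _jac(ann.terms(s.source), ann.terms(s.target))
        else:
            j = 0.0
        out.append(FidelityRecord(source=s.source, target=s.target,
                                  confidence=s.confidence, jaccard=j,
                                  sign_call=s.sign_call))
    return out


def _zscores(values: np.ndarray) -> np.ndarray:
    if len(values) < 2:
        raise DegeneratePopulationError("fewer than 2 edges")
    sd = values.std()          # population SD
    if sd == 0:
        raise DegeneratePopulationError("zero variance in population")
    return (values - values.mean()) / sd


def zscore_log_confidence(records: list[FidelityRecord]) -> list[FidelityRecord]:
    """Natural-log confidence, z-scored over the edge population."""
    if any(r.confidence <= 0 for r in records):
        raise ValueError("zero confidence edge cannot exist in the population")
    zc = _zscores(np.array([math.log(r.confidence) for r in records]))
    return [replace(r, zc=float(z)) for r, z in zip(records, zc)]


def zscore_jaccard(records: list[FidelityRecord]) -> list[FidelityRecord]:
    """Z-score nonzero Jaccard values; zero-overlap edges get min(Zj) - 1."""
    nz_idx = [i for i, r in enumerate(records) if r.jaccard > 0]
    if len(nz_idx) < 2:
        warnings.warn("fewer than 2 nonzero-Jaccard edges; "
                      "semantic weight disabled (all Zj = 0)", stacklevel=2)
        return [replace(r, zj=0.0) for r in records]
    zj_nz = _zscores(np.array([records[i].jaccard for i in nz_idx]))
    sentinel = float(zj_nz.min()) - 1.0
    zj = np.full(len(records), sentinel)
    for i, z in zip(nz_idx, zj_nz):
        zj[i] = z
    return [replace(r, zj=float(z)) for r, z in zip(records, zj)]


def fidelity(records: list[FidelityRecord], w: float) -> list[FidelityRecord]:
    """Combine populated zc/zj into z_w = zc + w * zj."""
    if w < 0:
        raise ValueError("weight w must be nonnegative")
    out = []
    for r in records:
        if r.zc is None or r.zj is None:
            raise ValueError("zc/zj must be populated before fidelity()")
        out.append(replace(r, z_w=r.zc + w * r.zj))
    return out


def score_records(records: list[FidelityRecord], w: float = 1.0,
                  ) -> list[FidelityRecord]:
    """Convenience: z-score both metrics then combine at weight w."""
    return fidelity(zscore_jaccard(zscore_log_confidence(records)), w)


def optimize_weight(
    records: list[FidelityRecord],
    reference: set[frozenset],
    grid=DEFAULT_WEIGHT_GRID,
) -> float:
    """Pick the weight maximizing AUPR against the reference edge set.

    The comparison is undirected; ties in AUPR resolve to the smallest
    weight.  Raises if the reference shares no pair with the records.
    """
    from .evaluation import aupr_of_scored, to_undirected

    if not reference:
        raise ValueError("reference edge set is empty")
    base = zscore_jaccard(zscore_log_confidence(records))
    pairs = {frozenset((r.source, r.target)) for r in base}
    if not pairs & set(reference):
        raise ValueError("reference disjoint from scored edges: AUPR undefined")
    genes = sorted({g for r in base for g in (r.source, r.target)})
    best_w, best_aupr = None, -1.0
    for w in sorted(grid):
        scored = to_undirected([(r.source, r.target, r.zc + w * r.zj)
                                for r in base])
        aupr = aupr_of_scored(scored, reference, genes)
        if aupr > best_aupr + 1e-12:
            best_w, best_aupr = w, aupr
    return float(best_w)


def filter_network(records: list[FidelityRecord], cutoff: float) -> FilteredNetwork:
    """Retain edges with z_w strictly above the cutoff; drop isolated nodes."""
    kept = [r for r in records if r.z_w is not None and r.z_w > cutoff]
    return FilteredNetwork(edges=kept, cutoff=cutoff)


def ranked_table(records: list[FidelityRecord]) -> pd.DataFrame:
    """Scored edge table ranked by descending fidelity score."""
    df = pd.DataFrame([{
        "source": r.source, "target": r.target,
        "confidence": r.confidence, "jaccard": r.jaccard,
        "zc": r.zc, "zj": r.zj, "z_w": r.z_w,
        "sign_call": r.sign_call, "cluster_product": r.cluster_product,
    } for r in records])
    if not df.empty:
        df = df.sort_values(["z_w", "source", "target"],
                            ascending=[False, True, True], kind="stable")
        df = df.reset_index(drop=True)
    return df
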