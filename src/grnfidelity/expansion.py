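"""Phase 2: cluster expansion of the filtered scaffold network.

Genes with near-identical profiles are interchangeable to a purely
profile-driven inference, so each scaffold edge A->B is expanded to every
cross pair between A's and B's co-clustering clusters (|cluster(A)| x
|cluster(B)| combinations, self-pairs excluded).  Expanded pairs inherit
the parent edge's confidence, get their own Jaccard similarity, and the
whole expanded population is re-z-scored and filtered with the fidelity
score.  The cluster product then prioritises predictions explained by few
interchangeable genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .fidelity import (
    FidelityRecord,
    FilteredNetwork,
    fidelity,
    zscore_jaccard,
    zscore_log_confidence,
)
from .similarity import AnnotationSet, jaccard
from .som import ClusterPartition, cluster_product

__all__ = [
    "ExpandedEdge",
    "expand",
    "rescore_and_filter",
    "prioritize",
]

DEFAULT_MAX_CLUSTER_PRODUCT = 30


@dataclass(frozen=True)
class ExpandedEdge:
    parent_source: str
    parent_target: str
    source: str
    target: str
    inherited_confidence: float
    jaccard: float
    cluster_product: int
    z_w: float | None = None


def expand(
    scaffold: FilteredNetwork,
    part: ClusterPartition,
    ann: AnnotationSet,
) -> list[ExpandedEdge]:
    """All cross-cluster combinations of every scaffold edge.

    Self-pairs are dropped.  When the same unordered pair arises from
    several parent edges, the parent with the highest inherited
    confidence wins; both orientations generated within a single
    same-cluster parent are kept (they are distinct combinations of that
    expansion, not duplicates).
    """
    by_pair: dict[frozenset, list[ExpandedEdge]] = {}
    for rec in scaffold.edges:
        src_cluster = sorted(part.cluster_of(rec.source))
        tgt_cluster = sorted(part.cluster_of(rec.target))
        prod = len(src_cluster) * len(tgt_cluster)
        for s in src_cluster:
            for t in tgt_cluster:
                if s == t:
                    continue
                edge = ExpandedEdge(
                    parent_source=rec.source, parent_target=rec.target,
                    source=s, target=t,
                    inherited_confidence=rec.confidence,
                    jaccard=jaccard(ann.terms(s), ann.terms(t)),
                    cluster_product=prod,
                )
                by_pair.setdefault(frozenset((s, t)), []).append(edge)
    out: list[ExpandedEdge] = []
    for candidates in by_pair.values():
        top = max(c.inherited_confidence for c in candidates)
        winner_parent = next(
            (c.parent_source, c.parent_target) for c in candidates
            if c.inherited_confidence == top)
        out.extend(c for c in candidates
                   if (c.parent_source, c.parent_target) == winner_parent)
    return sorted(out, key=lambda e: (e.source, e.target))


def expansion_cardinality(edge_src: str, edge_tgt: str,
                          part: ClusterPartition) -> int:
    """|cluster(src)| * |cluster(tgt)| minus the self-pairs removed."""
    cs = part.cluster_of(edge_src)
    ct = part.cluster_of(edge_tgt)
    return len(cs) * len(ct) - len(cs & ct)


def rescore_and_filter(
    expanded: list[ExpandedEdge],
    w: float = 1.0,
    cutoff: float = 2.5,
) -> FilteredNetwork:
    """Recompute fidelity z-scores over the expanded population and filter.

    Z-scores are population statistics, so the expanded network gets its
    own, never the scaffold's.
    """
    if not expanded:
        raise ValueError("expanded edge list is empty")
    records = [FidelityRecord(source=e.source, target=e.target,
                              confidence=e.inherited_confidence,
                              jaccard=e.jaccard,
                              cluster_product=e.cluster_product)
               for e in expanded]
    scored = fidelity(zscore_jaccard(zscore_log_confidence(records)), w)
    kept = [r for r in scored if r.z_w > cutoff]
    return FilteredNetwork(edges=kept, cutoff=cutoff)


def prioritize(
    expanded: FilteredNetwork,
    max_cluster_product: int = DEFAULT_MAX_CLUSTER_PRODUCT,
    part: ClusterPartition | None = None,
) -> pd.DataFrame:
    """Secondary filter on profile uniqueness, then rank.

    Keeps edges with cluster product <= max_cluster_product, ranked by
    z_w descending; ties break by ascending cluster product, then by the
    lexicographic pair.
    """
    rows = []
    for r in expanded.edges:
        prod = r.cluster_product
        if prod is None:
            prod = cluster_product((r.source, r.target), part) if part else 1
        if prod <= max_cluster_product:
            rows.append({"source": r.source, "target": r.target,
                         "confidence": r.confidence, "jaccard": r.jaccard,
                         "z_w": r.z_w, "cluster_product": prod,
                         "sign_call": r.sign_call})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["z_w", "cluster_product", "source", "target"],
            ascending=[False, True, True, True], kind="stable",
        ).reset_index(drop=True)
    return df
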