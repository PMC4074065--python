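"""GO-term-set semantic similarity (Jaccard index) between gene pairs.

Annotations are assumed pre-propagated to the ontology root, so the term
set itself proxies a gene's biological role and plain set overlap
|A ∩ B| / |A ∪ B| measures functional similarity.  Information-content or
graph-based measures are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AnnotationSet",
    "SimilarityRecord",
    "jaccard",
    "pairwise_similarity",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class SimilarityRecord:
    gene_a: str
    gene_b: str
    jaccard: float


class AnnotationSet(dict):
    """gene id -> frozenset of opaque term identifiers.

    Missing genes behave as unannotated (empty set).
    """

    def terms(self, gene: str) -> frozenset:
        return self.get(gene, frozenset())


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|, defined as 0.0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def pairwise_similarity(ann: AnnotationSet, pairs) -> list[SimilarityRecord]:
    """One symmetric record per requested gene pair."""
    return [SimilarityRecord(g1, g2, jaccard(ann.terms(g1), ann.terms(g2)))
            for g1, g2 in pairs]


def read_annotations(path, fmt: str = "tsv") -> AnnotationSet:
    """Read gene->terms from two-column TSV (gene_id, term_id) or GAF 2.x.

    For GAF only the DB-object-symbol (col 2) and GO id (col 5) are used;
    comment lines starting with '!' are skipped.
    """
    ann = AnnotationSet()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", header=0,
                         names=["gene_id", "term_id"], dtype=str, comment="#")
        for gene, grp in df.groupby("gene_id"):
            ann[gene] = frozenset(grp["term_id"])
    elif fmt == "gaf":
        genes: dict[str, set] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 5:
                    continue
                genes.setdefault(cols[1], set()).add(cols[4])
        for g, terms in genes.items():
            ann[g] = frozenset(terms)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return ann


def write_annotations(ann: AnnotationSet, path) -> None:
    rows = [(g, t) for g in sorted(ann) for t in sorted(ann[g])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        path, sep="\t", index=False)
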