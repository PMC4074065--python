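"""Benchmarking scored networks against a reference interaction set.

Reference databases export undirected interactions, so every comparison
collapses direction first (max score over the two directions).  The edge
population for curves is all unordered pairs among the evaluated genes —
pairs never called by the inference receive a score below every called
edge — which makes the false-positive rate well defined.  Network-level
enrichment is the upper-tail hypergeometric probability of the observed
reference-edge overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "CurveReport",
    "EnrichmentResult",
    "to_undirected",
    "curves",
    "aupr_of_scored",
    "hypergeometric_significance",
    "topk_enrichment",
    "significance_vs_cutoff",
]


@dataclass
class EnrichmentResult:
    population: int        # N: possible undirected pairs
    reference_size: int    # K
    called: int            # n
    hits: int              # x
    p_value: float


@dataclass
class CurveReport:
    pr_points: list[tuple[float, float]]     # (recall, precision)
    roc_points: list[tuple[float, float]]    # (fpr, tpr)
    aupr: float
    auroc: float
    baseline_precision: float


def to_undirected(scored_edges) -> dict[frozenset, float]:
    """Collapse directed scores to unordered pairs, keeping the max."""
    out: dict[frozenset, float] = {}
    for src, tgt, score in scored_edges:
        key = frozenset((src, tgt))
        if key not in out or score > out[key]:
            out[key] = score
    return out


def _population_scores(scored: dict[frozenset, float], reference, genes):
    """Score + label vectors over all unordered gene pairs.

    Uncalled pairs score one unit below the lowest called edge so that a
    threshold sweep places them in a single trailing tie group.
    """
    genes = sorted(genes)
    floor = (min(scored.values()) - 1.0) if scored else 0.0
    y, s = [], []
    for a, b in combinations(genes, 2):
        key = frozenset((a, b))
        y.append(1 if key in reference else 0)
        s.append(scored.get(key, floor))
    return np.asarray(y), np.asarray(s, dtype=float)


def curves(scored: dict[frozenset, float], reference, genes) -> CurveReport:
    """PR and ROC curves with trapezoidal AUCs, grouped-tie thresholds."""
    y, s = _population_scores(scored, reference, genes)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative pair")
    prec, rec, _ = precision_recall_curve(y, s)
    # sklearn's arrays run from the lowest threshold (recall 1) up to the
    # (recall 0, precision 1) endpoint; reversing keeps tie groups in
    # sweep order so the trapezoid is well defined
    prec, rec = prec[::-1], rec[::-1]
    aupr = float(np.trapezoid(prec, rec))
    fpr, tpr, _ = roc_curve(y, s)
    auroc = float(np.trapezoid(tpr, fpr))
    return CurveReport(
        pr_points=list(zip(rec.tolist(), prec.tolist())),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        aupr=aupr,
        auroc=auroc,
        baseline_precision=float(y.mean()),
    )


def aupr_of_scored(scored: dict[frozenset, float], reference, genes) -> float:
    return curves(scored, reference, genes).aupr


def hypergeometric_significance(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail P(X >= x), X ~ Hypergeometric(N, K, n), log-space stable.

    This is the complement convention of a CDF routine: enrichment asks
    how surprising at least x reference edges among n called are.
    """
    if not (0 <= x <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"impossible counts N={N}, K={K}, n={n}, x={x}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, K, n))


def topk_enrichment(
    scored: dict[frozenset, float], reference, ks
) -> dict[int, float]:
    """Fraction of reference edges among the k top-scored pairs.

    Ranking is score descending with lexicographic pair tie-break, so the
    result is deterministic under tied scores.
    """
    ranked = sorted(scored.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
    out = {}
    for k in ks:
        if k > len(ranked):
            raise ValueError(f"k={k} exceeds {len(ranked)} scored pairs")
        hits = sum(1 for key, _ in ranked[:k] if key in reference)
        out[int(k)] = hits / k
    return out


def significance_vs_cutoff(
    scored: dict[frozenset, float], reference, cutoffs, genes
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of the network retained at each cutoff.

    An empty retained set has undefined enrichment and is reported with
    p = 1.0 (hits = called = 0).
    """
    genes = sorted(set(genes))
    N = len(genes) * (len(genes) - 1) // 2
    ref = {k for k in reference
           if all(g in genes for g in k)}
    K = len(ref)
    out = []
    for cut in cutoffs:
        called = {k for k, v in scored.items() if v > cut}
        x = len(called & ref)
        n = len(called)
        p = 1.0 if n == 0 else hypergeometric_significance(N, K, n, x)
        out.append(EnrichmentResult(population=N, reference_size=K,
                                    called=n, hits=x, p_value=p))
    return out
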