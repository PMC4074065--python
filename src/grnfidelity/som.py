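"""SOM co-clustering of expression profiles.

Genes with near-identical time courses confound profile-driven inference,
so profile-similarity clusters are estimated stochastically: many
self-organizing maps with randomly drawn square grid sizes (3x3 through
50x50 in the full-scale setting) are trained on the profiles, and the
fraction of runs in which two genes map to the same map node — their
coincidence frequency — measures profile similarity.  Thresholding the
coincidence graph (70% by default) and taking connected components yields
the clusters used for Phase 2 module expansion.

A dispersion pre-filter removes stable, non-dynamic genes (standard
deviation over mean below 20% on the pre-scaling measurement scale).

The SOM itself is the classic batch algorithm on a square grid with a
Gaussian neighborhood whose radius shrinks linearly over a fixed number
of epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "CoClusterResult",
    "ClusterPartition",
    "dispersion_filter",
    "batch_som",
    "co_cluster",
    "partition",
    "cluster_product",
]

DISPERSION_CUTOFF = 0.20
COINCIDENCE_THRESHOLD = 0.70


@dataclass
class CoClusterResult:
    genes: list[str]
    coincidence: np.ndarray        # (n, n) symmetric, unit diagonal
    n_runs: int
    excluded: list[str] = field(default_factory=list)

    def pair_frequency(self, a: str, b: str) -> float:
        i, j = self.genes.index(a), self.genes.index(b)
        return float(self.coincidence[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format nonzero off-diagonal pairs (a < b)."""
        rows = []
        for i, a in enumerate(self.genes):
            for j in range(i + 1, len(self.genes)):
                f = self.coincidence[i, j]
                if f > 0:
                    rows.append((a, self.genes[j], f))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "frequency"])


@dataclass
class ClusterPartition:
    clusters: list[frozenset]
    threshold: float

    @property
    def singleton_count(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)

    def cluster_of(self, gene: str) -> frozenset:
        for c in self.clusters:
            if gene in c:
                return c
        return frozenset({gene})      # unclustered genes act as singletons

    def size_of(self, gene: str) -> int:
        return len(self.cluster_of(gene))


def dispersion_filter(
    m: ExpressionMatrix, cutoff: float = DISPERSION_CUTOFF
) -> tuple[list[str], list[str]]:
    """Split genes into (included, excluded) by SD/mean dispersion.

    Uses population SD (denominator n).  Genes with dispersion below the
    cutoff are stable/non-dynamic and excluded; zero-mean profiles are
    excluded too (dispersion undefined).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    included, excluded = [], []
    for g in m.gene_ids:
        prof = m.profile(g)
        mean = prof.mean()
        if mean == 0:
            excluded.append(g)
            continue
        disp = prof.std() / mean
        (included if disp >= cutoff else excluded).append(g)
    return included, excluded


def batch_som(
    data: np.ndarray,
    side: int,
    n_epochs: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Train a square batch SOM; return the best-matching unit per sample.

    Code vectors initialize from random data rows; each epoch assigns
    BMUs and replaces every code vector by the Gaussian-neighborhood
    weighted mean of the data, the radius shrinking linearly from side/2
    to 0.5.
    """
    rng = rng or np.random.default_rng()
    data = np.asarray(data, dtype=float)
    n = len(data)
    n_nodes = side * side
    gi, gj = np.divmod(np.arange(n_nodes), side)
    grid_d2 = (gi[:, None] - gi[None, :]) ** 2 + (gj[:, None] - gj[None, :]) ** 2
    w = data[rng.integers(0, n, size=n_nodes)].copy()
    w += rng.normal(0, 1e-4, size=w.shape)       # break exact init ties
    sigma0, sigma1 = max(side / 2.0, 1.0), 0.5
    for epoch in range(n_epochs):
        d2 = ((data[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        sigma = sigma0 + (sigma1 - sigma0) * epoch / max(n_epochs - 1, 1)
        h = np.exp(-grid_d2[:, bmu] / (2.0 * sigma * sigma))  # (nodes, samples)
        mass = h.sum(axis=1)
        upd = h @ data
        nz = mass > 1e-12
        w[nz] = upd[nz] / mass[nz, None]
    d2 = ((data[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def co_cluster(
    m: ExpressionMatrix,
    n_runs: int = 200,
    grid_min: int = 3,
    grid_max: int = 50,
    n_epochs: int = 50,
    seed: int = 0,
) -> CoClusterResult:
    """Pool repeated SOM runs into a gene-pair coincidence matrix.

    Each run draws the grid side uniformly in [grid_min, grid_max]; two
    genes coincide in a run when they map to the same node.  The study
    scale is 2,240 runs on grids 3x3..50x50; the default here is a
    desk-scale 200 runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    genes = m.gene_ids
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to co-cluster")
    data = m.values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(genes)
    counts = np.zeros((n, n), dtype=np.int64)
    for _ in range(n_runs):
        side = int(rng.integers(grid_min, grid_max + 1))
        bmu = batch_som(data, side, n_epochs=n_epochs, rng=rng)
        same = bmu[:, None] == bmu[None, :]
        counts += same
    coincidence = counts / n_runs
    np.fill_diagonal(coincidence, 1.0)
    return CoClusterResult(genes=list(genes), coincidence=coincidence,
                           n_runs=n_runs)


def partition(
    cc: CoClusterResult, threshold: float = COINCIDENCE_THRESHOLD
) -> ClusterPartition:
    """Connected components of the coincidence graph at the threshold.

    At threshold 0 every pair connects (one all-gene cluster); raising
    the threshold can only split clusters, never merge them.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(cc.genes)
    n = len(cc.genes)
    for i in range(n):
        for j in range(i + 1, n):
            if cc.coincidence[i, j] >= threshold:
                g.add_edge(cc.genes[i], cc.genes[j])
    clusters = [frozenset(comp) for comp in nx.connected_components(g)]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterPartition(clusters=clusters, threshold=threshold)


def cluster_product(edge: tuple[str, str], part: ClusterPartition) -> int:
    """|cluster(source)| x |cluster(target)| — the profile-uniqueness metric.

    Low products mark edges whose endpoints have nearly unique profiles and
    are therefore high-priority, experimentally unambiguous predictions.
    """
    src, tgt = edge
    return part.size_of(src) * part.size_of(tgt)
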