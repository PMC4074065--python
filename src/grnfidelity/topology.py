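"""Topology characterisation of filtered networks.

The unfiltered inference output is a near-complete "hairball" whose degree
distribution is approximately Poisson (lambda ~ mean degree 2E/N).  As the
fidelity cutoff rises, the retained networks become scale-free — degree
counts follow a power law p(k) ~ k^-gamma — and hierarchical, with the
average clustering coefficient scaling as C(k) ~ 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "TopologyReport",
    "degree_stats",
    "powerlaw_fit",
    "clustering_scaling",
    "topology_report",
]


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    degree_hist: dict[int, int]
    lambda_hat: float
    gamma_hat: float | None
    gamma_r2: float | None
    ck_r2: float | None


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph) and not net.is_directed():
        return net
    if isinstance(net, nx.DiGraph):
        return net.to_undirected()
    return net.to_graph(directed=False)     # FilteredNetwork


def degree_stats(net) -> tuple[dict[int, int], float]:
    """Degree histogram and the Poisson mean-degree estimate 2E/N."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degs = [d for _, d in g.degree()]
    hist: dict[int, int] = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    lambda_hat = 2 * g.number_of_edges() / g.number_of_nodes()
    return dict(sorted(hist.items())), lambda_hat


def powerlaw_fit(degree_hist: dict[int, int]) -> tuple[float | None, float | None]:
    """Least-squares slope of log count vs log degree; gamma = -slope.

    Zero-degree and zero-count bins are ignored.  Requires at least three
    distinct positive degrees; otherwise returns (None, None).
    """
    ks = np.array([k for k, c in degree_hist.items() if k > 0 and c > 0],
                  dtype=float)
    cs = np.array([c for k, c in degree_hist.items() if k > 0 and c > 0],
                  dtype=float)
    if len(ks) < 3:
        return None, None
    x, y = np.log(ks), np.log(cs)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(-slope), r2


def clustering_scaling(net) -> float | None:
    """R^2 of the origin-through fit of mean C(k) against 1/k.

    C(k) averages the node clustering coefficient over nodes of degree k
    (degree >= 2 only; C is undefined below).  A value near 1 indicates a
    hierarchical network; returns None with fewer than 3 usable degrees.
    """
    g = _as_graph(net)
    coeffs = nx.clustering(g)
    by_k: dict[int, list[float]] = {}
    for node, c in coeffs.items():
        k = g.degree(node)
        if k >= 2:
            by_k.setdefault(k, []).append(c)
    if len(by_k) < 3:
        return None
    ks = np.array(sorted(by_k), dtype=float)
    ck = np.array([np.mean(by_k[int(k)]) for k in ks])
    x = 1.0 / ks
    beta = float(np.sum(ck * x) / np.sum(x * x))
    pred = beta * x
    ss_res = float(np.sum((ck - pred) ** 2))
    ss_tot = float(np.sum((ck - ck.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def topology_report(net) -> TopologyReport:
    g = _as_graph(net)
    hist, lam = degree_stats(g)
    gamma, gamma_r2 = powerlaw_fit(hist)
    ck_r2 = clustering_scaling(g)
    return TopologyReport(
        n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(),
        degree_hist=hist, lambda_hat=lam,
        gamma_hat=gamma, gamma_r2=gamma_r2, ck_r2=ck_r2,
    )
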