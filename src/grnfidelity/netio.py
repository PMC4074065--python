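"""Network export: TSV edge lists, SIF and GraphML.

Every TSV written by the pipeline carries a ``# config_hash:`` header so
artifacts produced under different configurations cannot be silently
mixed between phases.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "write_tsv_with_header",
    "read_tsv_with_header",
    "write_sif",
    "write_graphml",
]


def write_tsv_with_header(df: pd.DataFrame, path, config_hash: str | None = None,
                          ) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv_with_header(path, expect_hash: str | None = None):
    """Read a pipeline TSV; refuse it if the config hash does not match."""
    path = Path(path)
    found = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# config_hash:"):
            found = first.split(":", 1)[1].strip()
    if expect_hash is not None and found is not None and found != expect_hash:
        raise ValueError(
            f"{path} was produced under config {found[:12]}..., "
            f"expected {expect_hash[:12]}...: refusing to mix artifacts")
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, found


_SIF_RELATION = {"activating": "activates", "inhibiting": "inhibits",
                 "unclear": "interacts"}


def write_sif(net, path) -> None:
    """Simple interaction format: source <relation> target per line."""
    with open(path, "w") as fh:
        for r in net.edges:
            rel = _SIF_RELATION.get(r.sign_call, "interacts")
            fh.write(f"{r.source}\t{rel}\t{r.target}\n")


def write_graphml(net, path, directed: bool = True) -> None:
    g = nx.DiGraph() if directed else nx.Graph()
    for r in net.edges:
        g.add_edge(r.source, r.target,
                   confidence=float(r.confidence),
                   jaccard=float(r.jaccard),
                   z_w=float(r.z_w) if r.z_w is not None else 0.0,
                   sign=r.sign_call)
    nx.write_graphml(g, path)
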