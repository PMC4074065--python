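"""Expression-matrix container and preparation steps.

The pipeline consumes a genes x ordered-stages matrix of nonnegative
expression values.  Before inference each row is min-max scaled to [0, 1]
(zero = minimum expression of that gene across the time course, one =
maximum), multi-probeset genes are collapsed to the probeset with the
widest dynamic range, and the working gene list is the union of top
differentially-expressed genes, top differentially-expressed transcription
factors and a curated list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSelection",
    "collapse_probesets",
    "scale_rows",
    "select_genes",
    "read_expression_tsv",
    "write_expression_tsv",
]


class EmptyMatrixError(ValueError):
    """Raised when an operation receives a matrix with no rows."""


@dataclass
class ExpressionMatrix:
    """Genes x ordered developmental stages.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene identifiers, one column per stage
        in temporal order, nonnegative floats.
    symbols
        Optional display-name per gene id (defaults to the ids themselves).
    scaled
        True once every row has been min-max scaled to [0, 1].
    constant_rows
        Gene ids whose profile was constant at scaling time (set to 0.5).
    """

    values: pd.DataFrame
    symbols: pd.Series | None = None
    scaled: bool = False
    constant_rows: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dup[:5])}")
        self.values = self.values.astype(float)
        self.values.index.name = "gene_id"
        if self.symbols is None:
            self.symbols = pd.Series(self.values.index, index=self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_genes(self) -> int:
        return len(self.values)

    @property
    def n_stages(self) -> int:
        return self.values.shape[1]

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def subset(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return replace(
            self,
            values=self.values.loc[genes],
            symbols=self.symbols.loc[genes],
            constant_rows=tuple(g for g in self.constant_rows if g in genes),
        )


@dataclass
class GeneSelection:
    """Criteria for assembling the working gene list."""

    top_de_genes: int = 0
    top_de_tfs: int = 0
    curated_list: tuple[str, ...] = ()
    tf_flags: dict[str, bool] | None = None


def collapse_probesets(raw: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a multi-probeset matrix to one row per gene.

    ``raw`` needs columns ``gene_id``, ``probeset_id``, optionally
    ``symbol``, and one numeric column per stage.  For each gene the
    probeset with the largest dynamic range (max - min over stages) is
    kept; ties break to the lexicographically smallest probeset id.
    """
    if raw.empty:
        raise EmptyMatrixError("empty probeset matrix")
    meta_cols = [c for c in ("gene_id", "probeset_id", "symbol") if c in raw.columns]
    if "gene_id" not in meta_cols or "probeset_id" not in meta_cols:
        raise ValueError("collapse_probesets requires gene_id and probeset_id columns")
    stage_cols = [c for c in raw.columns if c not in meta_cols]
    df = raw.sort_values("probeset_id", kind="stable").copy()
    rng = df[stage_cols].max(axis=1) - df[stage_cols].min(axis=1)
    df["_range"] = rng
    # stable sort: within a gene, rows ordered by probeset id, so idxmax on
    # -range after a stable descending-range sort keeps the smallest id on ties
    df = df.sort_values(["gene_id", "_range", "probeset_id"],
                        ascending=[True, False, True], kind="stable")
    best = df.drop_duplicates("gene_id", keep="first")
    values = best.set_index("gene_id")[stage_cols]
    symbols = (best.set_index("gene_id")["symbol"]
               if "symbol" in best.columns
               else pd.Series(values.index, index=values.index))
    return ExpressionMatrix(values=values, symbols=symbols)


def scale_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Min-max scale every row to [0, 1]; idempotent.

    A constant row cannot be scaled; it is set to 0.5 everywhere and its
    gene id recorded in ``constant_rows`` (a warning is emitted).
    """
    vals = m.values.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    const = span[:, 0] == 0
    span[const] = 1.0
    out = (vals - lo) / span
    out[const] = 0.5
    flagged = tuple(np.asarray(m.values.index)[const])
    if flagged:
        warnings.warn(f"constant rows set to 0.5: {list(flagged)[:5]}", stacklevel=2)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values, scaled=True,
                   constant_rows=tuple(sorted(set(m.constant_rows) | set(flagged))))


def _ranking_stat(vals: pd.DataFrame, ranking: str) -> pd.Series:
    if ranking == "variance":
        # population variance of the min-max scaled profile
        v = vals.to_numpy(dtype=float)
        lo, hi = v.min(axis=1, keepdims=True), v.max(axis=1, keepdims=True)
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        scaled = (v - lo) / span
        return pd.Series(scaled.var(axis=1), index=vals.index)
    if ranking == "dynamic_range":
        return vals.max(axis=1) - vals.min(axis=1)
    raise ValueError(f"unknown ranking statistic {ranking!r}")


def select_genes(
    m: ExpressionMatrix,
    sel: GeneSelection,
    ranking: str = "variance",
) -> tuple[ExpressionMatrix, list[str]]:
    """Union of top-k DE genes, top-k DE TFs and a curated list.

    Ranking is by ``variance`` (cross-stage population variance of the
    scaled profile, the default) or ``dynamic_range``.  Returns the
    selected matrix (rows ordered by gene id) and the list of curated
    genes absent from the matrix (a warning, not an error).
    """
    stat = _ranking_stat(m.values, ranking)
    order = stat.sort_values(ascending=False, kind="stable")
    chosen: set[str] = set(order.index[: sel.top_de_genes])
    if sel.top_de_tfs > 0:
        if not sel.tf_flags:
            raise ValueError("top_de_tfs > 0 requires tf_flags")
        tf_order = [g for g in order.index if sel.tf_flags.get(g, False)]
        chosen |= set(tf_order[: sel.top_de_tfs])
    missing = [g for g in sel.curated_list if g not in m.values.index]
    chosen |= {g for g in sel.curated_list if g in m.values.index}
    if missing:
        warnings.warn(f"curated genes absent from matrix: {missing[:5]}", stacklevel=2)
    return m.subset(sorted(chosen)), missing


def read_expression_tsv(path) -> ExpressionMatrix | pd.DataFrame:
    """Read the TSV schema: gene_id, [symbol], [probeset_id], [is_tf], stages.

    If a ``probeset_id`` column is present, the raw DataFrame is returned
    for :func:`collapse_probesets`; otherwise an :class:`ExpressionMatrix`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "probeset_id" in df.columns:
        return df
    meta = [c for c in ("gene_id", "symbol", "is_tf") if c in df.columns]
    stage_cols = [c for c in df.columns if c not in meta]
    values = df.set_index("gene_id")[stage_cols]
    symbols = (df.set_index("gene_id")["symbol"] if "symbol" in df.columns else None)
    return ExpressionMatrix(values=values, symbols=symbols)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.insert(0, "symbol", m.symbols)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
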