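"""Within-group gene-gene and gene-set correlation of expression.

Correlations are computed per age group, across that group's cells, on the
untransformed RPKM vectors (Pearson by default, Spearman available). A gene
with zero variance in a group — typically one with no expression there at
all — has no defined correlation with anything; such pairs are reported
with an explicit *undefined* marker and serialised as ``"-"``, never
silently dropped. This mirrors real screens where a senescence gene like
Cdkn2a is simply undetected in young hepatocytes.

Gene-set screening correlates each query gene against every member of a
reference senescence signature (a SenMayo-style symbol list) that is
present in the data, flagging pairs at or above a configurable "high
correlation" cutoff and reporting set members that were not measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "GeneSet",
    "CorrelationMatrix",
    "GeneSetCorrelation",
    "pairwise_correlation",
    "geneset_correlation",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene symbols."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ConfigurationError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ConfigurationError(f"gene set {self.name!r} has duplicate symbols")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric correlation matrix with explicit undefined entries.

    ``matrix`` holds the coefficients with NaN marking *undefined* (at
    least one gene of the pair has zero variance in the group); ``defined``
    is the matching boolean mask. Undefined entries serialise as ``"-"``.
    """

    matrix: pd.DataFrame
    defined: pd.DataFrame
    n_cells: int
    method: str

    def is_defined(self, a: str, b: str) -> bool:
        return bool(self.defined.loc[a, b])

    def coefficient(self, a: str, b: str) -> float:
        """The coefficient for a pair; NaN when undefined."""
        return float(self.matrix.loc[a, b])


@dataclass(frozen=True)
class GeneSetCorrelation:
    """Query-vs-gene-set correlations plus the unmeasured set members."""

    table: pd.DataFrame  # query_gene, set_gene, coefficient, defined, high
    not_measured: tuple[str, ...]
    gene_set: str
    high_r: float
    n_cells: int
    method: str


def _resolve_genes(expr: AnnData, genes: list[str]) -> tuple[list[int], list[str]]:
    """Map requested gene labels (id or symbol) to column indices."""
    by_id = {g: i for i, g in enumerate(expr.var_names)}
    symbols = expr.var["symbol"].to_numpy() if "symbol" in expr.var.columns else None
    idx, labels = [], []
    for g in genes:
        if g in by_id:
            idx.append(by_id[g])
            labels.append(g)
            continue
        if symbols is not None:
            hits = np.flatnonzero(symbols == g)
            if hits.size == 1:
                idx.append(int(hits[0]))
                labels.append(g)
                continue
            if hits.size > 1:
                raise AnalysisError(f"gene symbol {g!r} is ambiguous")
        raise AnalysisError(f"unknown gene {g!r}")
    if len(set(labels)) != len(labels):
        raise AnalysisError(f"duplicate genes requested: {genes}")
    return idx, labels


def _dense_submatrix(expr: AnnData, cols: list[int], group_cells: list[str]) -> np.ndarray:
    obs_index = pd.Index(expr.obs_names)
    missing = [c for c in group_cells if c not in obs_index]
    if missing:
        raise AnalysisError(f"cells not in expression matrix: {missing[:10]}")
    rows = obs_index.get_indexer(group_cells)
    X = sparse.csr_matrix(expr.X)
    return np.asarray(X[rows][:, cols].todense(), dtype=np.float64)


def pairwise_correlation(
    expr: AnnData,
    genes: list[str],
    group_cells: list[str],
    method: str = "pearson",
) -> CorrelationMatrix:
    """Correlation of every unordered gene pair across a group's cells.

    ``genes`` may be gene ids or symbols; ``group_cells`` selects the group
    (at least 3 cells). Zero-variance genes yield undefined entries; the
    diagonal is 1 wherever it is defined.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    if len(group_cells) < 3:
        raise AnalysisError(
            f"need at least 3 cells to correlate, got {len(group_cells)}"
        )
    cols, labels = _resolve_genes(expr, list(genes))
    sub = _dense_submatrix(expr, cols, list(group_cells))

    if method == "spearman":
        sub = stats.rankdata(sub, axis=0)
    sd = sub.std(axis=0)
    defined_gene = sd > 0

    k = len(labels)
    mat = np.full((k, k), np.nan)
    if defined_gene.any():
        centred = sub[:, defined_gene] - sub[:, defined_gene].mean(axis=0)
        cov = centred.T @ centred
        norm = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        sub_corr = cov / norm
        np.fill_diagonal(sub_corr, 1.0)
        live = np.flatnonzero(defined_gene)
        mat[np.ix_(live, live)] = np.clip(sub_corr, -1.0, 1.0)

    matrix = pd.DataFrame(mat, index=labels, columns=labels)
    defined = pd.DataFrame(
        np.outer(defined_gene, defined_gene), index=labels, columns=labels
    )
    return CorrelationMatrix(
        matrix=matrix, defined=defined, n_cells=len(group_cells), method=method
    )


def geneset_correlation(
    expr: AnnData,
    query_genes: list[str],
    gene_set: GeneSet,
    group_cells: list[str],
    high_r: float = 0.6,
    method: str = "pearson",
) -> GeneSetCorrelation:
    """Correlate query genes against a reference gene set within a group.

    Set members absent from the expression matrix are reported as
    ``not_measured``; rows with a defined coefficient >= ``high_r`` are
    flagged ``high``. Coefficients are NaN (undefined) when either gene has
    zero variance in the group.
    """
    symbols = (
        set(expr.var["symbol"]) if "symbol" in expr.var.columns else set()
    ) | set(expr.var_names)
    measured = [s for s in gene_set.symbols if s in symbols]
    not_measured = tuple(s for s in gene_set.symbols if s not in symbols)

    if not measured:
        table = pd.DataFrame(
            columns=["query_gene", "set_gene", "coefficient", "defined", "high"]
        )
        return GeneSetCorrelation(
            table=table,
            not_measured=not_measured,
            gene_set=gene_set.name,
            high_r=high_r,
            n_cells=len(group_cells),
            method=method,
        )

    queries = list(query_genes)
    set_only = [s for s in measured if s not in set(queries)]
    corr = pairwise_correlation(expr, queries + set_only, group_cells, method=method)

    rows = []
    for q in queries:
        for s in measured:
            if s == q:
                continue
            coef = corr.coefficient(q, s)
            defined = corr.is_defined(q, s)
            rows.append(
                {
                    "query_gene": q,
                    "set_gene": s,
                    "coefficient": coef if defined else np.nan,
                    "defined": defined,
                    "high": bool(defined and coef >= high_r),
                }
            )
    table = pd.DataFrame(rows, columns=["query_gene", "set_gene", "coefficient", "defined", "high"])
    return GeneSetCorrelation(
        table=table,
        not_measured=not_measured,
        gene_set=gene_set.name,
        high_r=high_r,
        n_cells=len(group_cells),
        method=method,
    )
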