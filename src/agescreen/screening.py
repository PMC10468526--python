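"""The positive-cell-rate screen for age-associated genes.

A cell is *positive* for a gene when its expression exceeds 1 RPKM (strict
inequality). The *positive cell rate* of a gene in a group is the number of
positive cells divided by the group's cell count. Genes are ranked on the
old-minus-young difference of these rates — the screen targets genes whose
expressing-cell fraction rises with age — and the top K genes that have a
known mouse ortholog become the candidate list.

The gene universe of the ranking is the union over groups; a gene never
detected in one group contributes a rate of zero there (absence of
detection is informative for an increase screen). Ties in the rate
difference are broken by ascending gene id so the ranking is deterministic.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "call_positive",
    "positive_rates",
    "rank_by_rate_difference",
    "select_candidates",
]


def call_positive(expr: AnnData, threshold_rpkm: float = 1.0) -> AnnData:
    """Binarise expression: call = 1 iff rpkm > threshold (strict).

    Zeros can never be positive for a non-negative threshold, so the calls
    are computed on the sparse structure without densification.
    """
    if threshold_rpkm < 0:
        raise ConfigurationError("threshold_rpkm must be >= 0")
    X = sparse.csr_matrix(expr.X)
    calls = X.copy()
    calls.data = (calls.data > threshold_rpkm).astype(np.int8)
    calls.eliminate_zeros()
    out = AnnData(X=calls, obs=expr.obs.copy(), var=expr.var.copy())
    out.uns["threshold_rpkm"] = float(threshold_rpkm)
    return out


def positive_rates(
    calls: AnnData, group_of_cell: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-gene, per-group positive-cell counts and rates.

    ``group_of_cell`` maps every cell id in ``calls`` to its group label.
    Returns a long table with one row per (gene, group): ``gene_id``,
    ``group``, ``n_positive``, ``n_cells`` and ``rate`` (the exact ratio).
    """
    if isinstance(group_of_cell, pd.Series):
        mapping = group_of_cell.to_dict()
    else:
        mapping = dict(group_of_cell)
    labels = []
    unassigned = []
    for c in calls.obs_names:
        g = mapping.get(c)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            unassigned.append(c)
        else:
            labels.append(str(g))
    if unassigned:
        raise AnalysisError(f"cells without a group label: {unassigned[:10]}")

    labels = np.asarray(labels, dtype=object)
    X = sparse.csr_matrix(calls.X)
    rows = []
    for group in sorted(set(labels)):
        members = labels == group
        n_cells = int(members.sum())
        if n_cells == 0:
            raise AnalysisError(f"group {group!r} has no cells")
        n_pos = np.asarray(X[members].sum(axis=0)).ravel().astype(np.int64)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": list(calls.var_names),
                    "group": group,
                    "n_positive": n_pos,
                    "n_cells": n_cells,
                    "rate": n_pos / n_cells,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def rank_by_rate_difference(rates: pd.DataFrame) -> pd.DataFrame:
    """Rank genes on the old-minus-young positive-rate difference.

    The union of both groups' genes is used; a gene missing from one group
    gets rate 0 there. The result has columns ``gene_id``, ``rate_young``,
    ``rate_old``, ``delta`` and ``rank`` (1 = largest delta), sorted by
    descending delta with ties broken by ascending gene id.
    """
    present = set(rates["group"].unique())
    for needed in ("young", "old"):
        if needed not in present:
            raise AnalysisError(f"group {needed!r} missing from the rate table")
    wide = (
        rates.pivot_table(index="gene_id", columns="group", values="rate", fill_value=0.0)
        .reindex(columns=["young", "old"], fill_value=0.0)
        .rename(columns={"young": "rate_young", "old": "rate_old"})
    )
    wide["delta"] = wide["rate_old"] - wide["rate_young"]
    out = wide.reset_index().sort_values(
        ["delta", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)[["gene_id", "rate_young", "rate_old", "delta", "rank"]]


def select_candidates(
    ranking: pd.DataFrame,
    annotation: pd.DataFrame,
    top_k: int = 43,
    require_ortholog: bool = True,
) -> pd.DataFrame:
    """Take the top-K candidates, optionally requiring a mouse ortholog.

    With ``require_ortholog`` the genes lacking an ortholog symbol are
    dropped *before* truncation, so the list always holds the K best
    ortholog-bearing genes (shorter only if the ranking runs out). Ranks
    from the full ranking are preserved for auditability.
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be >= 1")
    merged = ranking.merge(
        annotation[["gene_id", "symbol", "ortholog_symbol"]], on="gene_id", how="left"
    )
    if require_ortholog:
        merged = merged[merged["ortholog_symbol"].notna()]
    return merged.head(top_k).reset_index(drop=True)
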