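"""Cell quality control, per-cell RPKM, and albumin gating.

Two quality rules are applied to the raw count matrix: cells detecting fewer
than ``min_genes`` genes (count > 0) are dropped, and cells whose
mitochondrial reads exceed ``max_mito`` of their total reads are dropped.
Both comparisons are strict, so a cell at exactly the threshold (200 genes,
20% mitochondrial) is retained. The mitochondrial fraction is computed on
raw counts, before any normalisation.

Expression is then normalised per cell to RPKM::

    rpkm(c, g) = count(c, g) * 1e9 / (total_counts(c) * length_bp(g))

i.e. reads per kilobase of transcript per million reads of that cell.
Finally, cells are gated on the hepatocyte marker albumin: only cells whose
gate-gene RPKM strictly exceeds a threshold (default 1, the same rule that
defines a positive cell in the screen) enter the analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .errors import AnalysisError

__all__ = ["qc_filter", "compute_rpkm", "gate_positive_cells"]


def _aligned_annotation(adata: AnnData, annotation: pd.DataFrame) -> pd.DataFrame:
    """Annotation rows in the matrix's gene order; error on missing genes."""
    ann = annotation.set_index("gene_id", drop=False)
    if ann.index.has_duplicates:
        dupes = ann.index[ann.index.duplicated()].unique().tolist()[:10]
        raise AnalysisError(f"duplicate gene_id in annotation: {dupes}")
    missing = [g for g in adata.var_names if g not in ann.index]
    if missing:
        shown = missing[:10]
        more = "" if len(missing) <= 10 else f" (and {len(missing) - 10} more)"
        raise AnalysisError(f"genes absent from annotation: {shown}{more}")
    out = ann.loc[list(adata.var_names)]
    out.index.name = None
    return out


def qc_filter(
    counts: AnnData,
    annotation: pd.DataFrame,
    min_genes: int = 200,
    max_mito: float = 0.20,
) -> tuple[AnnData, pd.DataFrame]:
    """Drop low-complexity and high-mitochondrial cells.

    Parameters
    ----------
    counts
        Cells x genes sparse integer matrix.
    annotation
        Gene annotation with ``gene_id`` and ``is_mitochondrial`` columns
        covering every gene in ``counts``.
    min_genes
        Minimum number of detected genes (count > 0); cells with strictly
        fewer are excluded.
    max_mito
        Maximum mitochondrial fraction of total counts; cells strictly above
        are excluded.

    Returns
    -------
    kept, report
        The filtered matrix (gene universe unchanged) and a per-cell report
        with columns ``genes_detected``, ``mito_fraction``, ``passed`` and
        ``reason`` (one of ``none``, ``low_genes``, ``high_mito``, ``both``)
        covering every input cell.
    """
    if counts.n_obs == 0 or counts.n_vars == 0:
        raise AnalysisError("empty count matrix: nothing to QC")
    ann = _aligned_annotation(counts, annotation)

    X = sparse.csr_matrix(counts.X)
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = ann["is_mitochondrial"].to_numpy(dtype=bool)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)

    low = genes_detected < min_genes
    high = mito_fraction > max_mito
    passed = ~low & ~high
    reason = np.where(
        low & high, "both", np.where(low, "low_genes", np.where(high, "high_mito", "none"))
    )
    report = pd.DataFrame(
        {
            "cell_id": list(counts.obs_names),
            "genes_detected": genes_detected.astype(np.int64),
            "mito_fraction": mito_fraction,
            "passed": passed,
            "reason": reason,
        }
    )
    kept = counts[passed].copy()
    return kept, report


def compute_rpkm(counts: AnnData, annotation: pd.DataFrame) -> AnnData:
    """Per-cell RPKM from raw counts and transcript lengths.

    The sparsity pattern is preserved: a zero count maps to a zero RPKM.
    Cells with zero total counts cannot be normalised (run QC first) and
    raise :class:`~agescreen.errors.AnalysisError` naming the offenders.
    """
    ann = _aligned_annotation(counts, annotation)
    lengths = ann["length_bp"].to_numpy(dtype=np.float64)
    if np.any(lengths <= 0):
        bad = ann.loc[lengths <= 0, "gene_id"].tolist()[:10]
        raise AnalysisError(f"non-positive transcript lengths for genes: {bad}")

    X = sparse.csr_matrix(counts.X).astype(np.float64)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total == 0):
        bad = [c for c, t in zip(counts.obs_names, total) if t == 0][:10]
        raise AnalysisError(f"cells with zero total counts (QC first): {bad}")

    rpkm = (
        sparse.diags(1e9 / total) @ X @ sparse.diags(1.0 / lengths)
    ).tocsr()
    out = AnnData(X=rpkm, obs=counts.obs.copy(), var=ann.copy())
    out.uns = dict(counts.uns)
    out.uns["normalisation"] = "RPKM"
    return out


def gate_positive_cells(
    expr: AnnData, gate_symbol: str = "Alb", threshold_rpkm: float = 1.0
) -> list[str]:
    """Cells whose gate-gene RPKM strictly exceeds ``threshold_rpkm``.

    The gate symbol must resolve to exactly one gene in ``expr.var``; input
    cell order is preserved in the returned ids.
    """
    if "symbol" not in expr.var.columns:
        raise AnalysisError("expression matrix lacks a 'symbol' column in var")
    hits = np.flatnonzero(expr.var["symbol"].to_numpy() == gate_symbol)
    if hits.size == 0:
        raise AnalysisError(f"gate symbol {gate_symbol!r} not found")
    if hits.size > 1:
        ids = expr.var_names[hits].tolist()
        raise AnalysisError(f"gate symbol {gate_symbol!r} is ambiguous: {ids}")
    col = np.asarray(sparse.csr_matrix(expr.X)[:, hits[0]].todense()).ravel()
    keep = col > threshold_rpkm
    return [c for c, k in zip(expr.obs_names, keep) if k]
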