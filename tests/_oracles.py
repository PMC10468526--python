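"""Independent brute-force reference implementations.

Everything here works on dense arrays with explicit Python loops and
closed-form formulas, deliberately sharing no code with the package, so the
vectorised sparse implementations can be checked against a second route.
"""

from __future__ import annotations

import math

import numpy as np


def qc_oracle(dense, mito_flags, min_genes, max_mito):
    """Per-cell keep decision by looping over a dense count matrix."""
    keep = []
    for c in range(dense.shape[0]):
        detected = sum(1 for g in range(dense.shape[1]) if dense[c, g] > 0)
        total = sum(dense[c, g] for g in range(dense.shape[1]))
        mito = sum(dense[c, g] for g in range(dense.shape[1]) if mito_flags[g])
        frac = mito / total if total > 0 else 0.0
        keep.append(detected >= min_genes and frac <= max_mito)
    return np.array(keep)


def rpkm_oracle(dense, lengths):
    """Elementwise RPKM by the direct formula."""
    out = np.zeros(dense.shape, dtype=float)
    for c in range(dense.shape[0]):
        total = dense[c].sum()
        for g in range(dense.shape[1]):
            out[c, g] = dense[c, g] * 1e9 / (total * lengths[g])
    return out


def calls_oracle(rpkm_dense, threshold):
    return (rpkm_dense > threshold).astype(int)


def rates_oracle(calls_dense, groups):
    """{(gene_index, group): (n_positive, n_cells, rate)} by double loop."""
    out = {}
    for group in sorted(set(groups)):
        members = [c for c, g in enumerate(groups) if g == group]
        for gene in range(calls_dense.shape[1]):
            n_pos = sum(calls_dense[c, gene] for c in members)
            out[(gene, group)] = (n_pos, len(members), n_pos / len(members))
    return out


def ranking_oracle(gene_ids, rate_young, rate_old):
    """Gene ids sorted on (-delta, gene_id)."""
    delta = {g: rate_old[g] - rate_young[g] for g in gene_ids}
    return sorted(gene_ids, key=lambda g: (-delta[g], g))


def pearson_oracle(x, y):
    """Closed-form Pearson coefficient; NaN when either vector is constant."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)
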