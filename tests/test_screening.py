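"""Tests of positive calls, rates, the difference ranking, and candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from agescreen import (
    AnalysisError,
    ConfigurationError,
    call_positive,
    positive_rates,
    rank_by_rate_difference,
    select_candidates,
)

from conftest import make_annotation, make_counts
from _oracles import calls_oracle, ranking_oracle, rates_oracle


def expr_from(dense, annotation=None):
    """Treat a dense float array directly as an RPKM matrix."""
    adata = make_counts(np.zeros_like(dense, dtype=int), annotation)
    adata.X = sparse.csr_matrix(np.asarray(dense, dtype=float))
    return adata


class TestCallPositive:
    def test_strict_boundary(self):
        expr = expr_from([[1.0, 1.0001, 0.9999, 0.0]])
        calls = call_positive(expr, threshold_rpkm=1.0)
        dense = np.asarray(sparse.csr_matrix(calls.X).todense())
        assert dense.tolist() == [[0, 1, 0, 0]]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            call_positive(expr_from([[1.0]]), threshold_rpkm=-0.5)

    def test_matches_dense_oracle(self, rng):
        for _ in range(10):
            dense = rng.uniform(0, 3, size=(25, 30)) * (rng.random((25, 30)) < 0.5)
            thr = float(rng.uniform(0.2, 2.0))
            calls = call_positive(expr_from(dense), threshold_rpkm=thr)
            got = np.asarray(sparse.csr_matrix(calls.X).todense())
            assert (got == calls_oracle(dense, thr)).all()

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(0, 5, allow_nan=False), min_size=8, max_size=8),
        st.floats(0.1, 2.0),
        st.floats(0.0, 2.0),
    )
    def test_raising_threshold_never_adds_calls(self, values, thr, bump):
        """Monotonicity: a higher threshold can only lose positive calls."""
        dense = np.asarray(values).reshape(2, 4)
        low = np.asarray(sparse.csr_matrix(call_positive(expr_from(dense), thr).X).todense())
        high = np.asarray(
            sparse.csr_matrix(call_positive(expr_from(dense), thr + bump).X).todense()
        )
        assert (high <= low).all()


class TestPositiveRates:
    def test_forced_ratios(self):
        dense = np.array([[2.0], [2.0], [2.0], [0.5]])
        calls = call_positive(expr_from(dense))
        groups = pd.Series(["old"] * 4, index=calls.obs_names)
        rates = positive_rates(calls, groups)
        assert rates.loc[0, "rate"] == 0.75
        zero = positive_rates(
            call_positive(expr_from(np.zeros((4, 1)))), groups
        )
        assert zero.loc[0, "rate"] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        dense = rng.uniform(0, 3, size=(40, 25)) * (rng.random((40, 25)) < 0.5)
        calls = call_positive(expr_from(dense))
        labels = rng.choice(["young", "old"], size=40)
        groups = pd.Series(labels, index=calls.obs_names)
        rates = positive_rates(calls, groups)
        expected = rates_oracle(calls_oracle(dense, 1.0), labels.tolist())
        gene_index = {g: i for i, g in enumerate(calls.var_names)}
        for _, row in rates.iterrows():
            n_pos, n_cells, rate = expected[(gene_index[row["gene_id"]], row["group"])]
            assert row["n_positive"] == n_pos
            assert row["n_cells"] == n_cells
            assert row["rate"] == rate

    def test_conservation_sum_of_positives(self, rng):
        """Per group, sum over genes of n_positive equals the total call count."""
        dense = rng.uniform(0, 3, size=(30, 20)) * (rng.random((30, 20)) < 0.5)
        calls = call_positive(expr_from(dense))
        labels = np.array(["young"] * 15 + ["old"] * 15)
        rates = positive_rates(calls, pd.Series(labels, index=calls.obs_names))
        X = np.asarray(sparse.csr_matrix(calls.X).todense())
        for group in ("young", "old"):
            total = X[labels == group].sum()
            assert rates.loc[rates["group"] == group, "n_positive"].sum() == total

    def test_unassigned_cell_rejected(self):
        calls = call_positive(expr_from(np.ones((3, 2))))
        groups = pd.Series(["young", "old"], index=list(calls.obs_names)[:2])
        with pytest.raises(AnalysisError):
            positive_rates(calls, groups)


class TestRanking:
    def test_forced_ordering_and_ties(self):
        rates = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "a", "b", "c"],
                "group": ["young"] * 3 + ["old"] * 3,
                "n_positive": [1, 2, 3, 5, 3, 4],
                "n_cells": [8] * 6,
                "rate": [0.125, 0.25, 0.375, 0.625, 0.375, 0.5],
            }
        )
        ranking = rank_by_rate_difference(rates)
        # deltas: a=0.5, b=0.125, c=0.125 -> exact tie broken by gene_id
        assert ranking["gene_id"].tolist() == ["a", "b", "c"]
        assert ranking["rank"].tolist() == [1, 2, 3]

    def test_gene_missing_from_one_group_gets_rate_zero(self):
        rates = pd.DataFrame(
            {
                "gene_id": ["a", "a", "b"],
                "group": ["young", "old", "old"],
                "n_positive": [1, 5, 9],
                "n_cells": [10, 10, 10],
                "rate": [0.1, 0.5, 0.9],
            }
        )
        ranking = rank_by_rate_difference(rates).set_index("gene_id")
        assert ranking.loc["b", "rate_young"] == 0.0
        assert ranking.loc["b", "delta"] == 0.9
        assert ranking.loc["b", "rank"] == 1

    def test_missing_group_rejected(self):
        rates = pd.DataFrame(
            {"gene_id": ["a"], "group": ["old"], "n_positive": [1], "n_cells": [2],
             "rate": [0.5]}
        )
        with pytest.raises(AnalysisError):
            rank_by_rate_difference(rates)

    def test_matches_sort_oracle_on_many_random_genes(self, rng):
        n = 500
        gene_ids = [f"g{i:04d}" for i in range(n)]
        ry = dict(zip(gene_ids, rng.integers(0, 11, n) / 10))
        ro = dict(zip(gene_ids, rng.integers(0, 11, n) / 10))
        rates = pd.DataFrame(
            {
                "gene_id": gene_ids * 2,
                "group": ["young"] * n + ["old"] * n,
                "n_positive": [int(ry[g] * 10) for g in gene_ids]
                + [int(ro[g] * 10) for g in gene_ids],
                "n_cells": [10] * (2 * n),
                "rate": [ry[g] for g in gene_ids] + [ro[g] for g in gene_ids],
            }
        )
        ranking = rank_by_rate_difference(rates)
        assert ranking["gene_id"].tolist() == ranking_oracle(gene_ids, ry, ro)
        assert ranking["rank"].tolist() == list(range(1, n + 1))
        assert ranking["delta"].is_monotonic_decreasing


class TestSelectCandidates:
    @staticmethod
    def _ranking(n=10):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i + 1:05d}" for i in range(n)],
                "rate_young": 0.0,
                "rate_old": np.linspace(1, 0.1, n),
                "delta": np.linspace(1, 0.1, n),
                "rank": range(1, n + 1),
            }
        )

    def test_ortholog_filter_applied_before_truncation(self):
        ranking = self._ranking(10)
        orthologs = [None] + [f"G{i + 1}" for i in range(1, 10)]
        ann = make_annotation(10, orthologs=orthologs)
        cand = select_candidates(ranking, ann, top_k=5, require_ortholog=True)
        # rank-1 gene lacks an ortholog: dropped, ranks 2..6 returned
        assert cand["rank"].tolist() == [2, 3, 4, 5, 6]

    def test_no_filter_takes_plain_head(self):
        ranking = self._ranking(10)
        ann = make_annotation(10, orthologs=[None] * 10)
        cand = select_candidates(ranking, ann, top_k=4, require_ortholog=False)
        assert cand["rank"].tolist() == [1, 2, 3, 4]

    def test_short_list_when_fewer_genes_than_k(self):
        ranking = self._ranking(3)
        ann = make_annotation(3)
        assert len(select_candidates(ranking, ann, top_k=43)) == 3

    def test_top_k_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            select_candidates(self._ranking(3), make_annotation(3), top_k=0)


def test_label_permutation_null_concentrates_near_zero():
    """Shuffled group labels leave no gene with a large rate difference."""
    from agescreen import SimulationConfig, generate_annotation, simulate_counts

    cfg = SimulationConfig(
        n_cells_young=500, n_cells_old=500, n_genes=500, n_mito_genes=8, seed=13
    )
    ann = generate_annotation(cfg)
    adata, truth = simulate_counts(cfg, ann)
    from agescreen import compute_rpkm

    expr = compute_rpkm(adata, ann)
    calls = call_positive(expr)
    rng = np.random.default_rng(99)
    labels = np.array(["young"] * 500 + ["old"] * 500)
    rng.shuffle(labels)
    rates = positive_rates(calls, pd.Series(labels, index=calls.obs_names))
    ranking = rank_by_rate_difference(rates)
    non_marker = ~ranking["gene_id"].isin(truth.marker_gene_ids)
    assert ranking.loc[non_marker, "delta"].abs().max() < 0.15
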