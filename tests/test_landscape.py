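"""Enrichment-sweep core: grids, hypergeometric tails, term/gene selection."""

import numpy as np
import pytest

import gosweep as gs
from gosweep.landscape import (
    EmptyLandscapeError,
    EmptyUniverseError,
    TermSummary,
    UnknownTermError,
)
from conftest import hypergeom_tail_bruteforce


def _ann(term_sets):
    return gs.AnnotationMap.from_term_sets(
        {t: frozenset(gs_) for t, gs_ in term_sets.items()}
    )


class TestStepGrid:
    def test_arithmetic_grid(self):
        grid = gs.build_step_grid(np.full(100, 0.01), step_size=25)
        assert grid.steps == (25, 50, 75, 100)

    def test_endpoint_only_when_short(self):
        grid = gs.build_step_grid(np.full(10, 0.01), step_size=25)
        assert grid.steps == (10,)

    def test_endpoint_appended(self):
        grid = gs.build_step_grid(np.full(103, 0.01), step_size=25)
        assert grid.steps == (25, 50, 75, 100, 103)

    def test_max_alpha_truncates_sweep(self):
        p = np.concatenate([np.full(40, 0.01), np.full(60, 0.9)])
        grid = gs.build_step_grid(p, step_size=25, max_alpha=0.5)
        assert grid.steps == (25, 40)

    def test_empty_universe_rejected(self):
        with pytest.raises(EmptyUniverseError):
            gs.build_step_grid(np.array([]))

    def test_grid_invariants_enforced(self):
        with pytest.raises(ValueError):
            gs.StepGrid((10, 10))
        with pytest.raises(ValueError):
            gs.StepGrid(())


class TestContingency:
    RANKED = [f"g{i}" for i in range(10)]

    def test_counts_for_term_at_top(self):
        ann = _ann({"T": ["g0", "g1", "g2"]})
        c = gs.contingency(3, "T", ann, self.RANKED)
        assert (c.N, c.K, c.n, c.k) == (10, 3, 3, 3)

    def test_term_outside_selection(self):
        ann = _ann({"T": ["g7", "g8", "g9"]})
        assert gs.contingency(3, "T", ann, self.RANKED).k == 0

    def test_term_inside_selection_k_equals_K(self):
        ann = _ann({"T": ["g1", "g3"]})
        c = gs.contingency(5, "T", ann, self.RANKED)
        assert c.k == c.K == 2

    def test_unknown_term(self):
        with pytest.raises(UnknownTermError):
            gs.contingency(3, "missing", _ann({"T": ["g0"]}), self.RANKED)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            gs.ContingencyCounts(N=10, K=12, n=3, k=1)
        with pytest.raises(ValueError):
            gs.ContingencyCounts(N=10, K=3, n=3, k=4)


class TestHypergeomTail:
    def test_k_zero_is_one(self):
        assert gs.hypergeom_tail(gs.ContingencyCounts(N=20, K=5, n=5, k=0)) == 1.0

    def test_known_exact_value(self):
        # sum_{i=3..5} C(5,i) C(15,5-i) / C(20,5) = 1126/15504
        p = gs.hypergeom_tail(gs.ContingencyCounts(N=20, K=5, n=5, k=3))
        assert p == pytest.approx(1126 / 15504, abs=1e-12)

    def test_all_small_configurations_match_bruteforce(self):
        """Exhaustive agreement with exact-fraction enumeration, N <= 12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, n + K - N), min(n, K)
                    for k in range(lo, hi + 1):
                        got = gs.hypergeom_tail(gs.ContingencyCounts(N=N, K=K, n=n, k=k))
                        want = hypergeom_tail_bruteforce(N, K, n, k)
                        assert got == pytest.approx(want, abs=1e-12), (N, K, n, k)

    def test_extreme_tail_no_underflow(self):
        p = gs.hypergeom_tail(gs.ContingencyCounts(N=20_000, K=100, n=100, k=90))
        assert 0 < p < 1e-100


class TestComputeLandscape:
    def test_single_term_fully_ranked_first(self):
        # all 10 genes annotated (universe 10) but only T is eligible:
        # the others sit in singleton terms below min_term_size
        ranked = [f"g{i}" for i in range(10)]
        term_sets = {"T": ["g0", "g1", "g2"]}
        term_sets.update({f"tiny{i}": [f"g{i}"] for i in range(3, 10)})
        ann = _ann(term_sets)
        land = gs.compute_landscape(ranked, ann, grid=gs.StepGrid((3,)), min_term_size=3)
        assert land.terms == ("T",)
        assert land.universe_size == 10
        assert land.raw_p[0, 0] == pytest.approx(1 / 120, abs=1e-12)
        assert land.adj_p[0, 0] == land.raw_p[0, 0]  # single term: BH no-op

    def test_never_selected_terms_give_p_one(self):
        # universe must exceed the selection for k=0 to be possible
        ranked = [f"g{i}" for i in range(10)]
        ann = _ann({"T": ["g7", "g8", "g9"], "U": ["g0", "g4", "g5", "g6"]})
        land = gs.compute_landscape(ranked, ann, grid=gs.StepGrid((2,)), min_term_size=3)
        i = land.terms.index("T")
        assert land.raw_p[i, 0] == 1.0

    def test_adjusted_columns_equal_bh_of_raw(self, default_experiment, default_de_table):
        _, ann, _, _ = default_experiment
        de = default_de_table
        land = gs.compute_landscape(
            de["gene"].tolist(), ann, ranked_p=de["p"].to_numpy()
        )
        for j in range(len(land.grid)):
            np.testing.assert_allclose(
                land.adj_p[:, j], gs.bh_adjust(land.raw_p[:, j]), atol=1e-15
            )

    def test_min_term_size_excludes_small_terms(self):
        ranked = [f"g{i}" for i in range(10)]
        ann = _ann({"small": ["g0", "g1"], "ok": ["g2", "g3", "g4"]})
        land = gs.compute_landscape(ranked, ann, grid=gs.StepGrid((5,)), min_term_size=3)
        assert land.terms == ("ok",)

    def test_no_eligible_terms_is_error(self):
        ranked = [f"g{i}" for i in range(10)]
        ann = _ann({"small": ["g0", "g1"]})
        with pytest.raises(EmptyLandscapeError):
            gs.compute_landscape(ranked, ann, grid=gs.StepGrid((2,)), min_term_size=3)

    def test_unannotated_ranking_is_error(self):
        ann = _ann({"T": ["x1", "x2", "x3"]})
        with pytest.raises(EmptyUniverseError):
            gs.compute_landscape(["g0", "g1"], ann, grid=gs.StepGrid((1,)))

    def test_gene_relabeling_changes_no_pvalue(self, default_experiment, default_de_table):
        """Permutation invariance: ids are opaque to the statistics."""
        _, ann, _, _ = default_experiment
        de = default_de_table.head(500)
        ranked = de["gene"].tolist()
        grid = gs.StepGrid((25, 100, 250))
        land1 = gs.compute_landscape(ranked, ann, grid=grid)
        relabel = {g: f"X{i}" for i, g in enumerate(sorted(set(ranked) | ann.genes))}
        ann2 = gs.AnnotationMap.from_term_sets(
            {t: frozenset(relabel[g] for g in ann.genes_of(t)) for t in ann.terms}
        )
        land2 = gs.compute_landscape([relabel[g] for g in ranked], ann2, grid=grid)
        np.testing.assert_array_equal(land1.raw_p, land2.raw_p)


class TestTermScoring:
    def _landscape(self, terms, adj_rows, steps, raw_rows=None):
        adj = np.asarray(adj_rows, float)
        raw = np.asarray(raw_rows, float) if raw_rows is not None else adj.copy()
        return gs.LandscapeMatrix(
            terms=tuple(terms),
            grid=gs.StepGrid(tuple(steps)),
            raw_p=raw,
            adj_p=adj,
            universe_size=100,
            term_sizes={t: 10 for t in terms},
            overlaps=np.ones_like(adj, dtype=int),
        )

    def test_row_minimum_and_step(self):
        land = self._landscape(["T"], [[0.2, 0.05, 0.01]], [10, 20, 30])
        (s,) = gs.score_terms(land)
        assert (s.best_adj_p, s.best_step) == (0.01, 30)

    def test_ties_resolve_to_smallest_step(self):
        land = self._landscape(["T"], [[0.5, 0.01, 0.01]], [10, 20, 30])
        (s,) = gs.score_terms(land)
        assert s.best_step == 20

    def test_constant_row_one(self):
        land = self._landscape(["T"], [[1.0, 1.0]], [10, 20])
        (s,) = gs.score_terms(land)
        assert (s.best_adj_p, s.best_step) == (1.0, 10)

    def test_select_top_terms_ordering(self):
        summaries = [
            TermSummary("t1", 0.3, 10, 1.0, 5),
            TermSummary("t2", 0.001, 10, 1.0, 5),
            TermSummary("t3", 0.02, 10, 1.0, 5),
        ]
        top = gs.select_top_terms(summaries, 2)
        assert [s.term for s in top] == ["t2", "t3"]

    def test_select_top_terms_gives_all_when_topt_large(self):
        summaries = [TermSummary(f"t{i}", 0.1 * i, 10, 1.0, 5) for i in range(3, 0, -1)]
        top = gs.select_top_terms(summaries, 10)
        assert [s.term for s in top] == ["t1", "t2", "t3"]

    def test_full_tie_lexicographic(self):
        summaries = [TermSummary("zz", 0.01, 10, 1.0, 5), TermSummary("aa", 0.01, 10, 1.0, 5)]
        assert [s.term for s in gs.select_top_terms(summaries, 2)] == ["aa", "zz"]


class TestGeneRepresentation:
    def test_membership_counts_and_order(self):
        ann = _ann(
            {
                "t1": ["gA", "gB"],
                "t2": ["gA", "gC"],
                "t3": ["gA", "gB"],
            }
        )
        selected = [TermSummary(t, 0.01, 10, 1.0, 2) for t in ["t1", "t2", "t3"]]
        ranked = ["gC", "gA", "gB", "gD"]
        reps = gs.gene_representation(selected, ann, ranked)
        assert [(r.gene, r.n_selected_terms) for r in reps] == [
            ("gA", 3), ("gB", 2), ("gC", 1),
        ]
        # gD annotated nowhere: absent
        assert all(r.gene != "gD" for r in reps)

    def test_count_tie_broken_by_de_rank(self):
        ann = _ann({"t1": ["early", "late"], "t2": ["early", "late"]})
        selected = [TermSummary(t, 0.01, 10, 1.0, 2) for t in ["t1", "t2"]]
        ranked = ["x1", "x2", "x3", "early", "x4", "x5", "x6", "x7", "late"]
        reps = gs.gene_representation(selected, ann, ranked)
        assert [r.gene for r in reps] == ["early", "late"]
        assert [r.best_rank for r in reps] == [4, 9]


class TestHeatmapMatrix:
    def test_cells_are_neglog10_best_p_where_annotated(self):
        ann = _ann({"T": ["gA"], "U": ["gB"]})
        terms = [TermSummary("T", 0.01, 10, 1.0, 1), TermSummary("U", 1.0, 10, 1.0, 1)]
        genes = [
            gs.landscape.GeneRepresentation("gA", 1, 1),
            gs.landscape.GeneRepresentation("gB", 1, 2),
        ]
        mat = gs.heatmap_matrix(genes, terms, ann)
        assert mat[0, 0] == pytest.approx(2.0)  # -log10(0.01)
        assert mat[0, 1] == 0.0  # not annotated
        assert mat[1, 1] == 0.0  # p=1 -> weight 0
        assert mat.shape == (2, 2)
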