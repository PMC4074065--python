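import itertools
import math

import numpy as np
import pytest

from grnfidelity.evaluation import (
    curves,
    hypergeometric_significance,
    significance_vs_cutoff,
    to_undirected,
    topk_enrichment,
)


class TestToUndirected:
    def test_max_over_directions(self):
        out = to_undirected([("a", "b", 0.4), ("b", "a", 0.7)])
        assert out == {frozenset(("a", "b")): 0.7}

    def test_single_direction_unchanged(self):
        out = to_undirected([("a", "b", 0.4)])
        assert out[frozenset(("a", "b"))] == 0.4

    def test_never_more_pairs_than_edges(self):
        edges = [("a", "b", 1.0), ("b", "a", 0.5), ("a", "c", 0.2)]
        assert len(to_undirected(edges)) <= len(edges)


class TestCurves:
    def test_perfect_separation(self):
        genes = ["a", "b", "c", "d"]
        ref = {frozenset(("a", "b"))}
        scored = {frozenset(("a", "b")): 10.0,
                  frozenset(("a", "c")): 1.0}
        rep = curves(scored, ref, genes)
        assert rep.auroc == 1.0
        assert rep.aupr == pytest.approx(1.0)

    def test_random_scores_auroc_half(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(70)]       # 2415 pairs
        pairs = [frozenset(p) for p in itertools.combinations(genes, 2)]
        ref = set(rng.choice(len(pairs), 200, replace=False))
        ref = {pairs[i] for i in ref}
        scored = {p: float(rng.random()) for p in pairs}
        rep = curves(scored, ref, genes)
        # 3 SDs of the AUROC null (~sqrt(n_pos^-1 + n_neg^-1)/sqrt(12))
        assert abs(rep.auroc - 0.5) < 0.05

    def test_uncalled_pairs_form_trailing_tie_group(self):
        genes = ["a", "b", "c"]
        ref = {frozenset(("b", "c"))}
        scored = {frozenset(("a", "b")): 1.0}
        rep = curves(scored, ref, genes)
        assert rep.auroc < 0.5                     # positive is uncalled

    def test_baseline_precision_is_reference_density(self):
        genes = [f"g{i}" for i in range(10)]
        pairs = [frozenset(p) for p in itertools.combinations(genes, 2)]
        ref = set(pairs[:9])
        scored = {p: 1.0 for p in pairs}
        rep = curves(scored, ref, genes)
        assert rep.baseline_precision == pytest.approx(9 / 45)

    def test_no_positive_fatal(self):
        with pytest.raises(ValueError):
            curves({frozenset(("a", "b")): 1.0}, set(), ["a", "b", "c"])


class TestHypergeometric:
    def _enumeration_oracle(self, N, K, n):
        """Exhaustive draw enumeration; returns upper-tail P(X >= x) per x."""
        pop = list(range(N))
        ref = set(range(K))
        counts = [0] * (min(n, K) + 1)
        total = 0
        for draw in itertools.combinations(pop, n):
            counts[len(ref & set(draw))] += 1
            total += 1
        tail = [0.0] * (len(counts) + 1)
        for x in range(len(counts) - 1, -1, -1):
            tail[x] = tail[x + 1] + counts[x] / total
        return tail[:-1]

    def test_matches_enumeration_small_instances(self):
        for N in range(2, 9):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    tail = self._enumeration_oracle(N, K, n)
                    for x in range(1, min(n, K) + 1):
                        p = hypergeometric_significance(N, K, n, x)
                        assert p == pytest.approx(tail[x], abs=1e-10)

    def test_example_instance_n10(self):
        tail = self._enumeration_oracle(10, 4, 5)
        assert hypergeometric_significance(10, 4, 5, 4) == \
            pytest.approx(tail[4], abs=1e-12)

    def test_zero_hits_is_one(self):
        assert hypergeometric_significance(20, 5, 4, 0) == 1.0

    def test_full_draw_saturates(self):
        assert hypergeometric_significance(8, 3, 8, 3) == pytest.approx(1.0)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_significance(10, 4, 5, 6)


class TestTopK:
    def _scored(self):
        return {frozenset((f"a{i}", f"b{i}")): 1.0 - i / 10 for i in range(8)}

    def test_reference_superset_gives_one(self):
        scored = self._scored()
        assert topk_enrichment(scored, set(scored), [3])[3] == 1.0

    def test_top1_hit(self):
        scored = self._scored()
        ref = {frozenset(("a0", "b0"))}
        out = topk_enrichment(scored, ref, [1, 4])
        assert out[1] == 1.0 and out[4] == 0.25

    def test_tie_break_deterministic(self):
        scored = {frozenset(("a", "x")): 1.0, frozenset(("a", "y")): 1.0}
        ref = {frozenset(("a", "x"))}
        # lexicographic pair order puts (a, x) first at equal score
        assert topk_enrichment(scored, ref, [1])[1] == 1.0

    def test_k_beyond_population_rejected(self):
        with pytest.raises(ValueError):
            topk_enrichment(self._scored(), set(), [99])


class TestSignificanceVsCutoff:
    def test_retained_counts_non_increasing(self, scored_records):
        scored = to_undirected([(r.source, r.target, r.z_w)
                                for r in scored_records])
        genes = sorted({g for r in scored_records
                        for g in (r.source, r.target)})
        ref = set(list(scored)[:5])
        res = significance_vs_cutoff(scored, ref, [-10, 0, 1, 2, 10], genes)
        called = [r.called for r in res]
        assert called == sorted(called, reverse=True)

    def test_pure_true_positive_network_is_significant(self):
        genes = [f"g{i}" for i in range(12)]
        pairs = [frozenset(p) for p in itertools.combinations(genes, 2)]
        ref = set(pairs[:6])
        scored = {p: (5.0 if p in ref else -5.0) for p in pairs}
        res = significance_vs_cutoff(scored, ref, [0.0], genes)
        assert res[0].p_value < 1e-6
        assert res[0].hits == 6

    def test_empty_retained_set_reports_one(self):
        res = significance_vs_cutoff({}, {frozenset(("a", "b"))}, [0.0],
                                     ["a", "b", "c"])
        assert res[0].p_value == 1.0 and res[0].called == 0

    def test_calling_everything_not_significant(self):
        """A network calling nearly all pairs has high recall but no
        enrichment signal."""
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        pairs = [frozenset(p) for p in itertools.combinations(genes, 2)]
        ref = {pairs[i] for i in rng.choice(len(pairs), 15, replace=False)}
        scored = {p: 1.0 for p in pairs}          # call 100% of pairs
        res = significance_vs_cutoff(scored, ref, [0.0], genes)
        assert res[0].p_value > 0.05
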