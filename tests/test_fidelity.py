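import math

import numpy as np
import pytest

from grnfidelity.fidelity import (
    DegeneratePopulationError,
    FidelityRecord,
    fidelity,
    filter_network,
    optimize_weight,
    ranked_table,
    score_records,
    zscore_jaccard,
    zscore_log_confidence,
)


def _rec(src, tgt, conf, jac):
    return FidelityRecord(source=src, target=tgt, confidence=conf, jaccard=jac)


class TestZscoreLogConfidence:
    def test_two_point_arithmetic(self):
        c = 0.1
        recs = zscore_log_confidence([_rec("a", "b", c, 0),
                                      _rec("c", "d", c * math.e ** 2, 0)])
        assert recs[0].zc == pytest.approx(-1.0)
        assert recs[1].zc == pytest.approx(1.0)

    def test_population_normalized(self, scored_records):
        zc = np.array([r.zc for r in scored_records])
        assert zc.mean() == pytest.approx(0.0, abs=1e-9)
        assert zc.std() == pytest.approx(1.0, abs=1e-9)

    def test_equal_confidences_degenerate(self):
        recs = [_rec("a", "b", 0.5, 0)] * 3
        with pytest.raises(DegeneratePopulationError):
            zscore_log_confidence(recs)

    def test_zero_confidence_rejected(self):
        with pytest.raises(ValueError):
            zscore_log_confidence([_rec("a", "b", 0.0, 0)])


class TestZscoreJaccard:
    def test_sentinel_below_minimum(self):
        recs = zscore_jaccard([_rec("a", "b", 0.5, 0.2),
                               _rec("c", "d", 0.5, 0.8),
                               _rec("e", "f", 0.5, 0.0)])
        assert recs[0].zj == pytest.approx(-1.0)
        assert recs[1].zj == pytest.approx(1.0)
        assert recs[2].zj == pytest.approx(-2.0)   # min(zj) - 1

    def test_no_zero_jaccard_plain_zscores(self):
        recs = zscore_jaccard([_rec("a", "b", 0.5, 0.2),
                               _rec("c", "d", 0.5, 0.8)])
        assert sorted(r.zj for r in recs) == pytest.approx([-1.0, 1.0])

    def test_all_equal_nonzero_degenerate(self):
        recs = [_rec("a", "b", 0.5, 0.4), _rec("c", "d", 0.5, 0.4)]
        with pytest.raises(DegeneratePopulationError):
            zscore_jaccard(recs)

    def test_fewer_than_two_nonzero_disables_weight(self):
        with pytest.warns(UserWarning, match="disabled"):
            recs = zscore_jaccard([_rec("a", "b", 0.5, 0.0),
                                   _rec("c", "d", 0.5, 0.3)])
        assert all(r.zj == 0.0 for r in recs)


class TestFidelityScore:
    @pytest.fixture()
    def base(self):
        return zscore_jaccard(zscore_log_confidence([
            _rec("a", "b", 0.1, 0.2), _rec("c", "d", 0.5, 0.0),
            _rec("e", "f", 0.9, 0.9)]))

    def test_w_zero_equals_confidence_zscore(self, base):
        for r in fidelity(base, 0.0):
            assert r.z_w == r.zc

    def test_weighted_sum(self):
        recs = [FidelityRecord("a", "b", 0.5, 0.5, zc=2.0, zj=1.0)]
        assert fidelity(recs, 1.0)[0].z_w == 3.0

    def test_negative_weight_rejected(self, base):
        with pytest.raises(ValueError):
            fidelity(base, -0.1)

    def test_w0_ranking_invariant_to_jaccard_transform(self, base):
        ranked = [r.source for r in
                  sorted(fidelity(base, 0.0), key=lambda r: -r.z_w)]
        squashed = [FidelityRecord(r.source, r.target, r.confidence,
                                   r.jaccard ** 3) for r in base]
        base2 = zscore_jaccard(zscore_log_confidence(squashed))
        ranked2 = [r.source for r in
                   sorted(fidelity(base2, 0.0), key=lambda r: -r.z_w)]
        assert ranked == ranked2


class TestFilterNetwork:
    def test_boundaries(self, scored_records):
        assert len(filter_network(scored_records, -np.inf).edges) == \
            len(scored_records)
        top = max(r.z_w for r in scored_records)
        assert filter_network(scored_records, top + 1).edges == []

    def test_nested_filtration(self, scored_records):
        nets = [filter_network(scored_records, c) for c in (2.0, 2.5, 3.0)]
        for tighter, looser in zip(nets[1:], nets):
            assert set((r.source, r.target) for r in tighter.edges) <= \
                set((r.source, r.target) for r in looser.edges)

    def test_no_isolated_nodes(self, scored_records):
        net = filter_network(scored_records, 1.0)
        endpoint_genes = {g for r in net.edges for g in (r.source, r.target)}
        assert set(net.nodes) == endpoint_genes


class TestOptimizeWeight:
    def _population(self, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(60):
            conf = float(rng.uniform(0.01, 1.0))
            jac = float(rng.uniform(0, 1)) if rng.random() > 0.3 else 0.0
            recs.append(_rec(f"s{i}", f"t{i}", conf, jac))
        return recs

    def test_jaccard_correlated_reference_prefers_large_w(self):
        recs = self._population()
        reference = {frozenset((r.source, r.target))
                     for r in sorted(recs, key=lambda r: -r.jaccard)[:12]}
        assert optimize_weight(recs, reference) >= 2.0

    def test_confidence_correlated_reference_prefers_w0(self):
        recs = self._population(1)
        reference = {frozenset((r.source, r.target))
                     for r in sorted(recs, key=lambda r: -r.confidence)[:12]}
        assert optimize_weight(recs, reference) == 0.0

    def test_disjoint_reference_fatal(self):
        recs = self._population(2)
        with pytest.raises(ValueError, match="disjoint"):
            optimize_weight(recs, {frozenset(("x", "y"))})

    def test_empty_reference_fatal(self):
        with pytest.raises(ValueError):
            optimize_weight(self._population(), set())


def test_ranked_table_descending_and_complete(scored_records):
    df = ranked_table(scored_records)
    assert list(df.columns[:4]) == ["source", "target", "confidence",
                                    "jaccard"]
    assert (df["z_w"].to_numpy()[:-1] >= df["z_w"].to_numpy()[1:]).all()
    assert len(df) == len(scored_records)


def test_relabeling_preserves_ranking(scored_records):
    mapping = {g: f"X{g}" for r in scored_records
               for g in (r.source, r.target)}
    relabeled = [FidelityRecord(mapping[r.source], mapping[r.target],
                                r.confidence, r.jaccard)
                 for r in scored_records]
    orig = score_records([FidelityRecord(r.source, r.target, r.confidence,
                                         r.jaccard) for r in scored_records])
    new = score_records(relabeled)
    for a, b in zip(orig, new):
        assert a.z_w == pytest.approx(b.z_w)
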