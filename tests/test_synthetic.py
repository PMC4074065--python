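import numpy as np
import pytest

from grnfidelity.similarity import jaccard
from grnfidelity.synthetic import (
    depleted_preset,
    enriched_preset,
    make_annotations,
    make_dataset,
    make_reference,
    make_truth_network,
    simulate_timecourse,
    write_dataset,
)


class TestMakeTruthNetwork:
    def test_all_activation_when_fraction_one(self):
        t = make_truth_network(5, 1.0, activation_fraction=1.0, seed=0)
        assert all(sign == "activation" for _, _, sign in t.edges)

    def test_deterministic_for_seed(self):
        a = make_truth_network(30, 2.5, 0.7, seed=9)
        b = make_truth_network(30, 2.5, 0.7, seed=9)
        assert a.edges == b.edges and a.roots == b.roots

    def test_heavy_tailed_degrees(self):
        """max degree > 3x median for n=60, mean degree 3 (20 seeds)."""
        for seed in range(20):
            t = make_truth_network(60, 3.0, 0.7, seed=seed)
            deg: dict[str, int] = {}
            for a, b, _ in t.edges:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
            d = [deg.get(g, 0) for g in t.genes]
            assert max(d) > 3 * np.median(d)

    def test_no_self_edges_and_endpoints_in_genes(self):
        t = make_truth_network(40, 2.0, 0.7, seed=1)
        genes = set(t.genes)
        for a, b, _ in t.edges:
            assert a != b
            assert a in genes and b in genes

    def test_roots_have_no_regulators(self):
        t = make_truth_network(40, 2.0, 0.7, seed=2)
        for root in t.roots:
            assert t.regulators_of(root) == {}

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            make_truth_network(4, 1.0, 0.5, seed=0)


class TestSimulateTimecourse:
    def test_rows_scaled_to_unit_interval(self):
        t = make_truth_network(10, 2.0, 0.7, seed=3)
        m = simulate_timecourse(t, 9, 0.05, seed=3)
        v = m.values.to_numpy()
        np.testing.assert_allclose(v.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(v.max(axis=1), 1.0, atol=1e-12)

    def test_roots_high_nonroots_low_pre_noise(self):
        t = make_truth_network(10, 2.0, 0.7, seed=4)
        _noisy, clean = simulate_timecourse(t, 9, 0.0, seed=4,
                                            _return_noiseless=True)
        # roots decay from their start: scaled stage-0 value is maximal
        for root in t.roots:
            assert clean.profile(root)[0] == pytest.approx(1.0)
        for g in t.genes:
            if g not in t.roots:
                assert clean.profile(g)[0] <= 0.35

    def test_unregulated_gene_decays_monotonically(self):
        t = make_truth_network(6, 1.0, 1.0, seed=5)
        _noisy, clean = simulate_timecourse(t, 9, 0.0, seed=5,
                                            _return_noiseless=True)
        root = sorted(t.roots)[0]
        prof = clean.profile(root)
        assert np.all(np.diff(prof) <= 1e-9)

    def test_noise_residual_band(self):
        """Mean per-row residual SD vs the noiseless run stays in
        [0.02, 0.10] at noise_sd = 0.05 (Monte Carlo over seeds)."""
        res = []
        for seed in range(50):
            t = make_truth_network(8, 1.5, 0.7, seed=seed)
            noisy, clean = simulate_timecourse(t, 9, 0.05, seed=seed,
                                               _return_noiseless=True)
            r = noisy.values.to_numpy() - clean.values.to_numpy()
            res.append(float(r.std(axis=1).mean()))
        assert 0.02 <= np.mean(res) <= 0.10

    def test_too_few_stages_rejected(self):
        t = make_truth_network(6, 1.0, 0.7, seed=0)
        with pytest.raises(ValueError):
            simulate_timecourse(t, 2, 0.0, seed=0)


class TestMakeAnnotations:
    def _setup(self, seed=0):
        t = make_truth_network(30, 2.0, 0.7, seed=seed)
        clusters = [frozenset({g}) for g in t.genes]
        return t, clusters

    def test_share_prob_one_no_zero_target_all_overlap(self):
        t, clusters = self._setup()
        ann = make_annotations(t, clusters, share_prob=1.0,
                               zero_overlap_target=0.0, seed=1)
        for pair in t.undirected_edges():
            a, b = sorted(pair)
            assert jaccard(ann.terms(a), ann.terms(b)) > 0

    def test_share_prob_zero_disjoint_blocks_all_zero(self):
        t, clusters = self._setup()
        ann = make_annotations(t, clusters, share_prob=0.0,
                               zero_overlap_target=0.0, seed=1)
        for pair in t.undirected_edges():
            a, b = sorted(pair)
            assert jaccard(ann.terms(a), ann.terms(b)) == 0.0

    def test_zero_overlap_fraction_near_target(self):
        """Realized zero-overlap fraction within +-0.1 of the 0.37 target
        (about one third of true pairs, as in curated ontologies)."""
        fracs = []
        for seed in range(20):
            t, clusters = self._setup(seed)
            ann = make_annotations(t, clusters, share_prob=1.0,
                                   zero_overlap_target=0.37, seed=seed)
            zero = sum(
                1 for pair in t.undirected_edges()
                if jaccard(ann.terms(min(pair)), ann.terms(max(pair))) == 0)
            fracs.append(zero / len(t.undirected_edges()))
        assert 0.27 <= np.mean(fracs) <= 0.47

    def test_vocab_smaller_than_clusters_rejected(self):
        t, clusters = self._setup()
        with pytest.raises(ValueError):
            make_annotations(t, clusters, vocab_size=3, seed=0)


class TestMakeReference:
    def test_full_coverage_equals_undirected_truth(self):
        t = make_truth_network(20, 2.0, 0.7, seed=6)
        ref, n_true = make_reference(t, coverage=1.0, n_decoys=0, seed=0)
        assert ref == t.undirected_edges()
        assert n_true == len(ref)

    def test_zero_coverage_decoys_disjoint_from_truth(self):
        t = make_truth_network(20, 2.0, 0.7, seed=6)
        ref, n_true = make_reference(t, coverage=0.0, n_decoys=3, seed=0)
        assert len(ref) == 3 and n_true == 0
        assert not ref & t.undirected_edges()

    def test_bookkeeping_exact(self):
        t = make_truth_network(25, 2.0, 0.7, seed=7)
        ref, n_true = make_reference(t, coverage=0.6, n_decoys=12, seed=1)
        assert n_true == len(ref & t.undirected_edges())

    def test_too_many_decoys_rejected(self):
        t = make_truth_network(6, 4.0, 0.7, seed=0)
        with pytest.raises(ValueError):
            make_reference(t, 1.0, n_decoys=10_000, seed=0)

    def test_enriched_preset_reference_density(self):
        """50-gene enriched preset lands near 283 known interactions."""
        ds = enriched_preset(seed=0)
        assert 250 <= len(ds.reference_edges) <= 320

    def test_depleted_preset_sparse_reference(self):
        ds = depleted_preset(seed=0)
        assert len(ds.reference_edges) <= 8
        assert ds.reference_true_count == len(ds.reference_edges)


class TestMakeDataset:
    def test_byte_identical_for_seed(self, tmp_path):
        a = make_dataset(n_genes=10, n_modules=1, seed=5)
        b = make_dataset(n_genes=10, n_modules=1, seed=5)
        assert a.truth.edges == b.truth.edges
        assert a.expression.values.equals(b.expression.values)
        assert a.annotations == b.annotations
        assert a.reference_edges == b.reference_edges
        da, db = tmp_path / "a", tmp_path / "b"
        write_dataset(a, da)
        write_dataset(b, db)
        for name in ("expression.tsv", "annotations.tsv", "truth_edges.tsv",
                     "reference_edges.tsv", "dataset.json"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_planted_modules_highly_correlated(self):
        """Clones of a template stay at Pearson r > 0.95 for noise <= 0.05
        (checked over 10 seeds)."""
        for seed in range(10):
            ds = make_dataset(n_genes=10, n_modules=1, module_size=3,
                              noise_sd=0.05, seed=seed)
            module = next(c for c in ds.clusters if len(c) > 1)
            profs = [ds.expression.profile(g) for g in sorted(module)]
            for i in range(1, len(profs)):
                r = np.corrcoef(profs[0], profs[i])[0, 1]
                assert r > 0.95

    def test_expression_contains_clones_truth_does_not(self):
        ds = make_dataset(n_genes=10, n_modules=2, module_size=3, seed=2)
        assert ds.expression.n_genes == 10 + 2 * 2
        assert len(ds.truth.genes) == 10
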