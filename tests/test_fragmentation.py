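import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netcoherence import (
    Clustering,
    FixtureSpec,
    average_entropy,
    entropy_from_counts,
    entropy_permutation_null,
    fragmentation,
    make_fixture,
    propagate,
    qualifying_terms,
    rank_best,
    spl_reduction,
)
from netcoherence.fragmentation import FragmentationRecord
from netcoherence.network import EvidenceNetwork, EvidenceType
from netcoherence.ontology import build_dag
from netcoherence.synth import shuffle_annotations


def single_term_setup(split):
    """One term annotating sum(split) proteins, clustered per the split."""
    dag = build_dag([("T", "R")])
    proteins = [f"p{i}" for i in range(sum(split))]
    corpus = propagate({p: {"T"} for p in proteins}, dag)
    clusters, i = [], 0
    for size in split:
        clusters.append(set(proteins[i:i + size]))
        i += size
    return dag, corpus, Clustering.from_iterable(clusters)


class TestEntropy:
    def test_worked_example_16_1_1_1_1(self):
        """A 16/1/1/1/1 split of 20 proteins scores H = 0.338 in base 10."""
        dag, corpus, clustering = single_term_setup([16, 1, 1, 1, 1])
        record = fragmentation("T", clustering, corpus)
        assert record.n_fragments == 5
        assert round(record.entropy, 3) == 0.338

    def test_single_cluster_zero_entropy(self):
        dag, corpus, clustering = single_term_setup([20])
        record = fragmentation("T", clustering, corpus)
        assert record.n_fragments == 1
        assert record.entropy == 0.0

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_uniform_split_is_log10_k(self, k):
        dag, corpus, clustering = single_term_setup([2] * k)
        record = fragmentation("T", clustering, corpus)
        assert record.entropy == pytest.approx(math.log10(k))

    def test_fractions_sum_to_one_and_bounds(self):
        dag, corpus, clustering = single_term_setup([7, 5, 3, 1])
        record = fragmentation("T", clustering, corpus)
        assert sum(record.fractions.values()) == pytest.approx(1.0)
        assert 0.0 <= record.entropy <= math.log10(record.n_fragments) + 1e-12

    def test_unannotated_term_rejected(self):
        dag, corpus, clustering = single_term_setup([4])
        with pytest.raises(ValueError, match="annotates no protein"):
            fragmentation("R2", Clustering.from_iterable([{"zz"}]), corpus)

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=60)
    def test_zero_iff_single_fragment(self, counts):
        h = entropy_from_counts(counts)
        assert (h == 0.0) == (len(counts) == 1)
        assert h <= math.log10(len(counts)) + 1e-9

    @given(
        st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=12),
        st.data(),
    )
    @settings(deadline=None, max_examples=60)
    def test_merging_fragments_never_increases_entropy(self, counts, data):
        i = data.draw(st.integers(0, len(counts) - 2))
        merged = counts[:i] + [counts[i] + counts[i + 1]] + counts[i + 2:]
        assert entropy_from_counts(merged) <= entropy_from_counts(counts) + 1e-12


class TestAverageEntropy:
    def test_all_terms_in_one_cluster(self, small_fixture):
        clustering = Clustering.from_iterable([small_fixture.corpus.proteins])
        assert average_entropy(clustering, small_fixture.corpus, min_proteins=5) == 0.0

    def test_mean_of_zero_and_one(self):
        # two terms: one intact in a cluster (H=0), one split evenly over 10 (H=1)
        dag = build_dag([("T1", "R"), ("T2", "R")])
        direct = {f"a{i}": {"T1"} for i in range(10)}
        direct.update({f"b{i}": {"T2"} for i in range(10)})
        corpus = propagate(direct, dag)
        clusters = [{f"a{i}" for i in range(10)} | {f"b{0}"}]
        clusters += [{f"b{i}"} for i in range(1, 10)]
        clustering = Clustering.from_iterable(clusters)
        h1 = fragmentation("T1", clustering, corpus).entropy
        h2 = fragmentation("T2", clustering, corpus).entropy
        got = average_entropy(clustering, corpus, min_proteins=10)
        # qualifying terms: T1, T2 and the root R (all >= 10 proteins)
        h_root = fragmentation("R", clustering, corpus).entropy
        assert h1 == 0.0 and h2 == pytest.approx(1.0)
        assert got == pytest.approx((h1 + h2 + h_root) / 3)

    def test_matches_per_term_brute_force(self, small_fixture):
        clustering = small_fixture.truth
        corpus = small_fixture.corpus
        terms = qualifying_terms(clustering, corpus, min_proteins=5)
        expected = np.mean([
            fragmentation(t, clustering, corpus).entropy for t in terms
        ])
        assert average_entropy(clustering, corpus, min_proteins=5) == pytest.approx(expected)

    def test_no_qualifying_terms_rejected(self, small_fixture):
        with pytest.raises(ValueError, match="no term"):
            average_entropy(small_fixture.truth, small_fixture.corpus,
                            min_proteins=10_000)


class TestPermutationNull:
    def test_single_cluster_is_permutation_invariant(self, small_fixture):
        clustering = Clustering.from_iterable([small_fixture.corpus.proteins])
        s = entropy_permutation_null(
            clustering, small_fixture.corpus, n_perm=50, seed=1, min_proteins=5
        )
        assert s.actual_mean == 0.0
        assert s.permuted_mean == 0.0
        assert s.relative_decrease == 0.0
        assert s.p_value == pytest.approx(1.0)

    def test_structured_fixture_significant(self, small_fixture):
        s = entropy_permutation_null(
            small_fixture.truth, small_fixture.corpus,
            n_perm=1000, seed=3, min_proteins=5,
        )
        assert s.relative_decrease > 0
        assert s.p_value < 0.01
        # the identity holds as stated
        assert s.relative_decrease == pytest.approx(
            (s.permuted_mean - s.actual_mean) / s.permuted_mean * 100.0
        )

    def test_seed_reproducibility(self, small_fixture):
        kw = dict(n_perm=100, seed=9, min_proteins=5)
        a = entropy_permutation_null(small_fixture.truth, small_fixture.corpus, **kw)
        b = entropy_permutation_null(small_fixture.truth, small_fixture.corpus, **kw)
        assert a == b

    def test_null_fixture_relative_decrease_near_zero(self):
        """Incoherent annotations: decrease indistinguishable from 0 across seeds."""
        decreases = []
        for seed in range(20):
            fx = make_fixture(FixtureSpec(
                n_proteins=60, n_modules=4, annotation_coherence=0.0, seed=100 + seed,
            ))
            s = entropy_permutation_null(
                fx.truth, fx.corpus, n_perm=200, seed=seed, min_proteins=5,
            )
            decreases.append(s.relative_decrease)
        z = np.mean(decreases) / (np.std(decreases, ddof=1) / math.sqrt(len(decreases)))
        assert abs(z) < 3


class TestRankBest:
    @staticmethod
    def record(term, entropy, n_fragments):
        return FragmentationRecord(
            term=term, annotated_proteins=frozenset({"p"}),
            fragment_clusters=frozenset(range(n_fragments)),
            n_fragments=n_fragments,
            fractions={}, entropy=entropy,
        )

    def test_strictly_best_network_scores_100(self):
        nets = {
            "good": [self.record("T1", 0.1, 1), self.record("T2", 0.2, 2)],
            "bad": [self.record("T1", 0.5, 3), self.record("T2", 0.9, 4)],
        }
        summary = rank_best(nets)
        assert summary.bfrp == {"good": 100.0, "bad": 0.0}
        assert summary.berp == {"good": 100.0, "bad": 0.0}

    def test_full_tie_credits_both_networks(self):
        recs = [self.record("T1", 0.3, 2), self.record("T2", 0.0, 1)]
        summary = rank_best({"a": recs, "b": list(recs)})
        assert summary.bfrp == {"a": 100.0, "b": 100.0}
        assert summary.berp == {"a": 100.0, "b": 100.0}

    def test_missing_terms_dropped(self):
        nets = {
            "a": [self.record("T1", 0.1, 1), self.record("T2", 0.2, 2)],
            "b": [self.record("T1", 0.5, 3)],
        }
        summary = rank_best(nets)
        assert summary.n_terms_ranked == 1

    def test_matches_brute_force_argmin_on_random_networks(self):
        rng = np.random.default_rng(77)
        names = [f"net{i}" for i in range(5)]
        terms = [f"T{i}" for i in range(30)]
        table = {
            name: {
                t: (int(rng.integers(1, 6)), float(rng.choice([0.0, 0.25, 0.5, 0.75])))
                for t in terms
            }
            for name in names
        }
        nets = {
            name: [self.record(t, h, n) for t, (n, h) in vals.items()]
            for name, vals in table.items()
        }
        summary = rank_best(nets)
        for name in names:
            bf = 100.0 * sum(
                1 for t in terms
                if table[name][t][0] == min(table[m][t][0] for m in names)
            ) / len(terms)
            be = 100.0 * sum(
                1 for t in terms
                if table[name][t][1] == min(table[m][t][1] for m in names)
            ) / len(terms)
            assert summary.bfrp[name] == pytest.approx(bf)
            assert summary.berp[name] == pytest.approx(be)
            assert 0.0 <= summary.bfrp[name] <= 100.0


def two_clique_bridge_network():
    """Two 6-cliques joined by a single bridge edge."""
    net = EvidenceNetwork()
    left = [f"L{i}" for i in range(6)]
    right = [f"R{i}" for i in range(6)]
    for grp in (left, right):
        for i, a in enumerate(grp):
            for b in grp[i + 1:]:
                net.add_edge(a, b, {EvidenceType.PPI})
    net.add_edge(left[0], right[0], {EvidenceType.PPI})
    return net, left, right


class TestSplReduction:
    def test_annotated_everything_gives_no_reduction(self, small_fixture):
        dag = build_dag([("T", "R")])
        net, left, right = two_clique_bridge_network()
        corpus = propagate({p: {"T"} for p in list(net.nodes)}, dag)
        reduction, p = spl_reduction(net, "T", corpus, n_perm=50, seed=4)
        assert reduction == pytest.approx(0.0)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_planted_clique_annotation_concentrates(self):
        net, left, right = two_clique_bridge_network()
        dag = build_dag([("T", "R")])
        direct = {p: {"T"} for p in left}
        direct.update({p: {"R"} for p in right})
        corpus = propagate(direct, dag)
        reduction, p = spl_reduction(net, "T", corpus, n_perm=500, seed=5)
        # all annotated nodes inside one clique: observed SPL exactly 1
        assert reduction > 0
        assert p < 0.05

    def test_random_annotation_mean_reduction_near_zero(self):
        import networkx as nx
        from conftest import network_from_nx

        dag = build_dag([("T", "R")])
        reductions = []
        for seed in range(20):
            g = nx.gnp_random_graph(25, 0.15, seed=seed)
            net = network_from_nx(g)
            rng = np.random.default_rng(seed)
            chosen = rng.choice(sorted(net.nodes), size=6, replace=False)
            direct = {p: {"T"} for p in chosen}
            direct.update({p: {"R"} for p in net.nodes if p not in set(chosen)})
            corpus = propagate(direct, dag)
            try:
                reduction, _ = spl_reduction(net, "T", corpus, n_perm=200, seed=seed)
            except ValueError:
                continue
            reductions.append(reduction)
        assert abs(np.mean(reductions)) < 5.0

    def test_too_few_annotated_rejected(self):
        net, left, right = two_clique_bridge_network()
        dag = build_dag([("T", "R")])
        direct = {left[0]: {"T"}}
        direct.update({p: {"R"} for p in net.nodes if p != left[0]})
        corpus = propagate(direct, dag)
        with pytest.raises(ValueError, match="fewer than 2"):
            spl_reduction(net, "T", corpus, n_perm=10, seed=1)


class TestShuffledAnnotationsHelper:
    def test_shuffle_preserves_multiset(self, small_fixture):
        shuffled = shuffle_annotations(small_fixture.direct, seed=3)
        assert sorted(map(sorted, shuffled.values())) == \
            sorted(map(sorted, small_fixture.direct.values()))
        assert set(shuffled) == set(small_fixture.direct)
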