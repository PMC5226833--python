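import numpy as np
import pytest

from dcmm import cluster
from dcmm.model_select import Component


def make_component(label, rates, t_start=1, t_end=100, trace_id="tr"):
    rates = np.asarray(rates, dtype=float)
    return Component(
        trace_id=trace_id,
        t_start=t_start,
        t_end=t_end,
        label=label,
        rates=rates,
        counts=np.zeros_like(rates),
        n_transitions=10,
    )


def two_state_rates(k_lh, k_hl):
    return np.array([[1 - k_lh, k_lh], [k_hl, 1 - k_hl]])


def synthetic_arrow(before, after, rng=None, spread=0.0, n=1, trace_id="tr"):
    """Arrows with log-rate blocks centered at `before`/`after` (length d/2 each)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    out = []
    for i in range(n):
        vec = np.concatenate([before, after])
        if spread:
            vec = vec + rng.normal(0, spread, size=len(vec))
        out.append(
            cluster.KineticArrow(
                trace_id=trace_id,
                vector=vec,
                source_label=1,
                target_label=2,
                source_interval=(1, 2),
                target_interval=(2, 3),
            )
        )
    return out


class TestBuildArrows:
    def test_one_arrow_per_label_switch(self):
        comps = [
            make_component(1, two_state_rates(0.05, 0.05), 1, 100),
            make_component(2, two_state_rates(0.005, 0.01), 100, 200),
            make_component(1, two_state_rates(0.05, 0.05), 200, 300),
        ]
        arrows = cluster.build_arrows({"tr": comps})
        assert len(arrows) == 2
        assert (arrows[0].source_label, arrows[0].target_label) == (1, 2)
        # before block of the return arrow equals after block of the outgoing one
        np.testing.assert_allclose(arrows[1].vector[:2], arrows[0].vector[2:])

    def test_non_contiguous_components_skipped(self):
        comps = [
            make_component(1, two_state_rates(0.05, 0.05), 1, 100),
            make_component(2, two_state_rates(0.005, 0.01), 150, 250),
        ]
        assert cluster.build_arrows({"tr": comps}) == []

    def test_single_component_contributes_nothing(self):
        comps = [make_component(1, two_state_rates(0.05, 0.05))]
        assert cluster.build_arrows({"tr": comps}) == []

    def test_dimension_is_2n_nm1(self):
        # N = 4 observables -> 2 * 4 * 3 = 24
        r = np.full((4, 4), 0.02)
        np.fill_diagonal(r, 1 - 0.06)
        comps = [
            make_component(1, r, 1, 100),
            make_component(2, r * 0.99 + 0.0025 * np.eye(4), 100, 200),
        ]
        comps[1].rates /= comps[1].rates.sum(axis=1, keepdims=True)
        arrows = cluster.build_arrows({"tr": comps})
        assert arrows[0].dim == 24

    def test_mirror_is_an_involution_and_swaps_blocks(self, rng):
        v = rng.normal(size=8)
        np.testing.assert_array_equal(cluster.mirror(cluster.mirror(v)), v)
        np.testing.assert_array_equal(cluster.mirror(v)[:4], v[4:])


class TestKMeans:
    def test_recovers_well_separated_centers(self, rng):
        centers = rng.normal(scale=10.0, size=(6, 4))
        arrows = []
        truth = []
        for i, c in enumerate(centers):
            arrows += synthetic_arrow(c[:2], c[2:], rng=rng, spread=0.05, n=20)
            truth += [i] * 20
        labels, cents = cluster.kmeans_arrows(arrows, 6, n_init=50, seed=0)
        # same partition as construction (up to label names)
        mapping = {}
        for lab, t in zip(labels, truth):
            mapping.setdefault(t, lab)
            assert mapping[t] == lab
        assert len(set(mapping.values())) == 6

    def test_k_equals_n_arrows_gives_zero_inertia(self, rng):
        arrows = synthetic_arrow([0, 0], [1, 1], n=1) + synthetic_arrow(
            [5, 5], [6, 6], n=1
        )
        labels, cents = cluster.kmeans_arrows(arrows, 2, n_init=10, seed=0)
        X = np.array([a.vector for a in arrows])
        np.testing.assert_allclose(np.sort(cents, axis=0), np.sort(X, axis=0))

    def test_duplicate_arrows_collapse_to_one_centroid(self):
        arrows = synthetic_arrow([1, 2], [3, 4], n=10)
        labels, cents = cluster.kmeans_arrows(arrows, 1, n_init=5, seed=0)
        np.testing.assert_allclose(cents[0], [1, 2, 3, 4])

    def test_too_many_clusters_rejected(self):
        arrows = synthetic_arrow([0, 0], [1, 1], n=3)
        with pytest.raises(ValueError, match="exceed"):
            cluster.kmeans_arrows(arrows, 4)

    def test_cityblock_metric_supported(self, rng):
        arrows = synthetic_arrow([0, 0], [5, 5], rng=rng, spread=0.1, n=15) + \
            synthetic_arrow([5, 5], [0, 0], rng=rng, spread=0.1, n=15)
        labels, cents = cluster.kmeans_arrows(
            arrows, 2, n_init=20, seed=0, metric="cityblock"
        )
        assert len(np.unique(labels)) == 2


class TestPairing:
    def test_exact_mirror_pair_has_zero_distance(self):
        c = np.array([[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 1.0, 2.0]])
        S, D_c = cluster.pair_centroids(c)
        assert S == ((0, 1),)
        assert D_c == pytest.approx(0.0)

    def test_recovers_constructed_mirror_pairs(self, rng):
        a = rng.normal(scale=5, size=4)
        b = rng.normal(scale=5, size=4)
        cents = np.stack([
            a,
            b,
            cluster.mirror(a) + rng.normal(0, 0.01, 4),
            cluster.mirror(b) + rng.normal(0, 0.01, 4),
        ])
        S, _ = cluster.pair_centroids(cents)
        assert set(frozenset(p) for p in S) == {frozenset({0, 2}), frozenset({1, 3})}

    def test_odd_cluster_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            cluster.pair_centroids(np.zeros((3, 4)))

    def test_matching_enumeration_is_double_factorial(self):
        assert sum(1 for _ in cluster.perfect_matchings(range(6))) == 15
        assert sum(1 for _ in cluster.perfect_matchings(range(12))) == 10395

    def test_pairing_score_zero_for_identical_mirror_clusters(self):
        fwd = synthetic_arrow([1, 2], [3, 4], n=5)
        bwd = synthetic_arrow([3, 4], [1, 2], n=5)
        arrows = fwd + bwd
        assignment = np.array([0] * 5 + [1] * 5)
        D = cluster.pairing_score(arrows, assignment, ((0, 1),))
        assert D == pytest.approx(0.0)

    def test_singleton_clusters_reduce_to_centroid_distance(self, rng):
        a = synthetic_arrow([0.0, 0.0], [1.0, 1.0], n=1)
        b = synthetic_arrow([2.0, 0.0], [0.0, 0.0], n=1)
        arrows = a + b
        cents = np.stack([arrows[0].vector, arrows[1].vector])
        S, D_c = cluster.pair_centroids(cents)
        D = cluster.pairing_score(arrows, np.array([0, 1]), S)
        d01 = np.linalg.norm(arrows[0].vector - cluster.mirror(arrows[1].vector))
        assert D == pytest.approx(d01)
        assert D_c == pytest.approx(d01**2)


class TestSelectClusters:
    def _three_state_arrow_set(self, rng, n_per=12, spread=0.08):
        # K=3 internal states, N=2: 6 directed transition classes
        logk = {1: np.log([0.05, 0.05]), 2: np.log([0.00625, 0.0125]),
                3: np.log([0.2, 0.1])}
        arrows = []
        for mu in (1, 2, 3):
            for nu in (1, 2, 3):
                if mu != nu:
                    arrows += synthetic_arrow(
                        logk[mu], logk[nu], rng=rng, spread=spread, n=n_per
                    )
        return arrows

    def test_six_transition_classes_selects_six_clusters(self, rng):
        arrows = self._three_state_arrow_set(rng)
        scan = cluster.select_clusters(
            arrows, K_range=range(2, 11, 2), min_cluster_size=5, n_init=50, seed=1
        )
        assert scan.K_star == 6

    def test_single_bidirectional_path_selects_two(self, rng):
        arrows = synthetic_arrow(
            np.log([0.05, 0.05]), np.log([0.005, 0.01]), rng=rng, spread=0.05, n=15
        ) + synthetic_arrow(
            np.log([0.005, 0.01]), np.log([0.05, 0.05]), rng=rng, spread=0.05, n=15
        )
        # splitting a mirror pair can shave D slightly; the minimum-cluster-size
        # rule (as in the ensemble analysis) is what rejects the over-split K
        scan = cluster.select_clusters(
            arrows, K_range=[2, 4], min_cluster_size=10, n_init=50, seed=2
        )
        assert scan.K_star == 2

    def test_min_cluster_size_rule_can_leave_k_unset(self, rng):
        arrows = self._three_state_arrow_set(rng, n_per=3)
        scan = cluster.select_clusters(
            arrows, K_range=[2, 4], min_cluster_size=1000, n_init=10, seed=0
        )
        assert scan.K_star is None
        assert not any(scan.eligible.values())

    def test_result_invariant_to_arrow_order(self, rng):
        arrows = self._three_state_arrow_set(rng, n_per=6)
        scan_a = cluster.select_clusters(
            arrows, K_range=[4, 6], min_cluster_size=2, n_init=30, seed=3
        )
        order = rng.permutation(len(arrows))
        scan_b = cluster.select_clusters(
            [arrows[i] for i in order],
            K_range=[4, 6],
            min_cluster_size=2,
            n_init=30,
            seed=3,
        )
        assert scan_a.K_star == scan_b.K_star
        for K in (4, 6):
            assert scan_a.D[K] == pytest.approx(scan_b.D[K], rel=1e-9)


class TestLandscapeGraph:
    def test_three_pairs_give_three_edges(self, rng):
        cents = []
        for _ in range(3):
            a = rng.normal(scale=4, size=4)
            cents += [a, cluster.mirror(a)]
        cents = np.stack(cents)
        S = ((0, 1), (2, 3), (4, 5))
        G = cluster.landscape_graph(cents, S)
        assert G.number_of_edges() == 3

    def test_two_clusters_single_edge(self, rng):
        a = rng.normal(size=4)
        G = cluster.landscape_graph(np.stack([a, cluster.mirror(a)]), ((0, 1),))
        assert G.number_of_edges() == 1
        assert G.number_of_nodes() == 2

    def test_coinciding_endpoints_flag_self_loop(self):
        a = np.array([1.0, 2.0, 1.0, 2.0])  # before == after
        with pytest.warns(RuntimeWarning, match="self-loop"):
            G = cluster.landscape_graph(np.stack([a, a]), ((0, 1),))
        assert any(d["self_loop"] for _, _, d in G.edges(data=True))

    def test_merge_tolerance_collapses_shared_basins(self, rng):
        # star topology: basin 0 connected to basins 1 and 2
        sig = {i: rng.normal(scale=6, size=2) for i in range(3)}
        cents = np.stack([
            np.concatenate([sig[0], sig[1]]),
            np.concatenate([sig[1], sig[0]]),
            np.concatenate([sig[0], sig[2]]),
            np.concatenate([sig[2], sig[0]]),
        ])
        G = cluster.landscape_graph(cents, ((0, 1), (2, 3)), merge_tol=0.5)
        assert G.number_of_nodes() == 3
        assert G.number_of_edges() == 2
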