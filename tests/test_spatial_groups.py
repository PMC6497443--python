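import networkx as nx
import numpy as np
import pytest
from scipy import stats

from colonystate.errors import FitError
from colonystate.preprocess import IN_NEST, OUTSIDE, AntTrack
from colonystate.spatial_groups import (
    PerturbationConfig,
    SpatialPartition,
    SpatialSignature,
    build_similarity_network,
    detect_groups,
    group_consistency,
    ks_similarity,
    perturb_and_score,
    spatial_partition,
    spatial_signature,
)

from _oracles import brute_force_ks, exhaustive_best_modularity

from conftest import stationary_track


class TestSpatialSignature:
    def test_ant_at_entrance_all_zero(self, nest1):
        tr = stationary_track("a", nest1.entrance_point, 50)
        sig = spatial_signature(tr, nest1)
        assert np.allclose(sig.samples, 0.0, atol=1e-9)

    def test_outside_ant_empty(self, nest1):
        n = 51
        tr = AntTrack("a", np.full((n, 2), np.nan), np.full(n, OUTSIDE, dtype=np.int8))
        assert spatial_signature(tr, nest1).empty

    def test_alternating_points_two_valued(self, nest1):
        xy = np.tile([[10.0, 0.0], [30.0, 0.0]], (25, 1))
        tr = AntTrack("a", xy, np.full(50, IN_NEST, dtype=np.int8))
        sig = spatial_signature(tr, nest1)
        vals, counts = np.unique(np.round(sig.samples, 6), return_counts=True)
        assert len(vals) == 2
        assert counts[0] == counts[1]


class TestKSSimilarity:
    def test_identical_signatures(self):
        s = SpatialSignature("a", np.array([1.0, 2.0, 3.0]))
        t = SpatialSignature("b", np.array([1.0, 2.0, 3.0]))
        assert ks_similarity(s, t) == pytest.approx(1.0)

    def test_disjoint_point_masses(self):
        s = SpatialSignature("a", np.full(10, 10.0))
        t = SpatialSignature("b", np.full(10, 30.0))
        assert ks_similarity(s, t) == pytest.approx(0.0)

    def test_hand_computed_cdf_gap(self):
        s = SpatialSignature("a", np.array([10.0, 20.0]))
        t = SpatialSignature("b", np.array([20.0, 20.0]))
        assert ks_similarity(s, t) == pytest.approx(0.5)

    def test_empty_signature_rejected(self):
        s = SpatialSignature("a", np.empty(0))
        t = SpatialSignature("b", np.array([1.0]))
        with pytest.raises(FitError):
            ks_similarity(s, t)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_and_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.exponential(30.0, 80)
        b = rng.exponential(45.0, 60)
        got = 1.0 - ks_similarity(SpatialSignature("a", a), SpatialSignature("b", b))
        assert got == pytest.approx(stats.ks_2samp(a, b).statistic)
        assert got == pytest.approx(brute_force_ks(a, b))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.gamma(3.0, 10.0, 100)
        b = rng.gamma(2.0, 15.0, 100)
        s1 = ks_similarity(SpatialSignature("a", a), SpatialSignature("b", b))
        s2 = ks_similarity(SpatialSignature("a", 2 * a), SpatialSignature("b", 2 * b))
        assert s1 == pytest.approx(s2)


def _block_network(n_per=4, within=0.9, between=0.1, means=None):
    g = nx.Graph()
    nodes = [f"x{i}" for i in range(2 * n_per)]
    for i, a in enumerate(nodes):
        g.add_node(a, mean_distance=(means or [10.0] * n_per + [100.0] * n_per)[i])
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same = (i < n_per) == (nodes.index(b) < n_per)
            g.add_edge(a, b, weight=within if same else between)
    return g


class TestDetectGroups:
    def test_two_planted_blocks_match_exhaustive_optimum(self):
        g = _block_network()
        part = detect_groups(g, seed=0)
        q_best, best = exhaustive_best_modularity(g)
        assert part.modularity == pytest.approx(q_best, abs=1e-9)
        assert part.n_groups == 2
        # group 1 is the block nearer the entrance
        assert part.members(1) == frozenset(f"x{i}" for i in range(4))

    def test_equal_weight_complete_graph_single_group(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 0.5, "weight")
        nx.set_node_attributes(g, 10.0, "mean_distance")
        part = detect_groups(g, seed=0)
        q_best, _ = exhaustive_best_modularity(g)
        assert part.modularity == pytest.approx(q_best, abs=1e-9)
        assert part.n_groups == 1

    def test_single_ant(self):
        g = nx.Graph()
        g.add_node("only", mean_distance=5.0)
        part = detect_groups(g, seed=0)
        assert part.labels == {"only": 1}

    def test_relabelling_invariance(self):
        g = _block_network()
        part1 = detect_groups(g, seed=0)
        mapping = {n: f"y{n}" for n in g.nodes}
        part2 = detect_groups(nx.relabel_nodes(g, mapping), seed=0)
        for n in g.nodes:
            assert part1.labels[n] == part2.labels[f"y{n}"]


class TestNetwork:
    def test_two_identical_ants_weight_one(self):
        sigs = [
            SpatialSignature("a", np.array([5.0, 10.0])),
            SpatialSignature("b", np.array([5.0, 10.0])),
        ]
        g = build_similarity_network(sigs)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["weight"] == pytest.approx(1.0)

    def test_complete_graph(self):
        rng = np.random.default_rng(0)
        sigs = [SpatialSignature(f"a{i}", rng.uniform(0, 50, 30)) for i in range(7)]
        g = build_similarity_network(sigs)
        assert g.number_of_edges() == 7 * 6 // 2


class TestPerturbAndScore:
    def test_zero_reps_rejected(self):
        g = _block_network()
        with pytest.raises(ValueError):
            perturb_and_score(g, detect_groups(g, 0), PerturbationConfig(n_reps=0))

    def test_separated_blocks_rarely_change(self):
        g = _block_network(within=0.95, between=0.02)
        ref = detect_groups(g, seed=0)
        res = perturb_and_score(g, ref, PerturbationConfig(n_reps=200, seed=3))
        assert res.changed_fraction < 0.05

    def test_single_group_reference_never_changes(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.6, "weight")
        nx.set_node_attributes(g, 10.0, "mean_distance")
        ref = SpatialPartition(labels={n: 1 for n in g.nodes})
        res = perturb_and_score(g, ref, PerturbationConfig(n_reps=50, seed=1))
        assert res.changed_fraction == 0.0

    def test_beta_resampling_mean_change_near_ten_percent(self):
        # shape 4 with a mean constraint implies ~10% mean |change| for
        # mid-range similarities
        rng = np.random.default_rng(0)
        mu = 0.5
        alpha = 4 * mu / (1 - mu)
        draws = rng.beta(alpha, 4.0, 100_000)
        assert abs(draws.mean() - mu) < 0.005
        assert 0.05 < np.abs(draws - mu).mean() < 0.2


class TestGroupConsistency:
    def test_identical_partitions(self):
        labels = {f"a{i}": 1 + i % 3 for i in range(30)}
        p = SpatialPartition(labels=labels)
        rho, pval = group_consistency(p, p, n_perm=2000, seed=0)
        assert rho == pytest.approx(1.0)
        assert pval < 0.01

    def test_anti_ordered_partitions(self):
        high = {f"a{i}": 1 + i % 3 for i in range(30)}
        low = {k: 4 - v for k, v in high.items()}
        rho, _ = group_consistency(
            SpatialPartition(labels=high), SpatialPartition(labels=low), n_perm=1000
        )
        assert rho == pytest.approx(-1.0)

    def test_independent_labels_low_correlation(self):
        rng = np.random.default_rng(11)
        high = {f"a{i}": int(rng.integers(1, 4)) for i in range(80)}
        low = {f"a{i}": int(rng.integers(1, 4)) for i in range(80)}
        rho, pval = group_consistency(
            SpatialPartition(labels=_contig(high)),
            SpatialPartition(labels=_contig(low)),
            n_perm=2000,
            seed=1,
        )
        assert abs(rho) < 0.3
        assert pval > 0.01

    def test_too_few_shared_ants(self):
        p1 = SpatialPartition(labels={"a": 1, "b": 1})
        p2 = SpatialPartition(labels={"a": 1, "c": 1})
        with pytest.raises(FitError):
            group_consistency(p1, p2)


def _contig(labels):
    uniq = sorted(set(labels.values()))
    remap = {u: i + 1 for i, u in enumerate(uniq)}
    return {k: remap[v] for k, v in labels.items()}


class TestPlantedRecovery:
    def test_planted_groups_recovered(self, small_colony, nest4):
        scenario, tracks, labels, _ = small_colony
        part = spatial_partition(tracks, nest4, seed=0)
        # optimal label matching: planted group g -> majority detected label
        agree = 0
        for g in sorted(set(labels)):
            got = [part.labels[tr.ant_id] for tr, l in zip(tracks, labels) if l == g]
            agree += max(np.bincount(got).max(), 0)
        assert agree / len(labels) >= 0.95

    def test_outside_only_ants_get_group_zero(self, nest4):
        from colonystate.synthetic_data import ColonyScenario, simulate_tracks

        sc = ColonyScenario(n_ants=10, nest=nest4, duration=400, n_outside_only=2, seed=4)
        tracks = simulate_tracks(sc)
        part = spatial_partition(tracks, nest4, seed=0)
        for tr in tracks[10:]:
            assert part.labels[tr.ant_id] == 0
        assert all(part.labels[tr.ant_id] >= 1 for tr in tracks[:10])

    def test_group_count_bounds(self, small_colony, nest4):
        _, tracks, labels, _ = small_colony
        part = spatial_partition(tracks, nest4, seed=0)
        assert 1 <= part.n_groups <= len(tracks)
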