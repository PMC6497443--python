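import networkx as nx
import numpy as np
import pytest

from colonystate.errors import FitError
from colonystate.interaction_network import (
    AssortativityResult,
    InteractionCountSeries,
    TrophallaxisEvent,
    assortativity,
    build_network,
    fit_rate_glm,
    interaction_count_series,
)
from colonystate.spatial_groups import SpatialPartition

from _oracles import explicit_edge_jackknife


class TestCountSeries:
    def test_no_events_full_length(self):
        s = interaction_count_series([])
        assert len(s.counts) == 14401
        assert s.counts.sum() == 0

    def test_counts_and_conservation(self):
        evs = [
            TrophallaxisEvent("a", "b", 0, 5),
            TrophallaxisEvent("c", "d", 0, 2),
            TrophallaxisEvent("a", "c", 100, 110),
        ]
        s = interaction_count_series(evs, duration=200)
        assert s.counts[0] == 2
        assert s.counts[100] == 1
        assert s.counts.sum() == len(evs)

    def test_event_outside_window_rejected(self):
        with pytest.raises(ValueError):
            interaction_count_series([TrophallaxisEvent("a", "b", 500, 503)], duration=100)

    def test_event_shorter_than_two_seconds_rejected(self):
        with pytest.raises(ValueError):
            TrophallaxisEvent("a", "b", 10, 11)

    def test_stacked_design_size(self):
        series = [
            interaction_count_series([], colony=c, treatment=t)
            for c in "123"
            for t in ("high", "low")
        ]
        assert sum(len(s.counts) for s in series) == 86_406


class TestRateGLM:
    def _series(self, rates, seed=0):
        rng = np.random.default_rng(seed)
        return [
            InteractionCountSeries(
                rng.poisson(rates[(c, t)], 14401), colony=c, treatment=t
            )
            for c in ("1", "2", "3")
            for t in ("high", "low")
        ]

    def test_equal_rates_give_null_effects(self):
        rates = {(c, t): 0.03 for c in "123" for t in ("high", "low")}
        res = fit_rate_glm(self._series(rates))
        non_intercept = res.table.drop(index="Intercept")
        assert np.all(np.abs(non_intercept["estimate"]) < 0.1)
        assert np.all(non_intercept["p"] > 0.01)

    def test_table_mirrors_effect_level_structure(self):
        rates = {(c, t): 0.03 for c in "123" for t in ("high", "low")}
        res = fit_rate_glm(self._series(rates))
        idx = list(res.table.index)
        assert idx[0] == "Intercept"
        assert sum("colony" in s and "treatment" not in s.lower() for s in idx) == 2
        assert sum("treatment" in s.lower() and ":" not in s for s in idx) == 1
        assert sum(":" in s for s in idx) == 2
        assert len(res.pairwise) == 3

    def test_recovers_doubled_colony1_low_rate(self):
        rates = {(c, t): 0.02 for c in "123" for t in ("high", "low")}
        rates[("1", "low")] = 0.04
        res = fit_rate_glm(self._series(rates, seed=1))
        # colony 1's high-vs-low log-rate contrast differs from colonies 2, 3
        # by log 2; under sum-to-zero (+1/-1) coding the interaction-term
        # difference i_1 - i_c equals half of that
        pw = res.pairwise.set_index(["colony_a", "colony_b"])
        for other in ("2", "3"):
            row = pw.loc[("1", other)]
            assert abs(abs(row["difference"]) - np.log(2) / 2) < 2 * row["se"]
            assert row["p"] < 0.01

    def test_missing_cell_rejected(self):
        series = self._series({(c, t): 0.03 for c in "123" for t in ("high", "low")})
        with pytest.raises(FitError):
            fit_rate_glm(series[:-1])


class TestBuildNetwork:
    def test_no_events_edgeless_roster(self):
        g = build_network([], roster=["a", "b", "c"])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 0

    def test_repeated_dyad_accumulates_weight(self):
        evs = [TrophallaxisEvent("a", "b", t, t + 3) for t in (0, 10, 20)]
        g = build_network(evs)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["weight"] == 3

    def test_degree_sequence_matches_hand_tally(self):
        dyads = [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("d", "e"),
                 ("e", "f"), ("a", "f"), ("b", "f"), ("c", "d"), ("e", "c")]
        evs = [TrophallaxisEvent(u, v, 10 * k, 10 * k + 2) for k, (u, v) in enumerate(dyads)]
        g = build_network(evs)
        degree = {n: sum(1 for d in dyads if n in d) for n in "abcdef"}
        for n, want in degree.items():
            assert g.degree(n) == want

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            build_network([TrophallaxisEvent("a", "a", 0, 5)])


class TestAssortativity:
    def test_all_within_group_edges(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        nx.set_edge_attributes(g, 1, "weight")
        part = SpatialPartition(labels={"a": 1, "b": 1, "c": 2, "d": 2})
        res = assortativity(g, part)
        assert res.r == pytest.approx(1.0)

    def test_balanced_complete_bipartite(self):
        g = nx.complete_bipartite_graph(["a", "b"], ["c", "d"])
        nx.set_edge_attributes(g, 1, "weight")
        part = SpatialPartition(labels={"a": 1, "b": 1, "c": 2, "d": 2})
        assert assortativity(g, part).r == pytest.approx(-1.0)

    def test_single_group_undefined(self):
        g = nx.Graph([("a", "b")])
        part = SpatialPartition(labels={"a": 1, "b": 1})
        with pytest.raises(FitError):
            assortativity(g, part)

    def test_matches_networkx_coefficient(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(12, 0.4, seed=2)
        part = SpatialPartition(
            labels={n: 1 + int(rng.integers(0, 3)) for n in g.nodes}
        )
        nx.set_edge_attributes(g, 1, "weight")
        nx.set_node_attributes(g, {n: part.labels[n] for n in g.nodes}, "grp")
        want = nx.attribute_assortativity_coefficient(g, "grp")
        assert assortativity(g, part).r == pytest.approx(want)

    def test_relabelling_invariance(self):
        g = nx.gnp_random_graph(10, 0.5, seed=5)
        nx.set_edge_attributes(g, 1, "weight")
        rng = np.random.default_rng(0)
        lab = {n: 1 + int(rng.integers(0, 2)) for n in g.nodes}
        part1 = SpatialPartition(labels=lab)
        part2 = SpatialPartition(labels={n: 3 - v for n, v in lab.items()})
        assert assortativity(g, part1).r == pytest.approx(assortativity(g, part2).r)

    def test_jackknife_matches_explicit_leave_one_out(self):
        rng = np.random.default_rng(6)
        evs = []
        t = 0
        nodes = list("abcdefgh")
        while len(evs) < 18:
            u, v = rng.choice(nodes, 2, replace=False)
            evs.append(TrophallaxisEvent(str(u), str(v), t, t + 2))
            t += 10
        g = build_network(evs)
        part = SpatialPartition(
            labels={n: 1 if n in "abcd" else 2 for n in nodes}
        )
        res = assortativity(g, part)
        r_explicit, se_explicit = explicit_edge_jackknife(g, part)
        assert res.r == pytest.approx(r_explicit)
        assert res.se == pytest.approx(se_explicit, abs=1e-9)

    def test_null_labels_within_two_se(self):
        rng = np.random.default_rng(8)
        hits = 0
        for k in range(20):
            g = nx.gnp_random_graph(20, 0.3, seed=100 + k)
            nx.set_edge_attributes(g, 1, "weight")
            perm = rng.permutation(20)
            part = SpatialPartition(
                labels={n: 1 + (int(perm[n]) % 2) for n in g.nodes}
            )
            res = assortativity(g, part)
            hits += abs(res.r) < 2 * res.se + 1e-12
        assert hits >= 18  # >= 90%

    def test_monotone_in_between_group_probability(self, nest4):
        # planted-group event networks: r rises as between-group mixing falls
        rng = np.random.default_rng(9)
        labels = {f"a{i}": 1 + (i % 2) for i in range(20)}
        part = SpatialPartition(labels=labels)
        rs = []
        for p_between in (0.5, 0.2, 0.05):
            evs = []
            t = 0
            while len(evs) < 60:
                if rng.random() < p_between:
                    u = rng.choice([k for k, v in labels.items() if v == 1])
                    v = rng.choice([k for k, v in labels.items() if v == 2])
                else:
                    grp = 1 + int(rng.integers(0, 2))
                    u, v = rng.choice(
                        [k for k, g in labels.items() if g == grp], 2, replace=False
                    )
                evs.append(TrophallaxisEvent(str(u), str(v), t, t + 2))
                t += 5
            rs.append(assortativity(build_network(evs), part).r)
        assert rs[0] < rs[1] < rs[2]
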