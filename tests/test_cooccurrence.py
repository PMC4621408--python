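"""Prevalence filtering, PCC matrices, thresholded networks and the
scale-free threshold criterion."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microsync.cooccurrence import (
    CooccurrenceError,
    build_network,
    degree_powerlaw_fit,
    network_density,
    pcc_matrix,
    prevalence_filter,
    select_threshold,
)
from microsync.table import OtuTable

from oracles import pcc_bruteforce


def _table(counts, samples=None, otus=None):
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    otus = otus or [f"o{j}" for j in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=samples, columns=otus))


class TestPrevalenceFilter:
    def test_half_rule_on_nine_samples(self):
        """Present in 4 of 9 -> removed; 5 of 9 -> kept."""
        col4 = [1, 1, 1, 1, 0, 0, 0, 0, 0]
        col5 = [1, 1, 1, 1, 1, 0, 0, 0, 0]
        table = _table(np.array([col4, col5]).T, otus=["four", "five"])
        kept = prevalence_filter(table, table.sample_ids, 0.5)
        assert kept == ["five"]

    def test_zero_fraction_keeps_any_presence(self):
        table = _table([[1, 0], [0, 0], [1, 0]], otus=["seen", "never"])
        kept = prevalence_filter(table, table.sample_ids, 0.0)
        assert kept == ["seen"]

    def test_empty_group_errors(self, random_table):
        with pytest.raises(CooccurrenceError):
            prevalence_filter(random_table(), [], 0.5)


class TestPccMatrix:
    def test_proportional_vectors_give_unit_correlation(self):
        base = np.array([1, 2, 3, 4, 5, 6])
        table = _table(np.column_stack([base, base * 3, 7 - base]),
                       otus=["a", "b", "c"])
        cm = pcc_matrix(table, table.sample_ids, ["a", "b", "c"],
                        use_relative=False)
        assert cm.loc["a", "b"] == pytest.approx(1.0)
        assert cm.loc["a", "c"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        table = _table(rng.integers(1, 100, size=(6, 10)))
        cm = pcc_matrix(table, table.sample_ids, table.otu_ids)
        rel = table.counts / table.counts.sum(axis=1, keepdims=True)
        assert np.allclose(cm.to_numpy(), pcc_bruteforce(rel), atol=1e-12)

    def test_sample_total_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(6, 5))
        scaled = counts * np.array([1, 10, 2, 5, 1, 3])[:, None]
        cm1 = pcc_matrix(_table(counts), [f"s{i}" for i in range(6)],
                         [f"o{j}" for j in range(5)])
        cm2 = pcc_matrix(_table(scaled), [f"s{i}" for i in range(6)],
                         [f"o{j}" for j in range(5)])
        assert np.allclose(cm1.to_numpy(), cm2.to_numpy(), atol=1e-12)

    def test_too_few_samples_errors(self):
        table = _table(np.ones((3, 4), dtype=int))
        with pytest.raises(CooccurrenceError):
            pcc_matrix(table, table.sample_ids, table.otu_ids)

    def test_zero_variance_otus_dropped_with_warning(self):
        counts = np.array([[5, 1], [5, 2], [5, 3], [5, 4], [5, 9]])
        table = _table(counts, otus=["flat", "x"])
        # make another varying column so >=2 remain
        table = _table(np.column_stack([counts, [9, 1, 4, 2, 8]]),
                       otus=["flat", "x", "y"])
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = pcc_matrix(table, table.sample_ids, table.otu_ids,
                            use_relative=False)
        assert "flat" not in cm.index


class TestBuildNetwork:
    def _cm(self, vals, otus):
        return pd.DataFrame(vals, index=otus, columns=otus)

    def test_threshold_above_max_gives_no_edges(self):
        vals = np.full((4, 4), 0.95)
        np.fill_diagonal(vals, 1.0)
        net = build_network(self._cm(vals, list("abcd")), 1.0)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 4  # isolated nodes retained

    def test_complete_graph_at_low_threshold(self):
        vals = np.full((5, 5), 0.95)
        np.fill_diagonal(vals, 1.0)
        net = build_network(self._cm(vals, list("abcde")), 0.9)
        assert net.number_of_edges() == 10

    def test_hand_enumerated_edges_and_signs(self):
        otus = list("abcde")
        vals = np.eye(5)
        pairs = {("a", "b"): 0.95, ("a", "c"): -0.92, ("b", "d"): 0.5,
                 ("c", "e"): 0.89, ("d", "e"): -0.99}
        idx = {o: i for i, o in enumerate(otus)}
        for (u, v), r in pairs.items():
            vals[idx[u], idx[v]] = vals[idx[v], idx[u]] = r
        net = build_network(self._cm(vals, otus), 0.9)
        assert set(map(frozenset, net.edges)) == {
            frozenset({"a", "b"}), frozenset({"a", "c"}), frozenset({"d", "e"})
        }
        assert net.edges["a", "c"]["sign"] == -1
        assert net.edges["a", "b"]["sign"] == 1

    def test_edge_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 15))
        cm = pd.DataFrame(np.corrcoef(x, rowvar=False),
                          index=[f"o{j}" for j in range(15)],
                          columns=[f"o{j}" for j in range(15)])
        counts = [build_network(cm, t).number_of_edges()
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestPowerlawFit:
    def test_recovers_generated_exponent(self):
        """A degree sequence drawn as N(k) = round(1000 k^-1.5) fits back
        the generating exponent with near-perfect r^2."""
        degrees = []
        for k in range(1, 21):
            degrees += [k] * round(1000 * k ** -1.5)
        if sum(degrees) % 2:
            degrees[0] += 1
        g = nx.configuration_model(degrees, seed=1)
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        exponent, r2 = degree_powerlaw_fit(g)
        assert exponent == pytest.approx(1.5, abs=0.25)
        assert r2 > 0.9

    def test_regular_graph_errors(self):
        g = nx.cycle_graph(10)
        with pytest.raises(CooccurrenceError):
            degree_powerlaw_fit(g)

    def test_preferential_attachment_beats_uniform_random(self):
        """Scale-free generators fit a power law better than G(n, p)."""
        wins = 0
        for seed in range(10):
            ba = nx.barabasi_albert_graph(800, 2, seed=seed)
            er = nx.gnm_random_graph(800, ba.number_of_edges(), seed=seed)
            _, r2_ba = degree_powerlaw_fit(ba)
            try:
                _, r2_er = degree_powerlaw_fit(er)
            except CooccurrenceError:
                r2_er = -1.0
            wins += r2_ba > r2_er
        assert wins >= 9


class TestSelectThreshold:
    @staticmethod
    def _hub_cm():
        """Correlation matrix whose 0.9-network is a hub-and-spokes graph
        with a skewed (fittable) degree histogram."""
        otus = [f"o{j}" for j in range(12)]
        vals = np.eye(12)
        edges = [(0, j) for j in range(1, 8)] + [(1, 8), (1, 9), (2, 10)]
        for i, j in edges:
            vals[i, j] = vals[j, i] = 0.95
        return pd.DataFrame(vals, index=otus, columns=otus)

    def test_degenerate_grid_returns_single_point(self):
        assert select_threshold(self._hub_cm(), grid=[0.9], min_nodes=3) == 0.9

    def test_invariant_to_grid_ordering(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 30))
        x += x[:, :1] * rng.gamma(1.0, 1.0, size=30)
        cm = pd.DataFrame(np.corrcoef(x, rowvar=False),
                          index=[f"o{j}" for j in range(30)],
                          columns=[f"o{j}" for j in range(30)])
        grid = [0.5, 0.6, 0.7, 0.8, 0.9]
        assert select_threshold(cm, grid=grid, min_nodes=5) == select_threshold(
            cm, grid=grid[::-1], min_nodes=5
        )

    def test_no_feasible_point_errors(self):
        cm = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        with pytest.raises(CooccurrenceError):
            select_threshold(cm, grid=[0.9], min_nodes=3)


class TestNetworkDensity:
    def test_known_graphs(self):
        assert network_density(nx.complete_graph(5)) == pytest.approx(4.0)
        assert network_density(nx.empty_graph(7)) == pytest.approx(0.0)
        assert network_density(nx.path_graph(4)) == pytest.approx(1.5)

    def test_edges_per_node_alternative(self):
        g = nx.path_graph(4)
        assert network_density(g, mode="edges_per_node") == pytest.approx(0.75)

    def test_empty_network_errors(self):
        with pytest.raises(CooccurrenceError):
            network_density(nx.Graph())
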