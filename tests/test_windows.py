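"""Window statistic series, variance, compress ratio, and w* selection."""

import math

import networkx as nx
import pytest

from cohesionet import (compress_ratio, from_edges, select_window_size,
                        statistic_series, variance_of)
from cohesionet.windows import WindowSeries


# ---------------------------------------------------------------------------
# independent brute-force re-implementation (oracle)

def oracle_avg_path(edges):
    g = nx.Graph(edges)
    if g.number_of_edges() == 0:
        return None
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 2:
        return None
    total = n_pairs = 0
    for s in comp:
        lengths = nx.single_source_shortest_path_length(g.subgraph(comp), s)
        for t in comp:
            if t != s:
                total += lengths[t]
                n_pairs += 1
    return total / n_pairs


def oracle_series(net, w, degree_threshold=None):
    horizon = net.horizon
    n_windows = math.ceil(horizon / w)
    values = []
    for i in range(1, n_windows + 1):
        lo, hi = (i - 1) * w, i * w
        edges = [(u, v) for u, v, t in net.edges if lo < t <= hi]
        if degree_threshold is not None:
            t_end = min(hi, horizon)
            cum = nx.Graph((u, v) for u, v, t in net.edges if t <= t_end)
            keep = {n for n in cum if cum.degree(n) > degree_threshold}
            edges = [(u, v) for u, v in edges if u in keep and v in keep]
        values.append(oracle_avg_path(edges))
    return values


def oracle_select(net, grid, degree_threshold=100):
    variance, ratio = {}, {}
    for w in grid:
        full = [v for v in oracle_series(net, w) if v is not None]
        if not full:
            continue
        mean = sum(full) / len(full)
        variance[w] = sum((v - mean) ** 2 for v in full) / len(full)
        core = [v for v in oracle_series(net, w, degree_threshold)
                if v is not None]
        ratio[w] = len(full) / len(core) if core else float(len(full))

    def norm(d):
        lo, hi = min(d.values()), max(d.values())
        return {k: 0.0 if hi == lo else (v - lo) / (hi - lo) for k, v in d.items()}

    vn, rn = norm(variance), norm(ratio)
    obj = {w: abs(vn[w] - rn[w]) for w in variance}
    return min(obj, key=lambda w: (obj[w], w))


# ---------------------------------------------------------------------------

class TestStatisticSeries:
    def test_path_graph_window(self):
        net = from_edges([("a", "b", 1), ("b", "c", 1)])
        series = statistic_series(net, 1)
        assert series.values[0] == pytest.approx(4 / 3)

    def test_single_edge_window(self):
        net = from_edges([("a", "b", 1)])
        assert statistic_series(net, 1).values == [1.0]

    def test_empty_window_marked_undefined(self):
        net = from_edges([("a", "b", 1), ("c", "d", 3)])
        series = statistic_series(net, 1)
        assert series.values[1] is None

    def test_matches_oracle(self):
        net = from_edges([("a", "b", 1), ("b", "c", 2), ("c", "d", 2),
                          ("a", "d", 3), ("d", "e", 4), ("a", "e", 5)])
        for w in (1, 2, 3, 5):
            got = statistic_series(net, w).values
            want = oracle_series(net, w)
            assert got == pytest.approx(want)


class TestVariance:
    def test_constant_series_zero(self):
        s = WindowSeries(w=1, n_windows=3, graphs=[], values=[2.0, 2.0, 2.0])
        assert variance_of(s) == 0.0

    def test_population_variance(self):
        s = WindowSeries(w=1, n_windows=3, graphs=[], values=[1.0, 2.0, 3.0])
        assert variance_of(s) == pytest.approx(2 / 3)

    def test_undefined_entries_skipped(self):
        s = WindowSeries(w=1, n_windows=3, graphs=[], values=[1.5, None, 2.5])
        assert variance_of(s) == pytest.approx(0.25)

    def test_all_undefined_raises(self):
        s = WindowSeries(w=1, n_windows=1, graphs=[], values=[None])
        with pytest.raises(ValueError):
            variance_of(s)


class TestCompressRatio:
    def _dense_core_net(self):
        # hub pair with degree > 2 active in most months, plus sparse periphery
        edges = []
        for t in range(1, 6):
            edges += [("h1", f"p{t}a", t), ("h2", f"p{t}b", t)]
        edges += [("h1", "h2", 1), ("h1", "x", 2), ("h2", "y", 2)]
        return from_edges(edges)

    def test_fully_defined_series_gives_one(self):
        net = self._dense_core_net()
        assert compress_ratio(net, 5, degree_threshold=0) == 1.0

    def test_partial_core_definition(self):
        # full series defined in both windows; the degree->2 core
        # {h1, h2} is linked only inside window 1, so the core series
        # has one defined entry and the ratio is 2/1
        net = from_edges([("h1", "h2", 1), ("h1", "a", 1), ("h1", "b", 1),
                          ("h2", "c", 1), ("h2", "d", 1), ("x", "y", 2)])
        ratio = compress_ratio(net, 1, degree_threshold=2)
        assert ratio == pytest.approx(2 / 1)

    def test_unreachable_threshold_guarded(self, caplog):
        net = from_edges([("a", "b", 1), ("b", "c", 2)])
        with caplog.at_level("WARNING"):
            ratio = compress_ratio(net, 1, degree_threshold=100)
        assert ratio == 2.0  # number of defined full windows
        assert "undefined" in caplog.text


class TestSelectWindowSize:
    def test_single_candidate_selected(self):
        net = from_edges([("a", "b", 1), ("b", "c", 2), ("a", "c", 3)])
        assert select_window_size(net, grid=[2]).selected == 2

    def test_tie_broken_to_smaller_w(self):
        # constant statistic everywhere -> all objectives equal -> smallest w
        net = from_edges([("a", "b", 1), ("c", "d", 2), ("e", "f", 3),
                          ("g", "h", 4)])
        res = select_window_size(net, grid=[1, 2], degree_threshold=0)
        assert res.selected == 1

    def test_matches_brute_force_on_small_networks(self):
        from dataclasses import replace
        from cohesionet import SyntheticConfig, generate_growth_network
        for seed in (7, 8, 9):
            cfg = replace(SyntheticConfig(), months=24, n_init=6, e_init=7,
                          arrivals_per_month=1.5, seed=seed)
            net = generate_growth_network(cfg)
            assert net.n_nodes() <= 50
            grid = [2, 3, 5, 8, 12]
            got = select_window_size(net, grid=grid, degree_threshold=5)
            want = oracle_select(net, grid, degree_threshold=5)
            assert got.selected == want

    def test_objective_invariant_to_affine_rescaling(self):
        # normalization absorbs any affine transform of raw V or R
        raw_v = {1: 2.0, 2: 5.0, 3: 3.0}
        raw_r = {1: 1.0, 2: 1.5, 3: 1.2}
        from cohesionet.windows import _minmax
        base = {w: abs(_minmax(raw_v)[w] - _minmax(raw_r)[w]) for w in raw_v}
        scaled_v = {w: 10 + 3 * v for w, v in raw_v.items()}
        scaled = {w: abs(_minmax(scaled_v)[w] - _minmax(raw_r)[w]) for w in raw_v}
        assert base == pytest.approx(scaled)
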