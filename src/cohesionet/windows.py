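"""Time-window resolution selection for temporal networks.

Choosing how finely to slice a growing network in time is a bias/variance
trade-off: short windows oversample (the per-window statistic series is
noisy), long windows blur change (consecutive windows are redundant).
The selection procedure slices the timeline into ``T = ceil(horizon/w)``
windows for each candidate ``w``, computes the statistic series
``F_w = [f(G_1), ..., f(G_T)]`` with ``f`` the average shortest path
length on the largest connected component of each window graph, and
scores each ``w`` by two quantities:

* ``V(F_w)`` — population variance of the defined entries (oversampling
  noise);
* ``R(F_w)`` — the series-length ratio between the full-graph series and
  the series restricted to high-degree nodes (redundancy).  "Length" is
  the count of *defined* entries: windows where the (sub)graph has at
  least two connected nodes.  Taken literally as T/T the ratio is
  identically 1, so the defined-entry count is the operative
  reconstruction — see docs/methods.md.

``V`` and ``R`` live on different scales, so both are min–max normalized
across the candidate grid before taking the objective ``|V_n - R_n|``;
the selected ``w*`` minimizes it, ties going to the smallest ``w``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .cohesion import _lcc_distances
from .temporal import TemporalNetwork, snapshot_at, window_graphs

logger = logging.getLogger(__name__)


@dataclass
class WindowSeries:
    """Per-window graphs and the statistic series for one window size."""

    w: int
    n_windows: int
    graphs: list[nx.Graph]
    values: list[float | None]  # None marks an undefined entry

    def defined(self) -> list[float]:
        return [v for v in self.values if v is not None]

    def n_defined(self) -> int:
        return len(self.defined())


@dataclass
class WindowSelectionResult:
    grid: list[int]
    variance: dict[int, float]
    compress: dict[int, float]
    variance_norm: dict[int, float] = field(default_factory=dict)
    compress_norm: dict[int, float] = field(default_factory=dict)
    objective: dict[int, float] = field(default_factory=dict)
    selected: int = 0

    def to_dict(self) -> dict:
        return {
            "grid": self.grid,
            "variance": self.variance,
            "compress_ratio": self.compress,
            "objective": self.objective,
            "selected_w": self.selected,
        }


def _avg_shortest_path(g: nx.Graph) -> float | None:
    """Average geodesic length on the largest component; None if < 2
    connected nodes."""
    if g.number_of_edges() == 0:
        return None
    dist = _lcc_distances(g)
    n = dist.shape[0]
    if n < 2:
        return None
    return float(dist.sum() / (n * (n - 1)))


def statistic_series(net: TemporalNetwork, w: int,
                     degree_threshold: int | None = None) -> WindowSeries:
    """Average-shortest-path series over within-window graphs.

    With ``degree_threshold`` set, each window graph is first restricted
    to nodes whose *cumulative* degree at the window's end strictly
    exceeds the threshold (the persistent high-degree core).
    """
    graphs = window_graphs(net, w, mode="within")
    values: list[float | None] = []
    if degree_threshold is None:
        for g in graphs:
            values.append(_avg_shortest_path(g))
    else:
        restricted = []
        for i, g in enumerate(graphs, start=1):
            t_end = min(i * w, net.horizon)
            cum_deg = dict(snapshot_at(net, t_end).degree)
            keep = [n for n in g.nodes if cum_deg.get(n, 0) > degree_threshold]
            sub = g.subgraph(keep)
            restricted.append(sub)
            values.append(_avg_shortest_path(sub))
        graphs = restricted
    return WindowSeries(w=w, n_windows=len(graphs), graphs=graphs, values=values)


def variance_of(series: WindowSeries) -> float:
    """Population variance of the defined entries."""
    vals = series.defined()
    if not vals:
        raise ValueError("statistic series has no defined entries")
    mean = sum(vals) / len(vals)
    return sum((v - mean) ** 2 for v in vals) / len(vals)


def compress_ratio(net: TemporalNetwork, w: int,
                   degree_threshold: int = 100,
                   full_series: WindowSeries | None = None) -> float:
    """Defined-entry count of the full series over that of the
    high-degree-core series.

    If the core series is everywhere undefined the ratio is guarded: the
    full series' defined count is returned with a warning (the unguarded
    value would be infinite).  ``full_series`` may be passed to reuse an
    already-computed full-graph series for the same ``w``."""
    full = full_series if full_series is not None else statistic_series(net, w)
    core = statistic_series(net, w, degree_threshold=degree_threshold)
    n_full, n_core = full.n_defined(), core.n_defined()
    if n_core == 0:
        logger.warning(
            "high-degree series undefined in every window (w=%d, threshold=%d); "
            "returning the full series' defined count", w, degree_threshold)
        return float(n_full)
    return n_full / n_core


def _minmax(values: dict[int, float]) -> dict[int, float]:
    lo, hi = min(values.values()), max(values.values())
    if math.isclose(hi, lo):
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def select_window_size(net: TemporalNetwork, grid=None,
                       degree_threshold: int = 100) -> WindowSelectionResult:
    """Pick ``w*`` minimizing ``|V_norm - R_norm|`` over the grid.

    Default grid is every window length from 1 month to the horizon.
    Candidates whose statistic series has no defined entry are dropped;
    an all-degenerate grid raises.  Ties break toward the smallest ``w``.
    """
    if grid is None:
        grid = list(range(1, net.horizon + 1))
    grid = sorted(set(int(w) for w in grid))
    if not grid:
        raise ValueError("empty candidate grid")
    variance: dict[int, float] = {}
    compress: dict[int, float] = {}
    for w in grid:
        series = statistic_series(net, w)
        if series.n_defined() == 0:
            logger.warning("window size %d has no defined statistic; skipped", w)
            continue
        variance[w] = variance_of(series)
        compress[w] = compress_ratio(net, w, degree_threshold=degree_threshold,
                                     full_series=series)
    if not variance:
        raise ValueError("every candidate window size is degenerate")
    v_norm = _minmax(variance)
    r_norm = _minmax(compress)
    objective = {w: abs(v_norm[w] - r_norm[w]) for w in variance}
    selected = min(objective, key=lambda w: (objective[w], w))
    return WindowSelectionResult(
        grid=sorted(variance), variance=variance, compress=compress,
        variance_norm=v_norm, compress_norm=r_norm,
        objective=objective, selected=selected,
    )
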