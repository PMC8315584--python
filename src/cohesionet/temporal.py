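"""Data model and I/O for undirected temporal friendship networks.

A :class:`TemporalNetwork` is a set of attributed nodes plus undirected
edges timestamped by month index (1-based).  Every downstream stage —
cohesion metrics, community detection, window selection, growth models —
consumes either the full temporal object or static snapshots/windows
extracted here.

Conventions
-----------
* Edges are undirected; ``(u, v, t)`` and ``(v, u, t)`` are the same edge
  and storage is canonicalized with ``u < v``.
* A pair of nodes carries at most one edge, stamped with the *earliest*
  month it was observed: a friendship has a unique starting date.
* A node "arrives" with its first edge; nodes never touched by an edge up
  to month ``t`` are not members of the snapshot at ``t`` (the data carry
  no independent join date).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

CATEGORIES = ("PA", "FI", "AI", "CH", "UNKNOWN")
SEXES = ("F", "M", "UNKNOWN")

_YM_RE = re.compile(r"^(\d{4})-(\d{1,2})$")


class EdgeTableError(ValueError):
    """Raised for malformed edge or node tables (carries the line number)."""


@dataclass
class TemporalNetwork:
    """Undirected temporal network with monthly edge timestamps.

    Attributes
    ----------
    edges
        List of ``(u, v, t)`` with ``u < v`` (string node ids) and
        ``1 <= t <= horizon``.
    categories, sexes
        Node attribute maps; missing nodes are ``UNKNOWN``.
    horizon
        Last month index (``T_max``).
    """

    edges: list[tuple[str, str, int]] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)
    sexes: dict[str, str] = field(default_factory=dict)
    horizon: int = 0

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for u, v, _ in self.edges:
            out.add(u)
            out.add(v)
        return out

    def category_of(self, node: str) -> str:
        return self.categories.get(node, "UNKNOWN")

    def sex_of(self, node: str) -> str:
        return self.sexes.get(node, "UNKNOWN")

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        seen: set[tuple[str, str]] = set()
        for u, v, t in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if not u < v:
                raise ValueError(f"edge ({u!r}, {v!r}) not canonicalized")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))
            if not 1 <= t <= self.horizon:
                raise ValueError(f"timestamp {t} outside [1, {self.horizon}]")


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


def _build(raw: list[tuple[str, str, int]]) -> TemporalNetwork:
    """Canonicalize, drop self-loops, keep earliest month per pair."""
    earliest: dict[tuple[str, str], int] = {}
    n_loops = 0
    for u, v, t in raw:
        if u == v:
            n_loops += 1
            continue
        key = _canonical(u, v)
        if key not in earliest or t < earliest[key]:
            earliest[key] = t
    if n_loops:
        logger.warning("rejected %d self-loop edge(s)", n_loops)
    edges = sorted((u, v, t) for (u, v), t in earliest.items())
    horizon = max((t for _, _, t in edges), default=0)
    return TemporalNetwork(edges=edges, horizon=horizon)


def _parse_stamp(token: str, line_no: int) -> tuple[int | None, int]:
    """Return (absolute-months-since-year-0, raw-int) for a timestamp token.

    Calendar stamps "YYYY-MM" yield an absolute month count in the first
    slot; bare integers yield ``(None, value)``.
    """
    token = token.strip()
    m = _YM_RE.match(token)
    if m:
        year, month = int(m.group(1)), int(m.group(2))
        if not 1 <= month <= 12:
            raise EdgeTableError(f"line {line_no}: month out of range in {token!r}")
        return year * 12 + (month - 1), 0
    try:
        return None, int(token)
    except ValueError:
        raise EdgeTableError(
            f"line {line_no}: timestamp {token!r} is neither YYYY-MM nor an integer"
        ) from None


def load_edge_table(path, month_origin: str | None = None) -> TemporalNetwork:
    """Read a delimited edge table into a :class:`TemporalNetwork`.

    The file needs at least three columns ``u, v, t`` (header row optional
    but conventional); ``t`` is either a 1-based integer month index or a
    calendar stamp ``YYYY-MM``.  Calendar stamps are mapped to 1-based
    indices relative to the earliest stamp, or to ``month_origin``
    ("YYYY-MM") when given.  Duplicate pairs collapse to the earliest
    month; self-loops are rejected with a warning count.
    """
    rows: list[tuple[str, str, int | None, int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for line_no, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if line_no == 1 and [c.strip().lower() for c in row[:3]] == ["u", "v", "t"]:
                continue
            if len(row) < 3:
                raise EdgeTableError(f"line {line_no}: expected 3 columns, got {len(row)}")
            u, v = row[0].strip(), row[1].strip()
            if not u or not v:
                raise EdgeTableError(f"line {line_no}: empty node id")
            abs_month, raw_int = _parse_stamp(row[2], line_no)
            rows.append((u, v, abs_month, raw_int, line_no))
    if not rows:
        return TemporalNetwork()

    calendar = [r for r in rows if r[2] is not None]
    if calendar and len(calendar) != len(rows):
        raise EdgeTableError("edge table mixes calendar and integer timestamps")
    if calendar:
        if month_origin is not None:
            origin, _ = _parse_stamp(month_origin, 0)
        else:
            origin = min(r[2] for r in calendar)  # type: ignore[type-var]
        raw = []
        for u, v, abs_month, _, line_no in rows:
            t = abs_month - origin + 1  # type: ignore[operator]
            if t < 1:
                raise EdgeTableError(f"line {line_no}: stamp precedes month origin")
            raw.append((u, v, t))
    else:
        for u, v, _, t, line_no in rows:
            if t < 1:
                raise EdgeTableError(f"line {line_no}: month index {t} < 1")
        raw = [(u, v, t) for u, v, _, t, _ in rows]
    return _build(raw)


def from_edges(edges, horizon: int | None = None) -> TemporalNetwork:
    """Build a network from in-memory ``(u, v, t)`` triples (canonicalizing)."""
    net = _build([(str(u), str(v), int(t)) for u, v, t in edges])
    if horizon is not None:
        if horizon < net.horizon:
            raise ValueError("horizon smaller than the latest edge timestamp")
        net.horizon = horizon
    return net


def write_edge_table(net: TemporalNetwork, path) -> None:
    """Write the canonical edge table with header ``u,v,t`` (round-trips)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["u", "v", "t"])
        for u, v, t in sorted(net.edges):
            writer.writerow([u, v, t])


def attach_node_table(net: TemporalNetwork, path) -> TemporalNetwork:
    """Attach ``id,category,sex`` attributes from a delimited table (in place).

    Categories must be in {PA, FI, AI, CH} or blank; blank/missing means
    UNKNOWN.  Rows for ids absent from the network are ignored with a
    warning.  Returns the same network for chaining.
    """
    nodes = net.nodes
    unmatched = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for line_no, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if line_no == 1 and row[0].strip().lower() == "id":
                continue
            node = row[0].strip()
            cat = row[1].strip().upper() if len(row) > 1 and row[1].strip() else "UNKNOWN"
            sex = row[2].strip().upper() if len(row) > 2 and row[2].strip() else "UNKNOWN"
            if cat not in CATEGORIES:
                raise EdgeTableError(f"line {line_no}: unknown category {row[1].strip()!r}")
            if sex not in SEXES:
                raise EdgeTableError(f"line {line_no}: unknown sex {row[2].strip()!r}")
            if node not in nodes:
                unmatched += 1
                continue
            net.categories[node] = cat
            net.sexes[node] = sex
    if unmatched:
        logger.warning("node table: %d row(s) for ids absent from the network", unmatched)
    return net


def write_node_table(net: TemporalNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "category", "sex"])
        for node in sorted(net.nodes):
            writer.writerow([node, net.category_of(node), net.sex_of(node)])


def _as_graph(net: TemporalNetwork, edges) -> nx.Graph:
    g = nx.Graph()
    for u, v, t in edges:
        g.add_edge(u, v, month=t)
    for node in g.nodes:
        g.nodes[node]["category"] = net.category_of(node)
        g.nodes[node]["sex"] = net.sex_of(node)
    return g


def snapshot_at(net: TemporalNetwork, t: int) -> nx.Graph:
    """Cumulative static graph: all edges with timestamp <= t.

    Monotone in ``t``; isolated never-connected nodes are excluded.
    """
    if not 1 <= t <= net.horizon:
        raise ValueError(f"month {t} outside [1, {net.horizon}]")
    return _as_graph(net, ((u, v, s) for u, v, s in net.edges if s <= t))


def window_graphs(net: TemporalNetwork, w: int, mode: str = "within") -> list[nx.Graph]:
    """Split the timeline into ``T = ceil(horizon / w)`` window graphs.

    ``mode="within"``: window *i* holds edges with month in
    ``((i-1)*w, i*w]``.  ``mode="cumulative"``: edges with month
    ``<= i*w``.  The final window may be shorter.
    """
    if w < 1:
        raise ValueError("window length must be >= 1")
    if w > net.horizon:
        raise ValueError(f"window length {w} exceeds horizon {net.horizon}")
    if mode not in ("within", "cumulative"):
        raise ValueError(f"unknown mode {mode!r}")
    n_windows = -(-net.horizon // w)  # ceil
    out = []
    for i in range(1, n_windows + 1):
        lo = 0 if mode == "cumulative" else (i - 1) * w
        hi = i * w
        out.append(_as_graph(net, ((u, v, t) for u, v, t in net.edges if lo < t <= hi)))
    return out


def cumulative_counts(net: TemporalNetwork) -> list[tuple[int, int, int]]:
    """Per-month ``(t, N(t), E(t))`` cumulative node and edge counts."""
    by_month: dict[int, list[tuple[str, str]]] = {}
    for u, v, t in net.edges:
        by_month.setdefault(t, []).append((u, v))
    seen: set[str] = set()
    n_edges = 0
    out = []
    for t in range(1, net.horizon + 1):
        for u, v in by_month.get(t, ()):
            seen.add(u)
            seen.add(v)
            n_edges += 1
        out.append((t, len(seen), n_edges))
    return out


def export_graphml(g: nx.Graph, path) -> None:
    """Write a static graph (with node attributes) to GraphML."""
    nx.write_graphml(g, path)
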