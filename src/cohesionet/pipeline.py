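"""Orchestration: run the full analysis chain and emit one report.

``run_full`` executes the stages in dependency order — ingest (or
simulate), cohesion metrics with the randomized-null comparison,
community structure and centrality rankings, time-window selection, and
the growth models (attachment kernel at the selected window step,
densification scaling with jump detection) — and collects everything
into a single JSON-serializable :class:`AnalysisReport`.  Every default
and seed is echoed into the report's provenance section so any number in
it can be recomputed; the report itself carries no timestamps, making
reruns byte-identical for a given config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import yaml

from . import __version__
from .cohesion import cohesion_report, null_ensemble
from .communities import (centrality_rankings, community_hubs,
                          detect_communities, principal_communities)
from .growth import detect_jumps, estimate_kernel, fit_scaling
from .synthetic import SyntheticConfig, generate_growth_network, program_preset
from .temporal import (TemporalNetwork, attach_node_table, cumulative_counts,
                       load_edge_table, snapshot_at)
from .windows import select_window_size

logger = logging.getLogger(__name__)

DEFAULTS = {
    "seed": 0,
    "cohesion": {"null_reps": 100, "swaps_per_edge": 10},
    "communities": {"resolution": 1.0, "coverage": 0.83,
                    "hub_degree_threshold": 300, "top_n": 10},
    "windows": {"grid": None, "degree_threshold": 100},
    "growth": {"step": "auto", "pooling": "debiased", "binning": "log",
               "jump_z": 2.0},
}


@dataclass
class AnalysisReport:
    """Structured result of the full pipeline (JSON-serializable)."""

    sections: dict = field(default_factory=dict)
    net: TemporalNetwork | None = None  # kept for follow-up tables, not serialized
    selected_w: int | None = None

    def to_dict(self) -> dict:
        return self.sections

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.sections, indent=indent, sort_keys=True)


def _merged_config(config: dict) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _load_input(config: dict) -> TemporalNetwork:
    if "edge_table" in config:
        net = load_edge_table(config["edge_table"],
                              month_origin=config.get("month_origin"))
        if config.get("node_table"):
            attach_node_table(net, config["node_table"])
        return net
    sim = config.get("simulate")
    if sim is not None:
        if sim in ("program", "preset", {"preset": "program"}):
            cfg = program_preset()
        elif isinstance(sim, dict):
            base = program_preset() if sim.pop("preset", None) == "program" \
                else SyntheticConfig()
            for key, value in sim.items():
                if not hasattr(base, key):
                    raise ValueError(f"unknown simulate parameter {key!r}")
                setattr(base, key, value)
            cfg = base
        else:
            raise ValueError(f"unrecognized simulate section {sim!r}")
        cfg.seed = int(config.get("seed", cfg.seed))
        return generate_growth_network(cfg)
    raise ValueError("config must name an edge_table or a simulate section")


def _category_counts(net: TemporalNetwork) -> dict[str, int]:
    counts: dict[str, int] = {}
    for node in net.nodes:
        cat = net.category_of(node)
        counts[cat] = counts.get(cat, 0) + 1
    return dict(sorted(counts.items()))


def run_full(config: dict | str) -> AnalysisReport:
    """Run every stage on the configured input; stage failures leave an
    error entry in the report instead of aborting the rest."""
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merged_config(config)
    seed = int(cfg["seed"])

    report = AnalysisReport()
    log_section: list[dict] = []

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            report.sections[name] = fn()
            status = "ok"
        except Exception as exc:  # noqa: BLE001 - partial reports by contract
            logger.exception("stage %s failed", name)
            report.sections.setdefault("errors", {})[name] = str(exc)
            status = "error"
        logger.info("stage %-12s %s (%.2fs)", name, status, time.perf_counter() - t0)
        log_section.append({"stage": name, "status": status})

    net = _load_input(cfg)  # missing input must fail before any stage runs
    report.net = net
    final = snapshot_at(net, net.horizon)

    def input_stage():
        return {
            "n_nodes": net.n_nodes(), "n_edges": net.n_edges(),
            "horizon": net.horizon, "categories": _category_counts(net),
        }

    def cohesion_stage():
        c = cfg["cohesion"]
        ens = null_ensemble(final, n_reps=int(c["null_reps"]), seed=seed,
                            swaps_per_edge=int(c["swaps_per_edge"]))
        counts = cumulative_counts(net)
        first_t = next(t for t, n, _ in counts if n >= 2)
        return {
            "final": cohesion_report(final).to_dict(),
            "first_month": cohesion_report(snapshot_at(net, first_t)).to_dict(),
            "null_comparison": ens.to_dict(),
        }

    def community_stage():
        c = cfg["communities"]
        part = detect_communities(final, resolution=float(c["resolution"]), seed=seed)
        principal = principal_communities(part, coverage=float(c["coverage"]))
        hubs = community_hubs(final, part, community=0,
                              degree_threshold=int(c["hub_degree_threshold"]))
        ranks = centrality_rankings(final, top_n=int(c["top_n"]))
        return {
            "partition": part.to_dict(),
            "principal_communities": principal,
            "largest_community_hubs": hubs,
            "centrality": ranks.to_dict(),
        }

    def window_stage():
        c = cfg["windows"]
        result = select_window_size(net, grid=c["grid"],
                                    degree_threshold=int(c["degree_threshold"]))
        report.selected_w = result.selected
        return result.to_dict()

    def growth_stage():
        c = cfg["growth"]
        step = c["step"]
        if step == "auto":
            step = report.selected_w or 1
            if step >= net.horizon:
                step = max(1, net.horizon // 2)
        kernel = estimate_kernel(net, step=int(step), pooling=c["pooling"],
                                 binning=c["binning"])
        scaling = fit_scaling(net)
        jumps = detect_jumps(scaling, z=float(c["jump_z"]))
        return {
            "kernel": kernel.to_dict(),
            "scaling": scaling.to_dict(),
            "innovation_months": jumps,
            "step": int(step),
        }

    run_stage("input", input_stage)
    run_stage("cohesion", cohesion_stage)
    run_stage("communities", community_stage)
    run_stage("windows", window_stage)
    run_stage("growth", growth_stage)

    report.sections["provenance"] = {
        "config": {k: v for k, v in cfg.items()},
        "version": __version__,
    }
    report.sections["log"] = log_section
    return report


def summarize_growth_table(report: AnalysisReport, w: int | None = None):
    """Per-window growth summary as a pandas DataFrame.

    One row per window end: cumulative N, E, density, clustering,
    diameter, average degree per category, and the fraction of each
    category's ties whose other endpoint is a program attendee (PA).
    Categories absent from the network are omitted.
    """
    import pandas as pd

    from .cohesion import avg_clustering, density, diameter

    net = report.net
    if net is None:
        raise ValueError("report carries no network object")
    w = w or report.selected_w
    if not w:
        raise ValueError("no window size available; pass w explicitly")

    rows = []
    n_windows = -(-net.horizon // w)
    for i in range(1, n_windows + 1):
        t_end = min(i * w, net.horizon)
        g = snapshot_at(net, t_end)
        row = {
            "window": i, "t_end": t_end,
            "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges(),
            "density": density(g), "avg_clustering": avg_clustering(g),
            "diameter": diameter(g),
        }
        by_cat: dict[str, list] = {}
        for node in g.nodes:
            by_cat.setdefault(net.category_of(node), []).append(node)
        for cat, members in sorted(by_cat.items()):
            degs = [g.degree(n) for n in members]
            row[f"avg_degree_{cat}"] = sum(degs) / len(degs)
            ties = pa_ties = 0
            for n in members:
                for nbr in g.neighbors(n):
                    ties += 1
                    if net.category_of(nbr) == "PA":
                        pa_ties += 1
            row[f"pa_tie_frac_{cat}"] = pa_ties / ties if ties else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
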