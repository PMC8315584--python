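"""Attachment-kernel estimation and densification scaling."""

import math

import networkx as nx
import pytest

from cohesionet import (attachment_events, detect_jumps, estimate_kernel,
                        fit_alpha, fit_scaling, from_edges,
                        relative_probability)
from cohesionet.growth import KernelEstimate, ScalingFit
from conftest import net_with_counts


# ---------------------------------------------------------------------------
# independent brute-force event accounting (oracle)

def oracle_events(net, step):
    """Naive per-node recomputation of exposure and gains via snapshots."""
    horizon = net.horizon
    boundaries = list(range(step, horizon + 1, step))
    if boundaries[-1] != horizon:
        boundaries.append(horizon)
    out = []
    for t0, t1 in zip(boundaries, boundaries[1:]):
        g_before = nx.Graph((u, v) for u, v, t in net.edges if t <= t0)
        present = set(g_before.nodes)
        exposure = {}
        for n in present:
            exposure[g_before.degree(n)] = exposure.get(g_before.degree(n), 0) + 1
        gains = {}
        for u, v, t in net.edges:
            if t0 < t <= t1:
                for x in (u, v):
                    if x in present:
                        k = g_before.degree(x)
                        gains[k] = gains.get(k, 0) + 1
        out.append((t0, t1, len(present), exposure, gains))
    return out


def hub_toy():
    """Month 1: star a-{b,c,d}; month 2: a-e (e is new) and b-c."""
    return from_edges([("a", "b", 1), ("a", "c", 1), ("a", "d", 1),
                       ("a", "e", 2), ("b", "c", 2)])


class TestAttachmentEvents:
    def test_toy_exposure_and_gain(self):
        net = from_edges([("a", "b", 1), ("a", "c", 2)])
        (rec,) = attachment_events(net, step=1)
        assert rec.n_nodes == 2
        assert rec.exposure == {1: 2}
        assert rec.gains == {1: 1}  # a gained; newcomer c excluded

    def test_no_new_edges_means_no_gains(self):
        net = from_edges([("a", "b", 1), ("c", "d", 1), ("e", "f", 3)])
        recs = attachment_events(net, step=1)
        assert recs[0].gains == {}

    def test_gains_credited_to_boundary_degree(self):
        # a holds degree 1 at the boundary and gains twice inside the step;
        # both endpoints land in class 1
        net = from_edges([("a", "b", 1), ("a", "c", 2), ("a", "d", 2)])
        (rec,) = attachment_events(net, step=1)
        assert rec.gains == {1: 2}

    def test_step_must_be_below_horizon(self):
        net = from_edges([("a", "b", 1), ("b", "c", 2)])
        with pytest.raises(ValueError):
            attachment_events(net, step=2)

    @pytest.mark.parametrize("step", [1, 2, 3])
    def test_matches_brute_force_oracle(self, step):
        edges = [("a", "b", 1), ("a", "c", 2), ("b", "c", 3), ("c", "d", 3),
                 ("a", "d", 4), ("d", "e", 5), ("e", "f", 6), ("a", "f", 7)]
        net = from_edges(edges)
        got = attachment_events(net, step=step)
        want = oracle_events(net, step=step)
        assert len(got) == len(want)
        for rec, (t0, t1, n, exposure, gains) in zip(got, want):
            assert (rec.t, rec.t_next, rec.n_nodes) == (t0, t1, n)
            assert rec.exposure == exposure
            assert rec.gains == gains


class TestRelativeProbability:
    def test_single_step_hand_values(self):
        # boundary: a deg 3, b/c/d deg 1 (N=4); gains: a one endpoint,
        # b and c one each -> R_3 = (1/3)(4/1), R_1 = (2/3)(4/3)
        est = relative_probability(attachment_events(hub_toy(), step=1))
        by_k = {row["k"]: row for row in est.table}
        assert by_k[3]["p_k"] == pytest.approx(1.0)
        assert by_k[1]["p_k"] == pytest.approx(2 / 3)
        ratio = by_k[3]["r_k"] / by_k[1]["r_k"]
        assert ratio == pytest.approx((4 / 3) / (8 / 9))

    def test_single_step_pooling_orders_coincide(self):
        events = attachment_events(hub_toy(), step=1)
        rs = {}
        for pooling in ("debiased", "per_step", "pooled"):
            est = relative_probability(events, pooling=pooling)
            rs[pooling] = [row["r_k"] for row in est.table]
        # a single step admits no pooling ambiguity (up to normalization)
        for key in ("per_step", "pooled"):
            scale = rs["debiased"][0] / rs[key][0]
            assert rs[key] == pytest.approx([v / scale for v in rs["debiased"]])

    def test_uniform_gains_flatten_the_kernel(self):
        # every present node gains exactly one endpoint in the step
        net = from_edges([("a", "b", 1), ("a", "c", 1),
                          ("b", "c", 2), ("a", "d", 2)])
        est = relative_probability(attachment_events(net, step=1))
        by_k = {row["k"]: row for row in est.table}
        assert by_k[1]["p_k"] == 1.0 and by_k[2]["p_k"] == 1.0
        assert by_k[1]["r_k"] == pytest.approx(by_k[2]["r_k"])


class TestFitAlpha:
    def _table(self, fn, ks=range(1, 11)):
        return KernelEstimate(table=[
            {"k": k, "exposure": 100, "gains": 50, "p_k": 0.5, "r_k": fn(k)}
            for k in ks
        ])

    @pytest.mark.parametrize("binning", ["none", "log"])
    def test_exact_linear_kernel(self, binning):
        est = fit_alpha(self._table(lambda k: float(k)), binning=binning)
        assert est.alpha == pytest.approx(1.0, abs=1e-12)
        assert est.alpha_se == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("binning", ["none", "log"])
    def test_exact_sublinear_kernel(self, binning):
        est = fit_alpha(self._table(lambda k: 3 * k ** 0.5), binning=binning)
        assert est.alpha == pytest.approx(0.5, abs=1e-12)

    def test_regime_classification(self):
        assert fit_alpha(self._table(lambda k: k ** 0.3)).regime == "sublinear"
        assert fit_alpha(self._table(lambda k: k ** 1.7)).regime == "superlinear"

    def test_too_few_degree_classes_rejected(self):
        with pytest.raises(ValueError):
            fit_alpha(self._table(lambda k: float(k), ks=[1, 2]))

    def test_bootstrap_se_available(self):
        est = fit_alpha(self._table(lambda k: k * (1 + 0.01 * (-1) ** k)),
                        n_boot=50, seed=0)
        assert est.alpha_boot_se is not None


class TestFitScaling:
    def test_exact_superlinear(self):
        # Y = 2 N^1.5 at N in {25, 100, 400}
        net = net_with_counts([(25, 250), (100, 2000), (400, 16000)])
        fit = fit_scaling(net)
        assert fit.beta == pytest.approx(1.5, abs=1e-12)
        assert fit.y0 == pytest.approx(2.0, abs=1e-9)
        assert max(abs(r) for r in fit.residuals) < 1e-12

    def test_exact_linear(self):
        net = net_with_counts([(10, 30), (20, 60), (40, 120)])
        assert fit_scaling(net).beta == pytest.approx(1.0, abs=1e-12)

    def test_constant_n_rejected(self):
        net = net_with_counts([(10, 12), (10, 20), (10, 30)])
        with pytest.raises(ValueError):
            fit_scaling(net)


class TestDetectJumps:
    def _fit(self, residuals):
        months = list(range(1, len(residuals) + 1))
        return ScalingFit(months=months, n_nodes=[0] * len(months),
                          n_edges=[0] * len(months), beta=1.0, y0=1.0,
                          beta_se=0.0, residuals=residuals)

    def test_constant_residuals_no_jumps(self):
        assert detect_jumps(self._fit([0.3] * 20)) == []

    def test_single_injected_step_flagged(self):
        resid = [0.0] * 10 + [0.5] * 10
        assert detect_jumps(self._fit(resid)) == [11]

    def test_two_steps_twelve_months_apart(self):
        resid = [0.0] * 5 + [0.6] * 12 + [1.2] * 13
        assert detect_jumps(self._fit(resid)) == [6, 18]

    def test_consecutive_flags_merge(self):
        resid = [0.0] * 10 + [0.5, 1.0] + [1.0] * 8
        assert detect_jumps(self._fit(resid)) == [11]

    def test_short_series_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert detect_jumps(self._fit([0.1, 0.2])) == []


class TestEndToEndRecovery:
    """Small-scale sanity runs; full calibration grids live in the
    acceptance suite."""

    def test_scaling_recovery_on_generator(self):
        from dataclasses import replace
        from cohesionet import SyntheticConfig, generate_growth_network
        cfg = replace(SyntheticConfig(), beta_gen=1.73, seed=3)
        net = generate_growth_network(cfg)
        assert fit_scaling(net).beta == pytest.approx(1.73, abs=0.05)

    def test_kernel_recovery_on_generator(self):
        from dataclasses import replace
        from cohesionet import SyntheticConfig, generate_growth_network
        cfg = replace(SyntheticConfig(), alpha_gen=0.5, seed=4)
        net = generate_growth_network(cfg)
        est = estimate_kernel(net, step=1)
        assert est.alpha == pytest.approx(0.5, abs=0.15)
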