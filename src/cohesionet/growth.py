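"""Attachment-kernel estimation and densification (cohesion) scaling.

Two growth models characterize how a friendship network accretes ties.

**Attachment kernel.**  For each observation step, ``p_k(t)`` is the
probability that the recipient of a new friendship formed between ``t``
and ``t + step`` is a node holding ``k`` ties at ``t``.  Raw ``p_k``
confounds kernel shape with class occupancy and growth timing; the
relative probability

    R_k(t) = p_k(t) * N(t) / n_k(t)

(``N(t)`` nodes present, ``n_k(t)`` of them holding ``k`` ties) is flat
under uniform attachment and proportional to the kernel otherwise.  The
slope alpha of ``log R_k`` against ``log k`` classifies the regime:
alpha < 1 sublinear (stretched-exponential degrees), alpha = 1 linear
(power-law regime), alpha > 1 superlinear (winner-take-all).

**Densification scaling.**  Borrowing the urban-scaling form, cumulative
ties follow ``Y(t) = Y0 * N(t)**beta``; beta > 1 means friendships grow
faster than membership — read as emerging cohesion.  Months where edge
growth jumps above the fitted law (positive residual increments beyond
``mean + z*sd``) are flagged as innovation periods.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .temporal import TemporalNetwork, cumulative_counts

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# attachment events

@dataclass
class StepRecord:
    """Degree-class exposure and gain counts for one step pair (t, t+step).

    ``exposure[k]`` counts nodes present at ``t`` with degree ``k``;
    ``gains[k]`` counts new-tie endpoints acquired during the step by
    nodes that held degree ``k`` at ``t`` (a node gaining three ties
    contributes three, all credited to its boundary-time class).  Nodes
    first appearing inside the step are excluded from exposure (they had
    no degree at ``t``), though the edges they bring still count as
    gains for their already-present partners.
    """

    t: int
    t_next: int
    n_nodes: int
    exposure: dict[int, int]
    gains: dict[int, int]


def attachment_events(net: TemporalNetwork, step: int = 1) -> list[StepRecord]:
    """Per-step degree/gain accounting over consecutive step boundaries.

    Boundaries sit at ``step, 2*step, ...`` (plus the horizon if it is
    not a multiple); each consecutive boundary pair yields one record.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if step >= net.horizon:
        raise ValueError(f"step {step} must be smaller than the horizon {net.horizon}")

    by_month: dict[int, list[tuple[str, str]]] = {}
    for u, v, t in net.edges:
        by_month.setdefault(t, []).append((u, v))

    boundaries = list(range(step, net.horizon + 1, step))
    if boundaries[-1] != net.horizon:
        boundaries.append(net.horizon)

    deg: dict[str, int] = {}
    arrival: dict[str, int] = {}

    def apply_months(lo: int, hi: int, record: StepRecord | None, t0: int) -> None:
        bdeg: dict[str, int] = {}  # boundary-time degree, captured at first touch
        for month in range(lo, hi + 1):
            for u, v in by_month.get(month, ()):
                if record is not None:
                    for x in (u, v):
                        if arrival.get(x, month) <= t0:
                            if x not in bdeg:
                                bdeg[x] = deg[x]
                            k = bdeg[x]
                            record.gains[k] = record.gains.get(k, 0) + 1
                for x in (u, v):
                    if x not in deg:
                        deg[x] = 0
                        arrival[x] = month
                deg[u] += 1
                deg[v] += 1

    apply_months(1, boundaries[0], None, 0)
    records: list[StepRecord] = []
    for t0, t1 in zip(boundaries, boundaries[1:]):
        record = StepRecord(
            t=t0, t_next=t1, n_nodes=len(deg),
            exposure=dict(Counter(deg.values())), gains={},
        )
        apply_months(t0 + 1, t1, record, t0)
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# relative probability and the kernel fit

@dataclass
class KernelEstimate:
    """Pooled R_k table and (after fitting) the kernel slope alpha."""

    table: list[dict] = field(default_factory=list)  # rows: k, exposure, gains, p_k, r_k
    step: int = 1
    pooling: str = "per_step"
    alpha: float | None = None
    alpha_se: float | None = None
    alpha_boot_se: float | None = None
    binning: str | None = None
    bins: list[dict] = field(default_factory=list)

    @property
    def regime(self) -> str | None:
        if self.alpha is None:
            return None
        if self.alpha < 1:
            return "sublinear"
        if self.alpha > 1:
            return "superlinear"
        return "linear"

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_se": self.alpha_se,
            "regime": self.regime,
            "step": self.step,
            "pooling": self.pooling,
            "binning": self.binning,
            "n_degree_classes": len(self.table),
            "table": self.table,
        }


def _debiased_weights(events: list[StepRecord], n_iter: int = 200,
                      tol: float = 1e-10) -> dict[int, float]:
    """Self-consistent kernel weights with per-step rate effects.

    Model: gains to class k in step t are proportional to
    ``G(t) * n_k(t) * w(k) / W(t)`` with ``W(t) = sum_j n_j(t) w(k_j)``.
    The fixed-point iteration ``w(k) <- sum_t g_k / sum_t G n_k / W``
    is the maximum-likelihood solution; the per-step ``W(t)`` absorbs
    the time-varying global attachment rate, so classes populated only
    late in the growth are not deflated relative to early ones.  For a
    single step this reduces exactly to the plain relative probability.
    """
    steps = [rec for rec in events if sum(rec.gains.values()) > 0]
    ks = sorted({k for rec in events for k in rec.exposure})
    w = {k: 1.0 for k in ks}
    tot_gains = {k: sum(rec.gains.get(k, 0) for rec in steps) for k in ks}
    for _ in range(n_iter):
        denom = {k: 0.0 for k in ks}
        for rec in steps:
            g_total = sum(rec.gains.values())
            big_w = sum(n_k * w[k] for k, n_k in rec.exposure.items())
            for k, n_k in rec.exposure.items():
                denom[k] += g_total * n_k / big_w
        new_w = {k: (tot_gains[k] / denom[k] if denom[k] > 0 else 0.0) for k in ks}
        # normalize: exposure-weighted mean weight = 1
        tot_exp = sum(sum(rec.exposure.values()) for rec in steps)
        scale = sum(sum(n_k * new_w[k] for k, n_k in rec.exposure.items())
                    for rec in steps) / tot_exp
        new_w = {k: v / scale for k, v in new_w.items()}
        delta = max(abs(new_w[k] - w[k]) for k in ks)
        w = new_w
        if delta < tol:
            break
    return w


def relative_probability(events: list[StepRecord],
                         pooling: str = "debiased") -> KernelEstimate:
    """Pool per-step R_k(t) into one table, exposure-weighted.

    ``p_k(t)`` is the probability that the recipient of a new friendship
    holds ``k`` ties — the class share ``gains_k(t) / sum_j gains_j(t)``
    of nodes establishing a new tie in the step.  Normalizing by the
    class's relative size, ``R_k(t) = p_k(t) * N(t) / n_k(t)``, removes
    the growth-timing bias: under purely uniform attachment every class
    receives new ties in proportion to its occupancy and R_k is flat,
    while a kernel ``w(k)`` yields ``R_k`` proportional to ``w(k)``.
    (Reading ``p_k`` instead as a per-node event rate would make the
    ``N/n_k`` correction itself inject a spurious positive slope.)

    ``pooling="debiased"`` (default) solves the self-consistent
    step-effect model of :func:`_debiased_weights`, which additionally
    absorbs the declining global attachment rate of a densifying
    network (classes only populated late would otherwise be deflated).
    ``pooling="per_step"`` applies the correction inside each step and
    averages steps with exposure weights; ``pooling="pooled"`` pools the
    class share first and multiplies by the mean correction factor.
    All three coincide for a single step.  Large per_step/pooled gaps
    are logged.
    """
    if not events:
        raise ValueError("no attachment events")
    if pooling not in ("debiased", "per_step", "pooled"):
        raise ValueError(f"unknown pooling {pooling!r}")
    debiased = _debiased_weights(events) if pooling == "debiased" else None

    tot_exposure: dict[int, int] = {}
    tot_gains: dict[int, int] = {}
    weighted_rk: dict[int, float] = {}   # sum_t n_k(t) * R_k(t) = sum_t g_k/G * N
    sum_g_total: dict[int, int] = {}     # sum_t G(t) over steps where class k exists
    sum_n_total: dict[int, int] = {}     # sum_t N(t) over those steps
    any_gain = False
    for rec in events:
        g_total = sum(rec.gains.values())
        any_gain = any_gain or g_total > 0
        for k, n_k in rec.exposure.items():
            g = rec.gains.get(k, 0)
            tot_exposure[k] = tot_exposure.get(k, 0) + n_k
            tot_gains[k] = tot_gains.get(k, 0) + g
            if g_total:
                weighted_rk[k] = weighted_rk.get(k, 0.0) + g / g_total * rec.n_nodes
                sum_g_total[k] = sum_g_total.get(k, 0) + g_total
                sum_n_total[k] = sum_n_total.get(k, 0) + rec.n_nodes
    if not any_gain:
        raise ValueError("no step recorded any new tie")

    table = []
    for k in sorted(tot_exposure):
        n_k = tot_exposure[k]
        g = tot_gains[k]
        r_per_step = weighted_rk.get(k, 0.0) / n_k
        # pooled order: class share pooled across steps, then the mean
        # exposure correction sum N / sum n_k
        if sum_g_total.get(k):
            r_pooled = (g / sum_g_total[k]) * (sum_n_total[k] / n_k)
        else:
            r_pooled = 0.0
        if g and r_per_step > 0 and r_pooled > 0 and \
                abs(math.log(r_per_step) - math.log(r_pooled)) > 0.2:
            logger.debug("pooling orders differ at k=%d: %.4g vs %.4g",
                         k, r_per_step, r_pooled)
        if pooling == "debiased":
            r_k = debiased.get(k, 0.0)
        elif pooling == "per_step":
            r_k = r_per_step
        else:
            r_k = r_pooled
        table.append({
            "k": k, "exposure": n_k, "gains": g,
            "p_k": g / n_k,
            "r_k": r_k,
        })
    return KernelEstimate(table=table, pooling=pooling)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and slope SE of y on x."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate fit: no spread in the predictor")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = float(ym - slope * xm)
    if n > 2:
        resid = y - (intercept + slope * x)
        s2 = float((resid ** 2).sum()) / (n - 2)
        se = math.sqrt(s2 / sxx)
    else:
        se = 0.0
    return slope, intercept, se


def _log_bins(ks: np.ndarray, rs: np.ndarray, weights: np.ndarray,
              factor: float = 2.0) -> list[dict]:
    """Weighted geometric binning of (k, R_k) points.

    Bin edges grow by ``factor`` starting at the smallest k; within a bin
    the representative point is the weighted mean of (log k, log R).
    Sparse high-degree classes are thereby stabilized.
    """
    bins: list[dict] = []
    lo = float(ks.min())
    k_max = float(ks.max())
    while lo <= k_max:
        hi = lo * factor
        mask = (ks >= lo) & (ks < hi)
        if mask.any():
            w = weights[mask]
            bins.append({
                "k_lo": lo, "k_hi": hi,
                "log_k": float(np.average(np.log(ks[mask]), weights=w)),
                "log_r": float(np.average(np.log(rs[mask]), weights=w)),
                "weight": float(w.sum()),
            })
        lo = hi
    return bins


def fit_alpha(estimate: KernelEstimate, binning: str = "log",
              n_boot: int = 0, seed: int = 0) -> KernelEstimate:
    """Fit the kernel slope alpha of log R_k against log k.

    ``binning="log"`` (default) pools degree classes into geometric bins
    before the least-squares fit, which tames the sparse high-degree
    tail; ``binning="none"`` fits the raw classes.  Requires >= 3 usable
    points.  With ``n_boot > 0`` a case-resampling bootstrap SE over
    degree classes is reported alongside the analytic fit SE.
    """
    if binning not in ("none", "log"):
        raise ValueError(f"unknown binning {binning!r}")
    rows = [r for r in estimate.table if r["k"] > 0 and r["r_k"] > 0]
    if len({r["k"] for r in rows}) < 3:
        raise ValueError("need >= 3 distinct degree classes with positive R_k")
    ks = np.array([r["k"] for r in rows], dtype=float)
    rs = np.array([r["r_k"] for r in rows], dtype=float)
    # gains-based precision weights: var(log r_k) ~ 1/gains for counts
    ws = np.array([max(r["gains"], 1) for r in rows], dtype=float)

    if binning == "log":
        bins = _log_bins(ks, rs, ws)
        if len(bins) < 3:
            logger.warning("too few log bins (%d); falling back to unbinned fit", len(bins))
            binning, bins = "none", []
    else:
        bins = []

    if binning == "log":
        x = np.array([b["log_k"] for b in bins])
        y = np.array([b["log_r"] for b in bins])
    else:
        x, y = np.log(ks), np.log(rs)

    alpha, _, se = _ols(x, y)
    estimate.alpha, estimate.alpha_se = alpha, se
    estimate.binning, estimate.bins = binning, bins

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = len(x)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if len(set(x[idx])) < 2:
                continue
            b, _, _ = _ols(x[idx], y[idx])
            boots.append(b)
        if boots:
            estimate.alpha_boot_se = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0
    return estimate


def estimate_kernel(net: TemporalNetwork, step: int = 1,
                    pooling: str = "debiased", binning: str = "log") -> KernelEstimate:
    """Convenience: events -> pooled R_k -> fitted alpha in one call."""
    est = relative_probability(attachment_events(net, step=step), pooling=pooling)
    est.step = step
    return fit_alpha(est, binning=binning)


# ---------------------------------------------------------------------------
# densification scaling

@dataclass
class ScalingFit:
    """OLS fit of ln Y(t) on ln N(t) over monthly cumulative counts."""

    months: list[int]
    n_nodes: list[int]
    n_edges: list[int]
    beta: float
    y0: float
    beta_se: float
    residuals: list[float]  # per fitted month, ln Y - (ln Y0 + beta ln N)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "y0": self.y0,
            "beta_se": self.beta_se,
            "n_months_fit": len(self.months),
        }


def fit_scaling(net: TemporalNetwork) -> ScalingFit:
    """Fit ``Y(t) = Y0 * N(t)**beta`` by OLS in natural-log space.

    Uses monthly *cumulative* node and edge counts; months with fewer
    than 2 nodes or no edges are excluded.  Raises when N never varies.
    """
    counts = [(t, n, e) for t, n, e in cumulative_counts(net) if n >= 2 and e >= 1]
    if len(counts) < 3:
        raise ValueError("need >= 3 months with at least 2 nodes and 1 edge")
    months = [t for t, _, _ in counts]
    ns = np.array([n for _, n, _ in counts], dtype=float)
    es = np.array([e for _, _, e in counts], dtype=float)
    if ns.min() == ns.max():
        raise ValueError("node count is constant; scaling exponent undefined")
    x, y = np.log(ns), np.log(es)
    beta, intercept, se = _ols(x, y)
    resid = (y - (intercept + beta * x)).tolist()
    return ScalingFit(
        months=months, n_nodes=[int(n) for n in ns], n_edges=[int(e) for e in es],
        beta=beta, y0=float(math.exp(intercept)), beta_se=se, residuals=resid,
    )


def detect_jumps(fit: ScalingFit, z: float = 2.0) -> list[int]:
    """Months whose residual *increment* exceeds mean + z*sd of all
    increments; consecutive flagged months merge into one (the first).

    These are the innovation periods: intervals where tie growth
    outpaces the fitted scaling law.
    """
    resid = np.asarray(fit.residuals)
    if len(resid) < 3:
        logger.warning("fewer than 3 residuals; no jump detection possible")
        return []
    inc = np.diff(resid)
    threshold = float(inc.mean() + z * inc.std())
    if inc.std() == 0:
        return []
    flagged = [fit.months[i + 1] for i in range(len(inc)) if inc[i] > threshold]
    # keep the first month of each consecutive run
    merged: list[int] = []
    prev = None
    for month in flagged:
        if prev is None or month > prev + 1:
            merged.append(month)
        prev = month
    return merged
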