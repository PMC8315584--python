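# Methods

This note documents the models implemented in `cohesionet`, the design
choices made where the method descriptions left the design open, the
numerical conventions, and what the synthetic generator does and does
not emulate.

## Data model

A temporal network is a set of undirected friendship edges `(u, v, t)`
with `t` a 1-based month index, plus optional node attributes (category
in {PA, FI, AI, CH}, sex). Conventions:

* **Month granularity.** Finer timestamps are truncated to the month;
  calendar stamps `YYYY-MM` are mapped to indices relative to the
  earliest stamp (or an explicit origin).
* **Unique starting date.** Duplicate pairs keep the earliest month: a
  friendship begins once. Self-loops are rejected.
* **Arrival = first edge.** The data carry no independent join date, so
  a node exists from the month of its first tie; never-connected nodes
  are not members of any snapshot.
* **Windows** are 1-based and left-open/right-closed in month index:
  window *i* of size *w* holds months `((i−1)w, iw]`. The final partial
  window is retained, so a 98-month horizon at `w = 20` yields exactly 5
  windows (4×20 + 18).

## Cohesion metrics and the null ensemble

Density is `2E/(N(N−1))`; average clustering is the mean local
clustering with degree-<2 nodes contributing 0 (one of the two common
conventions, stated here because it changes the average); the diameter
is computed on the largest connected component, since a single isolate
would otherwise make it infinite.

The null model preserves the degree sequence exactly: each replicate
applies `10·E` double-edge-swap attempts (two random edges `(u,v)`,
`(x,y)` rewired to `(u,x)`, `(v,y)` unless that would create a loop or
multi-edge). Swaps are preferred over stub matching because they keep
the graph simple by construction, matching "same size and degree
distribution" literally. Significance is reported as the observed
value's mid-rank empirical percentile among the null values — not a
parametric p-value, which the small ensemble would not support. Density
is conserved by the swaps, so its percentile is 50 by construction and
serves as an internal check.

## Community structure

Louvain greedy modularity maximization (networkx implementation,
seeded; resolution 1 by default) with labels renumbered so community 0
is always the largest. Principal communities are the smallest prefix of
size-sorted communities whose cumulative share reaches the coverage
target (boundary inclusive). Hubs are community members whose
*whole-graph* degree strictly exceeds the threshold (default 300); note
this is within-network degree, not the members' global friend counts on
the platform, which the data do not contain.

Centralities: degree, betweenness, classic geodesic closeness computed
within each node's component (not the harmonic variant), k-core number,
and PageRank (damping 0.85, tolerance 1e−9). All rankings break ties by
node id so results are deterministic; top-n overlap (default n = 10) is
Jaccard on the top sets.

## Window-size selection

For each candidate `w`, the statistic `f(G_i)` is the average shortest
path length on the largest connected component of the *within-window*
graph `G_i` (a window with fewer than two connected nodes yields an
undefined entry). `V(F_w)` is the population variance of the defined
entries.

`R(F_w)` is defined here as the ratio of defined-entry counts between
the full-graph series and the series of the high-degree core (nodes
whose cumulative degree at the window's end strictly exceeds the
threshold, default 100). **This is a reconstruction** — the largest one
in the package. Taken literally, "length of F_w divided by length of
F_w*" is identically 1 because both series span T windows; counting
*defined* entries is the reading under which the ratio measures
anything (how often the persistent core is active per window). The
original window-selection literature uses an information-theoretic
compression ratio; that variant is deliberately not implemented.

`V` and `R` are min–max normalized across the candidate grid before the
objective `|V_norm − R_norm|` is taken — raw variance (squared path
lengths) and a dimensionless ratio are otherwise incommensurable. Ties
select the smallest `w`. If the core series is empty for some `w`, the
ratio falls back to the full series' defined count with a warning.

## Attachment kernel

`attachment_events` walks step boundaries (`step, 2·step, …`, plus the
horizon) and records, per boundary-degree class `k`: the exposure
`n_k(t)` (nodes present with degree `k`) and the gains `g_k(t)`
(new-tie endpoints acquired during the step by those nodes, with
multiplicity, credited to the boundary-time class). Nodes first
appearing inside a step are excluded from that step's exposure — they
had no degree at the boundary — though the ties they bring count as
gains for their already-present partners.

`p_k(t) = g_k(t)/Σ_j g_j(t)` is the class share of new-tie recipients,
and the relative probability `R_k(t) = p_k(t)·N(t)/n_k(t)` normalizes
by relative class size: flat under uniform attachment, proportional to
the kernel otherwise. (Reading `p_k` instead as a per-node event rate
would make the `N/n_k` factor itself inject a spurious positive slope —
a uniform-attachment network would appear preferential.)

Pooling across steps matters in a densifying network: the per-node
attachment rate falls over time, so high-degree classes — which exist
only late — would be deflated by naive averaging. The default pooling
is therefore a self-consistent step-effect estimator: iterate

    w(k) ← Σ_t g_k(t) / Σ_t G(t)·n_k(t)/W(t),   W(t) = Σ_j n_j(t)·w(k_j)

to its fixed point (the maximum-likelihood solution of the multinomial
step model), normalized to exposure-weighted mean 1. For a single step
this reduces exactly to the plain `R_k`. The simple exposure-weighted
per-step average and the pooled-share variant remain available as
`pooling="per_step"` / `"pooled"`.

`fit_alpha` fits `log R_k` on `log k` by least squares, by default
after geometric (factor-2) binning with gains-based precision weights
(`var(log count) ≈ 1/count`), which stabilizes the sparse high-degree
tail; the analytic slope SE is reported, with an optional
case-resampling bootstrap SE. How the uncertainty on α "should" be
computed is not settled by the method description, so both are exposed
without claiming either is canonical. α < 1 is classified sublinear,
α = 1 linear, α > 1 superlinear.

## Densification scaling and innovation periods

`fit_scaling` regresses `ln Y(t)` on `ln N(t)` over *monthly cumulative*
counts (months with ≥2 nodes and ≥1 edge), returning `(Y0, β)`, the
slope SE and per-month residuals. The fit is exact on noise-free
power-law inputs. Note that a two-point fit on the endpoint counts
(43→272 nodes, 55→2565 edges) gives β = ln(2565/55)/ln(272/43) ≈ 2.08 —
materially different from what a full monthly series can produce, which
is why the estimator insists on the series.

Innovation periods are months whose month-over-month residual
*increment* exceeds `mean + z·sd` of all increments (z = 2 by default,
exposed because visual identification of jumps has no canonical
threshold); consecutive flagged months merge into the first of the run.
Fewer than three residuals yield an empty list with a warning.

## Synthetic generator

`generate_growth_network` emulates the observable shape of a community
program's friendship network: monthly arrivals (fractional rates
accumulate to integers), cumulative edges tracking
`round(e_init·(N/n_init)^beta_gen)`, and partner choice with weight
`hub_bias_factor·(k + c)^alpha_gen`. Month 1 lays down a connected seed
(uniform random recursive tree plus uniform extra edges). Each arrival
joins by one kernel-chosen edge; the remaining monthly budget is spent
on edges whose first endpoint is drawn exactly kernel-proportionally
and whose partner is kernel-drawn among that endpoint's non-neighbors.
Rejecting whole pairs instead would under-sample hubs once they are
connected to much of the high-weight mass — a simple-graph artifact
that would bias kernel recovery downward.

Defaults are the study-shaped conditions: 98 months, 43 nodes / 55
edges initially, 229 arrivals (272 final), `alpha_gen = 0.5`,
`beta_gen = 1.73`, category mix PA 0.55 / FI 0.12 / AI 0.21 / CH 0.12
(instructors ≈ 21% of profiles). The kernel offset `c` defaults to 0:
every node in this process holds at least one tie from the month it
appears, so the usual reachability rationale for an offset does not
apply, and an offset would curve the log–log relation the estimator
fits. `hub_bias` (multiplicative weight for AI nodes) defaults to 1 so
the default kernel is homogeneous — a category bias is a *confound* for
kernel-exponent recovery, which is exactly what the default
configuration is used to validate. The `program_preset()` variant sets
`hub_bias = 3` (instructors are the most connected profiles in such
programs) and `beta_gen ≈ 2.083`, the endpoint-implied exponent, so the
expected final size lands on 272 nodes / 2565 edges.

What the generator does **not** emulate: triadic closure (its
clustering therefore sits at or below degree-preserving nulls, unlike
real friendship networks), degree assortativity, seasonal or bursty
edge arrival within months, member departure, and any coupling between
categories and community structure beyond the AI hub bias. Passing
recovery tests therefore demonstrates estimator correctness under the
stated growth model, not that real data will be as well behaved.

`generate_planted_partition` wraps a stochastic block model with
ground-truth labels for community-detection benchmarks.

## Validation scales

The test suite validates at these problem sizes, chosen to give the
estimators adequate statistics while keeping a full run on one CPU in
minutes: linear-kernel calibration on 20 replicates of 5000-node
growth with 2 edges per arrival (mean α within 0.15 of 1); kernel
recovery at the 272-node defaults over 10 replicates per
`alpha_gen ∈ {0, 0.5, 1}` (tolerance 0.15) and scaling recovery per
`beta_gen ∈ {1.0, 1.73}` (tolerance 0.1); 100-replicate null ensembles;
and brute-force oracle equivalence for window selection and event
accounting on networks of ≤ 50 nodes.

## Known limitations

* The compress-ratio definition is a reconstruction (above); on
  synthetic networks whose core is active in every window it is nearly
  constant and the selection is then driven by the variance term alone,
  which favors large windows (the preset run selects `w* = 98`).
* The kernel estimator measures the *effective* attachment propensity;
  heterogeneity (e.g. instructor hub bias) is absorbed into the slope
  and cannot be separated from the degree dependence without node-level
  covariates.
* Under strong densification, very-high-degree classes saturate (a hub
  cannot befriend members it already knows); gains-weighted binning
  limits but does not eliminate the resulting attenuation — recovered α
  at `alpha_gen = 1` averages ≈ 0.86 at the default scale.
* Diameter-on-LCC is a convention, not the only choice; on graphs with
  large disconnected parts the reported diameter describes the core
  only (the `lcc_fraction` field says how much that is).
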