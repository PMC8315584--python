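# cohesionet

Temporal social-network cohesion analysis for program evaluation.

Community-based health and physical-activity programs leave a digital
trace: the online friendship network of their attendees, instructors and
institutional staff. `cohesionet` treats that trace as a *temporal*
network — undirected friendship edges stamped with the month each tie
began — and asks whether the program is building social cohesion over
time. It is a library first (importable API plus `examples/`), with a
thin CLI for the common file-in/report-out workflow.

## What it computes

Given a timestamped edge table (and optionally a node table labelling
members as program attendees PA, fitness industry FI, activity
instructors AI, or city-hall staff CH):

1. **Cohesion metrics with randomized nulls.** Density `2E/(N(N−1))`,
   diameter (on the largest component) and average clustering, each
   located within an ensemble of degree-preserving random graphs
   (double-edge-swap configuration model) as an empirical percentile.
2. **Community structure.** Louvain modularity communities, the
   principal communities covering a target share of nodes, high-degree
   community hubs, and seed-node rankings under five centralities
   (degree, betweenness, closeness, k-core, PageRank) with their top-n
   Jaccard overlaps.
3. **Time-window resolution.** For each candidate window size *w* the
   timeline is cut into `T = ceil(horizon/w)` windows and the
   average-shortest-path series `F_w = [f(G_1), …, f(G_T)]` is scored by
   its variance `V(F_w)` (oversampling noise) and compress ratio
   `R(F_w)` (redundancy against the high-degree core); the selected `w*`
   minimizes the normalized `|V − R|`.
4. **Growth models.** The attachment kernel via the relative probability

       R_k(t) = p_k(t) · N(t) / n_k(t)

   where `p_k(t)` is the probability that the recipient of a new
   friendship held `k` ties at `t`; the log–log slope α classifies
   attachment as sublinear (α<1), linear (α=1) or superlinear (α>1).
   And the densification scaling law

       Y(t) = Y0 · N(t)^β

   fitted by OLS in log space over monthly cumulative counts; β>1 means
   friendships grow faster than membership ("emerging cohesion"), and
   months where edge growth jumps above the fitted law are flagged as
   innovation periods.
5. **Synthetic data.** A growth generator with known attachment exponent
   `alpha_gen`, densification exponent `beta_gen`, category mix and
   instructor hub bias, so every estimator can be validated by parameter
   recovery; plus a planted-partition benchmark for community detection.

## Worked example

```python
from cohesionet import run_full, summarize_growth_table

report = run_full({"simulate": {"preset": "program"}, "seed": 1})
```

The `program` preset generates a 98-month network shaped like a
three-location community program's profile: 43 members / 55 friendships
in month 1 growing to 272 / 2565. The run prints (see
`examples/06_full_pipeline.py`):

```
input: 272 nodes, 2565 edges, 98 months
categories: {'AI': 61, 'CH': 27, 'FI': 27, 'PA': 157}
final cohesion: density 0.070, diameter 5, clustering 0.377
alpha = 0.51, beta = 2.08, innovation months [3, 5, 7, 14]
 window  n_nodes  n_edges  density
      1       87      239 0.063887
      2      135      596 0.065893
      3      182     1111 0.067452
      4      229     1792 0.068643
      5      272     2565 0.069595
```

Reading the numbers: density 0.070 is the realized share of all possible
friendships; α = 0.51 recovers the preset's sublinear kernel — new ties
do *not* concentrate on the most popular members; β = 2.08 matches the
preset's endpoint-implied densification (each new member arrives with
ever more friendships than the last), the super-linear signature of
growing cohesion.

Each capability also has a narrative script under `examples/`, and the
same stages are exposed as CLI subcommands:

```sh
cohesionet simulate --preset program --seed 1 --out edges.csv --nodes nodes.csv
cohesionet metrics edges.csv --nodes nodes.csv
cohesionet windows edges.csv --grid 5,10,20,50
cohesionet attachment edges.csv --step 1
cohesionet scaling edges.csv
cohesionet run config.yaml --out report.json
```

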