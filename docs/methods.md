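# Methods

## The object of study

At a single extraction instant a hospital's inpatient service defines a
bipartite graph `G = (W ∪ U, E)`: ward nodes `W`, clinical-unit nodes `U`,
and an unweighted edge `(w, u)` iff at least one current inpatient is under
unit `u` while lying in ward `w`. Only the links present at the instant of
extraction are recorded — the construction is not cumulative — so a monthly
series of snapshots captures how the delivery structure breathes. Snapshot
graphs can be unioned into calendar-period composites, and rebuilt from only
emergency- or only elective-designated admissions ("subtraction" graphs).
Isolated rostered wards/units (no current patients) are excluded: a degree-0
node contributes nothing to the adjacency matrix and its modularity term is
undefined under Louvain. The per-edge patient count is retained as
`edge_support` but all default analyses are binary, undirected.

## Modularity and Louvain

Community quality is standard Newman–Girvan modularity on the bipartite
graph treated as an ordinary undirected graph,

    Q = Σ_c [ L_c/m − γ·(D_c/2m)² ],

with resolution γ = 1 by default. This is deliberately *not* a
bipartite-specific (Barber) modularity: the mainstream tooling this package
interoperates with computes the ordinary form, and published hospital Q
values reflect it.

The Louvain implementation is the classical two-phase greedy scheme:

1. *Local moving.* Nodes are visited in a seeded random order (reshuffled
   each pass). A node moves to the neighbouring community with the largest
   positive modularity gain; gains are compared with tolerance 1e-9 and ties
   keep the current community (minimising churn). Passes repeat until no
   node moves.
2. *Aggregation.* Communities collapse to super-nodes (intra-community
   weight becomes a self-loop), and phase 1 repeats on the aggregate, until
   no level improves Q.

The run is deterministic given the seed. Correctness is checked three ways:
analytic cases (one community ⇒ Q = 0; two disconnected equal blocks ⇒
Q = 0.5), term-by-term and matrix-form oracles, agreement with networkx's
independent implementation, and an exhaustive optimal-partition oracle
(restricted-growth-string enumeration of all set partitions, vectorised
scoring, feasible to 12 nodes) that Louvain must never exceed and almost
always attains on small graphs.

A bipartite random-graph null (m edges placed uniformly among the
`|W|·|U|` possible pairs) gives the distribution of Louvain Q under "nodes
connect at random"; observed graphs are compared against its 99th
percentile and empirical z-score.

## Temporal tracking and coherence classification

Louvain runs independently per snapshot, so module identity across months is
established post hoc by **marker pairs**: ward–unit combinations observed as
an edge at least once, ranked by their co-membership rate (fraction of
snapshots in which both nodes are present and share a community). Selection
is greedy by descending rate (ties lexicographic), subject to a
distinctness constraint — two selected markers may not share a community in
more than 20% of snapshots — so each marker tracks a different module. This
reconstruction uses only the already-computed partitions, is deterministic,
and degrades gracefully when modules merge or split.

A marker's module size at a snapshot is the node count of the community
containing *both* marker nodes; the slot is masked when either node is
absent or the two separate. The coefficient of variation of the size series
(sample sd, n−1, over present slots; switchable) classifies modules by a
strict threshold: `cv < 0.2` ⇒ high coherence, else general. The threshold
value, the strictness of the inequality, and node-count (rather than
patient-count) sizing follow the published analysis convention.

## Degree-distribution comparison

Node degrees (wards and units pooled) are binned at constant width 0.99
starting from the minimum degree and normalized to a density
(Σ density·width = 1). Two-parameter families — Weibull (shape k, scale λ,
location fixed at 0) and normal (μ, σ) — are fitted by nonlinear least
squares between the family pdf at bin centres and the observed densities,
from method-of-moments starts (Weibull: k ≈ (mean/sd)^1.086,
λ = mean/Γ(1+1/k)); fitting densities rather than counts is the only scale
on which published MSE magnitudes (~1e-4) are plausible. The preferred
family is the smaller MSE (within 1e-12: indeterminate). A log-log plotting
helper is provided for eyeballing tail behaviour; no formal power-law
inference is attempted, as that inference is contested methodological
territory.

## Congestion analysis

The congestion surrogate is the delayed-placement count: patients accepted
for admission but without an inpatient bed at midnight of the extraction
date. Three Pearson correlations are reported against per-snapshot
modularity: (1) the full graph, (2) the graph with the high-coherence
modules' communities removed and Louvain re-run on the residual
(recomputation, not rescoring of the frozen partition — exclusion changes
the achievable community structure), and (3) the same exclusion on
emergency-only subtraction graphs, reusing the markers selected on full
data. p-values are two-sided t-tests with n−2 df (scipy). Correlations are
reported *signed*: the substantive finding — disorganisation lowering
modularity while raising congestion — appears as r < 0, and
association-strength statements refer to |r|. Snapshots where exclusion
empties the residual graph (possible in extreme months on subtraction
graphs) are masked from the affected variant rather than aborting the run.

## The synthetic hospital

Real extracts are private, so all end-to-end behaviour is demonstrated on a
generator whose defaults describe one fixed "stated world":

* 8 planted modules — 3 **stable** (specialty: think mental health, women's
  health, geriatric assessment) and 5 **general** medical/surgical — each
  with 4 wards and 5 units (32 wards, 40 units: a mid-sized hospital);
* 360 patients per snapshot, 21 monthly snapshots (a full calendar year
  plus nine months), emergency fraction 0.65;
* each patient draws a home module uniformly; with probability
  `1 − cross_rate` both ward and unit are from it. The cross rate starts at
  `p_cross_base = 0.02` and is capped at `1 − p_within = 0.35`;
* **general-module disorganisation**: a fixed per-snapshot series d(t) in
  [0.1, 0.9] interpolates the general modules' cross rate toward the cap.
  Cross stays are mostly *boarded*: the home unit keeps the patient but the
  ward is drawn from the module's persistent ranked escalation list of six
  overflow wards, boarding spreading deeper down the list as d rises (the
  physical signature of bed pressure). A 15% remainder is diffuse
  consult-style linkage over persistent ward–unit pairs;
* **specialty volatility**: stable modules' cross rate moves along the same
  cap, but driven by an independent shared monthly uniform draw scaled by
  `stable_cross_volatility = 0.5`, and realised *only* as diffuse consult
  pairs spread thinly across the general modules. Specialty wards are
  protected (they never host boarded patients) and specialty silos do not
  link each other, so specialty communities neither accrete nor merge —
  their tracked cv stays well under 0.2 — while their fluctuating linkage
  adds congestion-*unrelated* variance to full-graph modularity. This is
  exactly the structure that makes excluding the high-coherence modules
  sharpen the modularity–congestion correlation, as an emergent property
  rather than an identity;
* **congestion read-out**:
  `delayed(t) = round(max(0, 8 + 15·d(t) + N(0, 1.5)))`, spanning roughly
  9–24 patients. Congestion is driven by the latent dial, never by
  modularity itself.

Everything is deterministic given the config seed. What the generator does
*not* emulate: length-of-stay dynamics, patient-level clinical attributes,
diagnostic-service nodes, inter-hospital differences in recording (live
location vs at-discharge), and any causal pathway from structure to
congestion — a green test establishes that the pipeline recovers planted
structure and designed couplings, not that real hospitals behave this way.

Recoverability (exact ARI = 1 Louvain recovery of the planted membership at
`p_within ≥ 0.95, p_cross_base ≤ 0.01`) is assessed at d = 0: the
disorganisation dial exists precisely to destroy the planted organisation,
and concentrated boarding can legitimately flip a ward's allegiance at
moderate d.

## Numerical choices and degenerate inputs

* Louvain gain tolerance 1e-9; tie-breaks keep the current community;
  community ids canonicalised to 0.. in sorted-node first-appearance order.
* Brute force ties: fewest communities, then lexicographically smallest
  membership string.
* Modularity on an edgeless graph, cv on < 2 present values or zero mean,
  and Pearson on constant series are errors, not silent values.
* Degree fits require ≥ 3 non-empty bins; a single-spike histogram raises a
  fit error.
* Monte-Carlo checks in the test suite reuse expensive intermediate series
  where statistically valid: the null-calibration check pairs 100
  excluded-modularity series (whose distribution does not depend on the
  congestion slope) with 2000 independent noise draws, keeping the suite
  fast without biasing the rejection rate.

## Known limitations

* Marker-based tracking assumes at least one ward–unit edge recurs within
  each real module; a module that is re-wired wholesale between months
  cannot be tracked.
* Ordinary (not bipartite) modularity slightly favours balanced communities
  and has the usual resolution limit; the resolution parameter is exposed
  but fixed at 1.0 for all reported analyses.
* The Weibull/normal comparison is a descriptive shape contrast on binned
  densities, not a goodness-of-fit test.
* With 21 monthly snapshots, correlation estimates carry wide confidence
  intervals; signs and orderings, not magnitudes, are the reproducible
  content.
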