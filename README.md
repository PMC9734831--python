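# wardnet

Network analysis of hospital inpatient care delivery.

Hospitals deliver inpatient care through the interplay of two kinds of
organisational units: **wards** (physical locations with geographically based
nursing staff) and **clinical units** (specialty teams of doctors and allied
health responsible for diagnosis and care planning). A monthly snapshot of a
hospital's patient administrative data induces an undirected, unweighted
**bipartite graph**: an edge links ward *w* to unit *u* whenever at least one
current inpatient is under unit *u* while located in ward *w*. The modular
structure of these graphs — specialty services forming tight, stable modules;
general medical/surgical services forming looser, variable ones — and its
relationship to hospital congestion are the subject of this package. It is
aimed at health-services researchers and hospital analysts with access to
routine administrative extracts; since such extracts are private, a seeded
synthetic generator with planted structure stands in for them everywhere.

## What it computes

* **Graph construction** — per-snapshot bipartite graphs from stay records,
  calendar-period composites (edge unions), and emergency-only /
  elective-only "subtraction" graphs.
* **Community detection** — Newman modularity

  `Q = Σ_c [ L_c/m − (D_c/2m)² ]`

  (m edges, L_c intra-community edges, D_c community degree sum) and the
  Louvain algorithm, both implemented from scratch; a brute-force
  optimal-partition oracle for graphs of ≤ 12 nodes; a bipartite
  Erdős–Rényi null model for testing whether observed modularity could be
  random.
* **Temporal tracking** — recurring ward–unit *marker pairs* link "the same"
  module across independently partitioned snapshots; each tracked module's
  node-count series gives a coefficient of variation `cv = sd/mean`, and
  modules with `cv < 0.2` are classified *high coherence* (empirically the
  specialty services), the rest *general*.
* **Degree statistics** — pooled node-degree histograms (bin width 0.99)
  fitted by nonlinear least squares with Weibull and normal densities and
  compared by MSE; modular hospital graphs prefer the fat-tailed Weibull.
* **Congestion analysis** — signed Pearson correlation between per-snapshot
  modularity and the *delayed placement* count (patients accepted for
  admission but without a bed at midnight), in three variants: full graph,
  high-coherence modules excluded, and the exclusion applied to
  emergency-only graphs. Lower modularity accompanies higher congestion, so
  the expected sign is negative, and excluding the uninvolved specialty
  modules sharpens the association.

## Worked example

```sh
wardnet run --config run.yaml --out out/     # or: python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With the default synthetic hospital (8 planted modules — 3 specialty +
5 general — over 32 wards and 40 units, 360 patients per monthly snapshot,
21 snapshots) at seed 1, the pipeline prints:

```json
{
  "composite_q": {"composite:2019": 0.3848, "composite:2020": 0.388},
  "mean_monthly_q": 0.6263,
  "n_high_coherence_modules": 3,
  "degree_fit_preferred": "weibull",
  "degree_fit_mse": {"weibull": 0.00134, "normal": 0.00140},
  "congestion_correlations": {"full": -0.808, "excluded": -0.817, "emergency_excluded": -0.77}
}
```

Reading this: monthly graphs are strongly modular (mean Q ≈ 0.63, against a
random-graph null whose 99th percentile is far lower); exactly three tracked
modules have cv < 0.2 (the planted specialty services); the pooled degree
distribution is better fitted by the Weibull family than the normal; and
modularity correlates negatively with the delayed-placement count, slightly
more strongly once the three high-coherence modules are excluded.

The CLI also exposes the individual stages (`simulate`, `build`,
`communities`, `temporal`, `degree`, `congestion`); every artefact (stay CSV,
edge lists, GraphML, membership/trajectory/classification CSVs, report JSON)
is reproducible byte-for-byte from `(config, seed)` and listed with its
sha256 in a `MANIFEST`.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` regenerates the
default synthetic hospital from the given seed, runs the complete pipeline
(graphs → Louvain → temporal classification → degree fits → congestion
correlations), prints the summary above and writes the results JSON to
`--out`.

See `docs/methods.md` for the model, the generator's assumptions, and known
limitations.
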