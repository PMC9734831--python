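"""Correlating snapshot modularity with delayed-placement congestion counts.

The congestion surrogate is the number of patients accepted for admission but
still without an inpatient bed at midnight of the extraction date.  The
analysis relates that count to per-snapshot modularity in three variants:

1. ``full``      — Louvain modularity of each whole snapshot graph;
2. ``excluded``  — modularity re-computed after removing the nodes of the
   high-coherence (low-cv, specialty) modules, on the assumption that those
   services are not involved in the high-volume general caseload that
   generates bed pressure;
3. ``emergency_excluded`` — the same exclusion applied to graphs rebuilt
   from emergency-designated admissions only.

Signed Pearson r is reported throughout: a hospital losing modular
organisation as congestion rises shows a *negative* correlation between
modularity and delayed counts, and exclusion of the uninvolved specialty
modules is expected to sharpen (raise the magnitude of) that correlation.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .build import (
    AdmissionType,
    SnapshotGraph,
    StayRecord,
    build_snapshot_graph,
    group_by_snapshot,
    subtraction_graph,
)
from .community import Partition, louvain
from .errors import GraphError, UndefinedStatisticError
from .temporal import MarkerPair, classify, select_markers, track


@dataclass
class CorrelationResult:
    """Pearson correlation between a modularity series and delayed counts."""

    variant: str
    r: float
    p_value: float
    n: int


@dataclass
class CongestionSeries:
    """Aligned per-snapshot series: delayed counts and modularity variants."""

    dates: list[datetime.date]
    delayed: list[int]
    q_full: list[float]
    q_excl: list[float]
    q_emergency: list[float] | None = None


@dataclass
class CongestionReport:
    """Full output of the three-variant congestion analysis."""

    series: CongestionSeries
    correlations: list[CorrelationResult]
    high_coherence_markers: list[MarkerPair]
    #: Convention note carried into serialized output: r is signed; an
    #: inverse modularity-congestion association appears as r < 0, and its
    #: magnitude |r| is what association-strength statements refer to.
    sign_convention: str = (
        "signed Pearson r; inverse modularity-congestion association is r < 0"
    )


def pearson(x: Sequence[float], y: Sequence[float], variant: str = "full") -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test (n - 2 df).

    Raises
    ------
    UndefinedStatisticError
        Fewer than 3 points, or a constant series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise UndefinedStatisticError(f"length mismatch {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise UndefinedStatisticError(f"correlation needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        variant=variant, r=float(res.statistic), p_value=float(res.pvalue), n=len(x)
    )


def _resolve_marker(partition: Partition, marker: MarkerPair) -> int | None:
    mw = partition.membership.get(marker.ward_id)
    mu = partition.membership.get(marker.unit_id)
    if mw is None or mu is None or mw != mu:
        return None
    return mw


def modularity_excluding(
    graph: SnapshotGraph,
    partition: Partition,
    excluded_markers: Sequence[MarkerPair],
    seed: int = 0,
    resolution: float = 1.0,
    strict: bool = True,
) -> float:
    """Modularity of the graph with the marked communities removed.

    Every node of each community containing an excluded marker is dropped
    (with its incident edges) and Louvain is re-run on the residual subgraph;
    the paper-style exclusion recomputes community structure rather than
    rescoring the frozen partition.  With no markers this reduces to plain
    Louvain modularity under the same seed.

    ``strict=False`` skips markers that do not resolve to a community in this
    partition (used by the pipeline, where a module may be absent or split in
    an individual month); ``strict=True`` raises instead.
    """
    drop: set[str] = set()
    for mk in excluded_markers:
        cid = _resolve_marker(partition, mk)
        if cid is None:
            if strict:
                raise GraphError(
                    f"marker ({mk.ward_id}, {mk.unit_id}) does not resolve to a "
                    f"community in partition of {graph.period_label!r}"
                )
            continue
        drop |= {n for n, c in partition.membership.items() if c == cid}
    residual = graph.subgraph((graph.ward_nodes | graph.unit_nodes) - drop)
    if residual.n_edges == 0:
        raise GraphError(
            f"residual graph of {graph.period_label!r} has no edges after exclusion"
        )
    return louvain(residual, seed=seed, resolution=resolution).modularity


def _snapshot_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-snapshot seeds derived from one base seed."""
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


def congestion_analysis(
    records: Sequence[StayRecord],
    delayed_counts: Sequence[int],
    seed: int = 0,
    resolution: float = 1.0,
    min_rate: float = 0.8,
    max_markers: int = 8,
    cv_threshold: float = 0.2,
    include_emergency: bool = True,
) -> CongestionReport:
    """The three-step modularity-congestion analysis.

    Builds one graph per snapshot date, runs Louvain on each, selects and
    classifies marker pairs on the full data, then correlates delayed counts
    with (1) full-graph modularity, (2) modularity excluding the
    high-coherence modules, and (3) the same exclusion on emergency-only
    subtraction graphs.  Marker selection is NOT repeated on the emergency
    subset; the full-data markers are reused.
    """
    by_date = group_by_snapshot(records)
    dates = list(by_date)
    if len(dates) != len(delayed_counts):
        raise UndefinedStatisticError(
            f"{len(dates)} snapshots but {len(delayed_counts)} delayed counts"
        )
    if len(dates) < 3:
        raise UndefinedStatisticError("congestion analysis needs >= 3 snapshots")

    seeds = _snapshot_seeds(seed, len(dates))
    graphs = [build_snapshot_graph(by_date[d], d) for d in dates]
    partitions = [louvain(g, seed=s, resolution=resolution) for g, s in zip(graphs, seeds)]
    q_full = [p.modularity for p in partitions]

    markers = select_markers(partitions, graphs, min_rate=min_rate, max_markers=max_markers)
    trajectories = [track(mk, partitions, graphs) for mk in markers]
    high, _general = classify(trajectories, threshold=cv_threshold)
    high_markers = [t.marker for t in high]

    def _excl_or_none(g, p, s):
        # a snapshot can degenerate (exclusion empties the graph in an
        # extremely disorganized month); mask it rather than abort the run
        try:
            return modularity_excluding(
                g, p, high_markers, seed=s, resolution=resolution, strict=False
            )
        except GraphError:
            return None

    q_excl = [_excl_or_none(g, p, s) for g, p, s in zip(graphs, partitions, seeds)]

    q_em: list[float | None] | None = None
    if include_emergency:
        em_graphs = [
            subtraction_graph(by_date[d], d, keep=AdmissionType.EMERGENCY) for d in dates
        ]
        em_parts = [louvain(g, seed=s, resolution=resolution) for g, s in zip(em_graphs, seeds)]
        q_em = [_excl_or_none(g, p, s) for g, p, s in zip(em_graphs, em_parts, seeds)]

    series = CongestionSeries(
        dates=dates,
        delayed=list(delayed_counts),
        q_full=q_full,
        q_excl=q_excl,
        q_emergency=q_em,
    )
    def _masked_pearson(q, variant):
        pairs = [(qi, c) for qi, c in zip(q, delayed_counts) if qi is not None]
        return pearson([p[0] for p in pairs], [p[1] for p in pairs], variant=variant)

    correlations = [
        pearson(q_full, delayed_counts, variant="full"),
        _masked_pearson(q_excl, "excluded"),
    ]
    if q_em is not None:
        correlations.append(_masked_pearson(q_em, "emergency_excluded"))
    return CongestionReport(
        series=series, correlations=correlations, high_coherence_markers=high_markers
    )
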