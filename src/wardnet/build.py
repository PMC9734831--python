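"""Construction of bipartite ward-unit graphs from patient stay snapshots.

A hospital's inpatient service can be represented, at a single extraction
instant, as an undirected bipartite graph: one node class for wards (physical
locations with their nursing staff), one for clinical units (specialty teams),
and an unweighted edge wherever at least one current inpatient links a ward to
a unit.  Edges record only presence/absence of shared patients at the moment
of extraction; the number of patients behind each edge is retained as
``edge_support`` but the default analyses are unweighted.

Monthly snapshot graphs can be merged into calendar-period composites, and
"subtraction" graphs are rebuilt from only emergency- or only
elective-designated admissions.
"""

from __future__ import annotations

import datetime
import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import GraphError, SchemaError

logger = logging.getLogger(__name__)


class AdmissionType(str, Enum):
    """Designation of an inpatient admission."""

    EMERGENCY = "emergency"
    ELECTIVE = "elective"


@dataclass(frozen=True)
class StayRecord:
    """One patient, under one clinical unit, in one ward, at one snapshot.

    The raw observational unit of the whole pipeline: a row of the patient
    administrative extract taken at a single instant.

    Parameters
    ----------
    snapshot_date
        Calendar date of the extraction instant.
    patient_id
        Opaque patient identifier; used only to count edge support.
    ward_id, unit_id
        Node labels.  The two namespaces must be disjoint across a data set.
    admission_type
        ``emergency`` or ``elective``.
    """

    snapshot_date: datetime.date
    patient_id: str
    ward_id: str
    unit_id: str
    admission_type: AdmissionType

    def __post_init__(self):
        if not self.ward_id or not self.unit_id:
            raise SchemaError("ward_id and unit_id must be non-empty")
        object.__setattr__(
            self, "admission_type", AdmissionType(self.admission_type)
        )


@dataclass
class SnapshotGraph:
    """Undirected, unweighted bipartite ward-unit graph for one period.

    Attributes
    ----------
    ward_nodes, unit_nodes
        The two node classes.  Only nodes appearing in at least one stay
        record are present (a rostered ward with no current patients is
        excluded: with no incident edges it contributes nothing to the
        adjacency matrix and its modularity term is undefined).
    edges
        Mapping from ``(ward_id, unit_id)`` to the number of distinct
        patients supporting the edge.  The default analyses treat every
        edge as binary; support is retained for weighted extensions.
    period_label
        A snapshot date (ISO format) or a composite label such as
        ``"composite:2019"``.
    """

    ward_nodes: set[str]
    unit_nodes: set[str]
    edges: dict[tuple[str, str], int]
    period_label: str

    def __post_init__(self):
        overlap = self.ward_nodes & self.unit_nodes
        if overlap:
            raise SchemaError(
                f"node labels appear as both ward and unit: {sorted(overlap)[:5]}"
            )
        for w, u in self.edges:
            if w not in self.ward_nodes or u not in self.unit_nodes:
                raise SchemaError(f"edge ({w}, {u}) is not ward-to-unit")

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """All nodes: wards in lexicographic order, then units."""
        return sorted(self.ward_nodes) + sorted(self.unit_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.ward_nodes) + len(self.unit_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        """Node degree (number of incident edges, unweighted)."""
        deg = {n: 0 for n in self.ward_nodes | self.unit_nodes}
        for w, u in self.edges:
            deg[w] += 1
            deg[u] += 1
        return deg

    def node_class(self, node: str) -> str:
        if node in self.ward_nodes:
            return "ward"
        if node in self.unit_nodes:
            return "unit"
        raise KeyError(node)

    def adjacency(self) -> dict[str, set[str]]:
        """Adjacency sets over all nodes."""
        adj: dict[str, set[str]] = {n: set() for n in self.ward_nodes | self.unit_nodes}
        for w, u in self.edges:
            adj[w].add(u)
            adj[u].add(w)
        return adj

    def subgraph(self, keep: Iterable[str]) -> "SnapshotGraph":
        """Induced subgraph on ``keep`` (nodes absent from the graph ignored)."""
        keep = set(keep)
        return SnapshotGraph(
            ward_nodes=self.ward_nodes & keep,
            unit_nodes=self.unit_nodes & keep,
            edges={
                e: s for e, s in self.edges.items() if e[0] in keep and e[1] in keep
            },
            period_label=self.period_label,
        )

    def to_networkx(self) -> nx.Graph:
        """Export as a :class:`networkx.Graph` with ``node_class`` attributes."""
        g = nx.Graph()
        for n in sorted(self.ward_nodes):
            g.add_node(n, node_class="ward")
        for n in sorted(self.unit_nodes):
            g.add_node(n, node_class="unit")
        for (w, u), s in sorted(self.edges.items()):
            g.add_edge(w, u, support=int(s))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, period_label: str) -> "SnapshotGraph":
        """Rebuild from a graph carrying ``node_class`` node attributes."""
        wards = {n for n, d in g.nodes(data=True) if d.get("node_class") == "ward"}
        units = {n for n, d in g.nodes(data=True) if d.get("node_class") == "unit"}
        missing = set(g.nodes) - wards - units
        if missing:
            raise SchemaError(f"nodes without a node_class attribute: {sorted(missing)[:5]}")
        edges = {}
        for a, b, d in g.edges(data=True):
            w, u = (a, b) if a in wards else (b, a)
            edges[(w, u)] = int(d.get("support", 1))
        return cls(ward_nodes=wards, unit_nodes=units, edges=edges, period_label=period_label)


def _check_namespaces(records: Iterable[StayRecord]) -> None:
    wards = {r.ward_id for r in records}
    units = {r.unit_id for r in records}
    collision = wards & units
    if collision:
        raise SchemaError(
            f"identifier(s) used as both ward and unit: {sorted(collision)[:5]}"
        )


def build_snapshot_graph(
    records: list[StayRecord], date: datetime.date | None = None
) -> SnapshotGraph:
    """Build the bipartite graph for a single snapshot date.

    An edge ``(w, u)`` exists iff at least one record at that date has ward
    ``w`` and unit ``u``; its support is the number of distinct patients on
    the pair.  A patient appearing in two records at one snapshot (a data
    artefact) contributes both edges; a warning is logged.

    Parameters
    ----------
    records
        Stay records, all sharing the same ``snapshot_date``.
    date
        Expected snapshot date; defaults to the records' common date.
    """
    records = list(records)
    if date is None and records:
        date = records[0].snapshot_date
    for r in records:
        if date is not None and r.snapshot_date != date:
            raise SchemaError(
                f"record for patient {r.patient_id} dated {r.snapshot_date}, expected {date}"
            )
    _check_namespaces(records)

    seen_patients = Counter(r.patient_id for r in records)
    dupes = [p for p, c in seen_patients.items() if c > 1]
    if dupes:
        logger.warning(
            "snapshot %s: %d patient id(s) appear in multiple records "
            "(first: %s); all their edges are retained",
            date, len(dupes), dupes[0],
        )

    support: dict[tuple[str, str], set[str]] = {}
    wards, units = set(), set()
    for r in records:
        wards.add(r.ward_id)
        units.add(r.unit_id)
        support.setdefault((r.ward_id, r.unit_id), set()).add(r.patient_id)

    label = date.isoformat() if date is not None else "empty"
    return SnapshotGraph(
        ward_nodes=wards,
        unit_nodes=units,
        edges={e: len(p) for e, p in support.items()},
        period_label=label,
    )


def merge_graphs(graphs: list[SnapshotGraph], label: str) -> SnapshotGraph:
    """Union of snapshot graphs into a calendar-period composite.

    Node and edge sets are unions; edge support sums over constituents.
    """
    if not graphs:
        raise GraphError("merge_graphs requires at least one graph")
    wards: set[str] = set()
    units: set[str] = set()
    edges: dict[tuple[str, str], int] = {}
    for g in graphs:
        wards |= g.ward_nodes
        units |= g.unit_nodes
        for e, s in g.edges.items():
            edges[e] = edges.get(e, 0) + s
    return SnapshotGraph(ward_nodes=wards, unit_nodes=units, edges=edges, period_label=label)


def subtraction_graph(
    records: list[StayRecord],
    date: datetime.date | None = None,
    keep: AdmissionType | str = AdmissionType.EMERGENCY,
) -> SnapshotGraph:
    """Snapshot graph rebuilt from only one admission designation.

    ``keep="emergency"`` repopulates the adjacency matrix with
    emergency-designated patients only (likewise for elective); the result's
    edge set is a subset of the full snapshot's.
    """
    keep = AdmissionType(keep)
    subset = [r for r in records if r.admission_type == keep]
    g = build_snapshot_graph(subset, date=date)
    if date is not None:
        g.period_label = f"{date.isoformat()}:{keep.value}"
    return g


def to_adjacency(graph: SnapshotGraph) -> tuple[np.ndarray, list[str]]:
    """Adjacency matrix with a deterministic node order.

    Rows/columns are wards in lexicographic order followed by units in
    lexicographic order, so the ward-ward and unit-unit blocks are zero and
    the output is diffable across runs.

    Returns
    -------
    (matrix, order)
        A symmetric 0/1 ``ndarray`` with zero diagonal, and the node order.
    """
    order = graph.nodes
    index = {n: i for i, n in enumerate(order)}
    a = np.zeros((len(order), len(order)), dtype=int)
    for w, u in graph.edges:
        i, j = index[w], index[u]
        a[i, j] = 1
        a[j, i] = 1
    return a, order


def group_by_snapshot(
    records: Iterable[StayRecord],
) -> dict[datetime.date, list[StayRecord]]:
    """Split a record list by snapshot date, in chronological order."""
    by_date: dict[datetime.date, list[StayRecord]] = {}
    for r in records:
        by_date.setdefault(r.snapshot_date, []).append(r)
    return dict(sorted(by_date.items()))
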