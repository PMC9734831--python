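"""Shared fixtures: small hand-built graphs and generated record sets."""

from __future__ import annotations

import datetime

import numpy as np
import pytest

from wardnet.build import SnapshotGraph, StayRecord, build_snapshot_graph, group_by_snapshot
from wardnet.synthetic import GeneratorConfig, generate_stays


def rand_bipartite(rng: np.random.Generator, n_ward: int, n_unit: int, m: int,
                   label: str = "rand") -> SnapshotGraph:
    """Random bipartite graph with m uniformly placed distinct edges;
    isolated endpoints dropped (as in graphs built from stays)."""
    flat = rng.choice(n_ward * n_unit, size=m, replace=False)
    edges = {(f"w{f // n_unit}", f"u{f % n_unit}"): 1 for f in flat}
    return SnapshotGraph(
        ward_nodes={e[0] for e in edges},
        unit_nodes={e[1] for e in edges},
        edges=edges,
        period_label=label,
    )


def two_k22() -> tuple[SnapshotGraph, dict[str, int]]:
    """Two disconnected complete-bipartite K(2,2) blocks and the
    block partition (the bipartite analogue of two disconnected cliques)."""
    edges = {}
    for blk, (ws, us) in enumerate([(("wA", "wB"), ("u1", "u2")),
                                    (("wC", "wD"), ("u3", "u4"))]):
        for w in ws:
            for u in us:
                edges[(w, u)] = 1
    g = SnapshotGraph(
        ward_nodes={"wA", "wB", "wC", "wD"},
        unit_nodes={"u1", "u2", "u3", "u4"},
        edges=edges,
        period_label="two-blocks",
    )
    membership = {"wA": 0, "wB": 0, "u1": 0, "u2": 0,
                  "wC": 1, "wD": 1, "u3": 1, "u4": 1}
    return g, membership


def make_records(pairs, date=datetime.date(2019, 1, 15), admission="emergency"):
    """StayRecords from (patient, ward, unit) triples at one date."""
    return [
        StayRecord(snapshot_date=date, patient_id=p, ward_id=w, unit_id=u,
                   admission_type=admission)
        for p, w, u in pairs
    ]


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic hospital: records, truth, per-snapshot graphs."""
    cfg = GeneratorConfig(seed=20)
    records, truth = generate_stays(cfg)
    by_date = group_by_snapshot(records)
    graphs = [build_snapshot_graph(rs, d) for d, rs in by_date.items()]
    return cfg, records, truth, graphs
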