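"""File formats, run configuration and the end-to-end pipeline.

Formats
-------
* Stay CSV: header ``snapshot_date,patient_id,ward_id,unit_id,admission_type``
  with ISO-8601 dates; the interchange format for patient snapshot extracts.
* Congestion CSV: header ``snapshot_date,delayed_count``.
* Edge-list CSV: ``source,target,support``.
* GraphML with a ``node_class in {ward, unit}`` attribute on every node
  (readable by standard graph tooling).
* Report JSON: one document combining per-snapshot modularity, composite
  modularity, markers, trajectories, cv classes, the degree-fit comparison
  and the congestion correlations.  Serialization is canonical (sorted keys,
  no timestamps) so identical (config, seed) gives byte-identical output; a
  MANIFEST lists every artefact with its sha256.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import yaml

from . import community, congestion as congestion_mod, degree as degree_mod, temporal
from .build import (
    AdmissionType,
    SnapshotGraph,
    StayRecord,
    build_snapshot_graph,
    group_by_snapshot,
    merge_graphs,
)
from .errors import ConfigurationError, SchemaError, WardnetError
from .synthetic import GeneratorConfig, generate_congestion, generate_stays

logger = logging.getLogger(__name__)

STAY_HEADER = ["snapshot_date", "patient_id", "ward_id", "unit_id", "admission_type"]
CONGESTION_HEADER = ["snapshot_date", "delayed_count"]


# ---------------------------------------------------------------------------
# Stay and congestion CSV
# ---------------------------------------------------------------------------


def read_stays(path: str | Path) -> list[StayRecord]:
    """Read and validate a stay CSV; malformed rows are rejected with their
    line numbers."""
    path = Path(path)
    records: list[StayRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if header != STAY_HEADER:
            raise SchemaError(f"{path}: expected header {STAY_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(STAY_HEADER):
                raise SchemaError(f"{path}:{lineno}: expected {len(STAY_HEADER)} fields, got {len(row)}")
            date_s, patient, ward, unit, adm = row
            try:
                date = datetime.date.fromisoformat(date_s)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: bad ISO date {date_s!r}") from None
            try:
                adm_t = AdmissionType(adm)
            except ValueError:
                raise SchemaError(
                    f"{path}:{lineno}: unknown admission_type {adm!r} "
                    f"(expected emergency|elective)"
                ) from None
            try:
                records.append(
                    StayRecord(
                        snapshot_date=date, patient_id=patient,
                        ward_id=ward, unit_id=unit, admission_type=adm_t,
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from None
    return records


def write_stays(records: Sequence[StayRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STAY_HEADER)
        for r in records:
            writer.writerow([
                r.snapshot_date.isoformat(), r.patient_id,
                r.ward_id, r.unit_id, r.admission_type.value,
            ])


def read_congestion(path: str | Path) -> dict[datetime.date, int]:
    """Read a congestion CSV into a date -> delayed-count mapping."""
    path = Path(path)
    out: dict[datetime.date, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CONGESTION_HEADER:
            raise SchemaError(f"{path}: expected header {CONGESTION_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                date = datetime.date.fromisoformat(row[0])
                count = int(row[1])
            except (ValueError, IndexError):
                raise SchemaError(f"{path}:{lineno}: bad row {row!r}") from None
            if count < 0:
                raise SchemaError(f"{path}:{lineno}: negative delayed_count {count}")
            out[date] = count
    return out


def write_congestion(counts: dict[datetime.date, int], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONGESTION_HEADER)
        for date in sorted(counts):
            writer.writerow([date.isoformat(), counts[date]])


# ---------------------------------------------------------------------------
# Graph interchange
# ---------------------------------------------------------------------------


def export_edgelist(graph: SnapshotGraph, path: str | Path) -> None:
    """Edge-list CSV (source=ward, target=unit, support), sorted for diffing."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "support"])
        for (w, u), s in sorted(graph.edges.items()):
            writer.writerow([w, u, s])


def read_edgelist(path: str | Path, period_label: str) -> SnapshotGraph:
    path = Path(path)
    edges: dict[tuple[str, str], int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["source", "target", "support"]:
            raise SchemaError(f"{path}: bad edge-list header {header}")
        for row in reader:
            if row:
                edges[(row[0], row[1])] = int(row[2])
    return SnapshotGraph(
        ward_nodes={e[0] for e in edges},
        unit_nodes={e[1] for e in edges},
        edges=edges,
        period_label=period_label,
    )


def export_graphml(graph: SnapshotGraph, path: str | Path) -> None:
    """GraphML export with ``node_class`` and ``support`` attributes."""
    nx.write_graphml(graph.to_networkx(), str(path))


def read_graphml(path: str | Path, period_label: str | None = None) -> SnapshotGraph:
    g = nx.read_graphml(str(path))
    return SnapshotGraph.from_networkx(g, period_label or Path(path).stem)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline configuration: either file inputs or a generator config.

    Defaults mirror the analysis constants: cv threshold 0.2, Louvain
    resolution 1.0, degree-histogram bin width 0.99.
    """

    stays_path: str | None = None
    congestion_path: str | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    cv_threshold: float = 0.2
    resolution: float = 1.0
    bin_width: float = 0.99
    min_rate: float = 0.8
    max_markers: int = 8
    out_dir: str = "wardnet_out"
    log_level: str = "INFO"

    def __post_init__(self):
        has_files = self.stays_path is not None
        has_gen = self.generator is not None
        if has_files == has_gen:
            raise ConfigurationError(
                "exactly one of stays_path or generator must be supplied"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen_raw = raw.pop("generator", None)
        gen = None
        if gen_raw is not None:
            if "disorganization_series" in gen_raw:
                gen_raw["disorganization_series"] = tuple(gen_raw["disorganization_series"])
            if gen_raw.get("elective_modules") is not None:
                gen_raw["elective_modules"] = tuple(gen_raw["elective_modules"])
            try:
                gen = GeneratorConfig(**gen_raw)
            except TypeError as exc:
                raise ConfigurationError(f"generator config: {exc}") from None
        try:
            return cls(generator=gen, **raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, sort_keys=True, indent=2, default=str) + "\n", encoding="utf-8"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all artefacts under ``out_dir``.

    Stages: load or simulate stays -> per-snapshot graphs and Louvain
    partitions -> calendar-year composites -> marker selection, tracking and
    cv classification -> degree-fit comparison on the first composite ->
    congestion correlations (when counts are available).  Returns the report
    dict; deterministic given (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: list[Path] = []

    def stage(name):
        logger.info("stage %s", name)
        return name

    stage_name = stage("input")
    try:
        if config.generator is not None:
            records, truth = generate_stays(config.generator)
            counts_list = generate_congestion(config.generator, truth)
            from .synthetic import snapshot_dates

            counts = dict(zip(snapshot_dates(config.generator), counts_list))
            write_stays(records, out / "stays.csv")
            write_congestion(counts, out / "congestion.csv")
            _dump_json(
                {
                    "planted_membership": truth.planted_membership,
                    "stable_module_ids": sorted(truth.stable_module_ids),
                    "disorganization": list(truth.disorganization),
                },
                out / "ground_truth.json",
            )
            artefacts += [out / "stays.csv", out / "congestion.csv", out / "ground_truth.json"]
        else:
            records = read_stays(config.stays_path)
            counts = (
                read_congestion(config.congestion_path)
                if config.congestion_path
                else None
            )

        stage_name = stage("graphs")
        by_date = group_by_snapshot(records)
        if not by_date:
            raise SchemaError("no stay records")
        graphs = [build_snapshot_graph(rs, d) for d, rs in by_date.items()]
        years = sorted({d.year for d in by_date})
        composites = [
            merge_graphs(
                [g for g, d in zip(graphs, by_date) if d.year == y], f"composite:{y}"
            )
            for y in years
        ]
        for g in composites:
            export_edgelist(g, out / f"{g.period_label.replace(':', '_')}_edges.csv")
            export_graphml(g, out / f"{g.period_label.replace(':', '_')}.graphml")
            artefacts += [
                out / f"{g.period_label.replace(':', '_')}_edges.csv",
                out / f"{g.period_label.replace(':', '_')}.graphml",
            ]

        stage_name = stage("communities")
        seeds = congestion_mod._snapshot_seeds(config.seed, len(graphs) + len(composites))
        partitions = [
            community.louvain(g, seed=s, resolution=config.resolution)
            for g, s in zip(graphs, seeds)
        ]
        comp_parts = [
            community.louvain(g, seed=s, resolution=config.resolution)
            for g, s in zip(composites, seeds[len(graphs):])
        ]
        with (out / "membership.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["period", "node", "node_class", "community"])
            for g, p in zip(graphs + composites, partitions + comp_parts):
                for n in g.nodes:
                    writer.writerow([g.period_label, n, g.node_class(n), p.membership[n]])
        artefacts.append(out / "membership.csv")

        stage_name = stage("temporal")
        markers = temporal.select_markers(
            partitions, graphs, min_rate=config.min_rate, max_markers=config.max_markers
        )
        trajectories = [temporal.track(mk, partitions, graphs) for mk in markers]
        high, general = temporal.classify(trajectories, threshold=config.cv_threshold)
        with (out / "trajectories.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["marker_ward", "marker_unit", "snapshot", "size", "absent"])
            for traj in trajectories:
                for d, s in zip(by_date, traj.sizes):
                    writer.writerow([
                        traj.marker.ward_id, traj.marker.unit_id, d.isoformat(),
                        "" if s is None else s, int(s is None),
                    ])
        with (out / "classification.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["marker_ward", "marker_unit", "co_membership_rate", "cv", "class"])
            for traj in trajectories:
                writer.writerow([
                    traj.marker.ward_id, traj.marker.unit_id,
                    f"{traj.marker.co_membership_rate:.6f}", f"{traj.cv:.6f}",
                    traj.coherence_class,
                ])
        artefacts += [out / "trajectories.csv", out / "classification.csv"]

        stage_name = stage("degree")
        hist = degree_mod.degree_histogram(composites[0], bin_width=config.bin_width)
        wb, nm, preferred = degree_mod.compare_fits(hist)

        stage_name = stage("congestion")
        congestion_block = None
        if counts is not None:
            missing = [d for d in by_date if d not in counts]
            if missing:
                raise SchemaError(
                    f"congestion counts missing for snapshot(s) {missing[:3]}"
                )
            report_c = congestion_mod.congestion_analysis(
                records,
                [counts[d] for d in by_date],
                seed=config.seed,
                resolution=config.resolution,
                min_rate=config.min_rate,
                max_markers=config.max_markers,
                cv_threshold=config.cv_threshold,
            )
            congestion_block = {
                "sign_convention": report_c.sign_convention,
                "correlations": [dataclasses.asdict(c) for c in report_c.correlations],
                "q_full": report_c.series.q_full,
                "q_excl": report_c.series.q_excl,
                "q_emergency": report_c.series.q_emergency,
                "delayed": report_c.series.delayed,
            }
    except WardnetError as exc:
        raise WardnetError(f"[stage:{stage_name}] {exc}") from exc

    report = {
        "seed": config.seed,
        "resolution": config.resolution,
        "cv_threshold": config.cv_threshold,
        "bin_width": config.bin_width,
        "snapshots": [
            {
                "date": d.isoformat(),
                "n_nodes": g.n_nodes,
                "n_edges": g.n_edges,
                "q": p.modularity,
                "n_communities": p.n_communities,
            }
            for d, g, p in zip(by_date, graphs, partitions)
        ],
        "composites": [
            {
                "label": g.period_label,
                "n_nodes": g.n_nodes,
                "n_edges": g.n_edges,
                "q": p.modularity,
                "n_communities": p.n_communities,
            }
            for g, p in zip(composites, comp_parts)
        ],
        "markers": [
            {
                "ward": t.marker.ward_id,
                "unit": t.marker.unit_id,
                "co_membership_rate": t.marker.co_membership_rate,
                "cv": t.cv,
                "mean_size": t.mean_size,
                "class": t.coherence_class,
            }
            for t in trajectories
        ],
        "n_high_coherence": len(high),
        "degree_fit": {
            "weibull": {"k": wb.params[0], "lambda": wb.params[1], "mse": wb.mse},
            "normal": {"mu": nm.params[0], "sigma": nm.params[1], "mse": nm.mse},
            "preferred": preferred,
        },
        "congestion": congestion_block,
    }
    _dump_json(report, out / "report.json")
    artefacts.append(out / "report.json")

    manifest = "".join(
        f"{_sha256(p)}  {p.name}\n" for p in sorted(artefacts, key=lambda p: p.name)
    )
    (out / "MANIFEST").write_text(manifest, encoding="utf-8")
    return report
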