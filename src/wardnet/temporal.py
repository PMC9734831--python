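"""Tracking modules across monthly snapshots and classifying their coherence.

Community detection runs independently on every snapshot graph, so "module 3
of March" has no intrinsic identity in April.  Recurring ward-unit *marker
pairs* — edges whose two endpoints sit in the same community in most
snapshots — are used to link a module across the sequence: the module tracked
by a marker at a given snapshot is the community containing both marker nodes.

Each tracked module's node-count series yields a coefficient of variation
(cv = sd / mean); modules with cv below a threshold (0.2 by default) are
classified *high coherence* — empirically the specialized services whose
composition barely changes — and the rest *general*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .build import SnapshotGraph
from .community import Partition
from .errors import UndefinedStatisticError

logger = logging.getLogger(__name__)

#: cv below this classifies a module as high coherence.
DEFAULT_CV_THRESHOLD = 0.2


@dataclass(frozen=True)
class MarkerPair:
    """A recurring ward-unit combination identifying one tracked module."""

    ward_id: str
    unit_id: str
    #: fraction of snapshots in which both nodes are present and share a community
    co_membership_rate: float = 0.0


@dataclass
class ModuleTrajectory:
    """One tracked module's size series and its coherence classification.

    ``sizes`` has one slot per snapshot: the node count of the community
    containing both marker nodes, or ``None`` when either node is absent or
    the two sit in different communities.  Absent slots are excluded from the
    mean, sd and cv.  Size counts nodes (wards + units), not patients.
    """

    marker: MarkerPair
    sizes: list[int | None]
    mean_size: float = 0.0
    sd_size: float = 0.0
    cv: float = float("nan")
    coherence_class: str = "general"

    @property
    def present(self) -> list[int]:
        return [s for s in self.sizes if s is not None]


def coefficient_of_variation(sizes: Sequence[float | None], ddof: int = 1) -> float:
    """cv = sd / mean over the present values of a series.

    Uses the sample standard deviation (``ddof=1``) by default; switchable.
    Scale-invariant: multiplying every value by k leaves cv unchanged.

    Raises
    ------
    UndefinedStatisticError
        Fewer than 2 present values, or non-positive mean.
    """
    vals = np.array([s for s in sizes if s is not None], dtype=float)
    if len(vals) < 2:
        raise UndefinedStatisticError(
            f"cv needs at least 2 present values, got {len(vals)}"
        )
    mean = float(np.mean(vals))
    if mean <= 0:
        raise UndefinedStatisticError(f"cv undefined for mean {mean}")
    return float(np.std(vals, ddof=ddof)) / mean


def _co_membership(
    ward: str, unit: str, partitions: Sequence[Partition], graphs: Sequence[SnapshotGraph]
) -> list[int | None]:
    """Per snapshot: community id containing both nodes, else None."""
    out: list[int | None] = []
    for part, g in zip(partitions, graphs):
        present = (
            ward in g.ward_nodes
            and unit in g.unit_nodes
            and ward in part.membership
            and unit in part.membership
        )
        if present and part.membership[ward] == part.membership[unit]:
            out.append(part.membership[ward])
        else:
            out.append(None)
    return out


def select_markers(
    partitions: Sequence[Partition],
    graphs: Sequence[SnapshotGraph],
    min_rate: float = 0.8,
    max_markers: int = 8,
    distinctness_cap: float = 0.2,
) -> list[MarkerPair]:
    """Choose marker pairs that each track a distinct module.

    Candidates are ward-unit pairs observed as an edge in at least one
    snapshot.  Each candidate's co-membership rate is the fraction of
    snapshots in which both nodes are present and share a community.
    Selection is greedy by descending rate (ties broken lexicographically),
    subject to: no two selected markers may sit together in one community in
    more than ``distinctness_cap`` of the snapshots — otherwise they would
    track the same module.

    Returns up to ``max_markers`` pairs; an empty list (with a logged
    warning) if nothing reaches ``min_rate``.
    """
    if len(partitions) != len(graphs):
        raise ValueError("partitions and graphs must be aligned")
    if len(graphs) < 2:
        raise ValueError("marker selection needs at least 2 snapshots")
    n_snap = len(graphs)

    candidates: set[tuple[str, str]] = set()
    for g in graphs:
        candidates |= set(g.edges)

    rated: list[tuple[float, str, str, list[int | None]]] = []
    for w, u in candidates:
        comem = _co_membership(w, u, partitions, graphs)
        rate = sum(1 for c in comem if c is not None) / n_snap
        if rate >= min_rate:
            rated.append((rate, w, u, comem))
    if not rated:
        logger.warning("no ward-unit pair reaches co-membership rate %.2f", min_rate)
        return []

    rated.sort(key=lambda t: (-t[0], t[1], t[2]))
    selected: list[MarkerPair] = []
    selected_comem: list[list[int | None]] = []
    for rate, w, u, comem in rated:
        if len(selected) >= max_markers:
            break
        clash = False
        for other in selected_comem:
            together = sum(
                1
                for a, b in zip(comem, other)
                if a is not None and b is not None and a == b
            )
            if together / n_snap > distinctness_cap:
                clash = True
                break
        if not clash:
            selected.append(MarkerPair(ward_id=w, unit_id=u, co_membership_rate=rate))
            selected_comem.append(comem)
    return selected


def track(
    marker: MarkerPair,
    partitions: Sequence[Partition],
    graphs: Sequence[SnapshotGraph],
) -> ModuleTrajectory:
    """Size series of the module a marker tracks.

    Per snapshot the size is the number of nodes in the community containing
    both marker nodes; the slot is absent when either node is missing or they
    sit in different communities.

    Raises
    ------
    UndefinedStatisticError
        If the marker nodes are never co-resident (all-absent trajectory).
    """
    comem = _co_membership(marker.ward_id, marker.unit_id, partitions, graphs)
    sizes: list[int | None] = []
    for cid, part in zip(comem, partitions):
        if cid is None:
            sizes.append(None)
        else:
            sizes.append(sum(1 for c in part.membership.values() if c == cid))
    present = [s for s in sizes if s is not None]
    if not present:
        raise UndefinedStatisticError(
            f"marker ({marker.ward_id}, {marker.unit_id}) never co-resident in a community"
        )
    traj = ModuleTrajectory(marker=marker, sizes=sizes)
    traj.mean_size = float(np.mean(present))
    traj.sd_size = float(np.std(present, ddof=1)) if len(present) > 1 else 0.0
    traj.cv = traj.sd_size / traj.mean_size if traj.mean_size > 0 else float("nan")
    return traj


def classify(
    trajectories: Sequence[ModuleTrajectory],
    threshold: float = DEFAULT_CV_THRESHOLD,
) -> tuple[list[ModuleTrajectory], list[ModuleTrajectory]]:
    """Split trajectories into (high_coherence, general) by cv.

    The inequality is strict: cv < threshold is high coherence; cv equal to
    the threshold is general.  Sets ``coherence_class`` in place.
    """
    high: list[ModuleTrajectory] = []
    general: list[ModuleTrajectory] = []
    for traj in trajectories:
        if math.isnan(traj.cv):
            raise UndefinedStatisticError(
                f"trajectory for ({traj.marker.ward_id}, {traj.marker.unit_id}) has no cv"
            )
        if traj.cv < threshold:
            traj.coherence_class = "high_coherence"
            high.append(traj)
        else:
            traj.coherence_class = "general"
            general.append(traj)
    return high, general


def classify_cvs(cvs: Sequence[float], threshold: float = DEFAULT_CV_THRESHOLD) -> int:
    """Number of high-coherence modules among a list of cv values (strict <)."""
    return sum(1 for cv in cvs if cv < threshold)
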