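"""Theoretical upper bound on DDA coverage via maximum bipartite matching.

Offline, with the whole run known, the best any DDA controller could do is
an assignment of MS2 scan slots to picked-peak bounding boxes: a slot can
serve a box only if the slot's time lies inside the box's RT extent, the
survey scan immediately preceding the slot also lies inside it, and the
peak is above the fragmentation intensity floor at that survey scan.  No
slot can serve two boxes and covering a box twice is pointless, so the
maximum number of boxes fragmentable at least once is the size of a maximum
matching in the slot-box bipartite graph — computed here with the
Hopcroft-Karp algorithm.  The bound needs global knowledge of the run and
is unattainable online; it calibrates how far a controller is from optimal.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Callable, Sequence

from .chem import (DEFAULT_MIN_INTENSITY, Mixture, PeakBoundingBox,
                   intensity_at)
from .instrument import AcquisitionLog, ScanLevel

logger = logging.getLogger("ddasim")

# (box, ms1_time) -> MS1 intensity attributable to the box at that scan
IntensityLookup = Callable[[PeakBoundingBox, float], float]


@dataclass(frozen=True)
class ScheduledScan:
    index: int
    level: ScanLevel
    start_time: float


def build_schedule(mean_ms1: float, mean_ms2: float, N: int,
                   run_length: float) -> list[ScheduledScan]:
    """Fixed-grid scan schedule: repeating [MS1, MS2 x N] duty cycles.

    Start times are cumulative sums of the mean scan durations from t = 0;
    the schedule ends before ``run_length``.
    """
    if mean_ms1 <= 0 or mean_ms2 <= 0:
        raise ValueError("scan durations must be positive")
    if N < 1:
        raise ValueError("N must be >= 1")
    if run_length < mean_ms1:
        logger.warning("run_length %.3g shorter than one MS1 scan: "
                       "empty schedule", run_length)
    schedule: list[ScheduledScan] = []
    t = 0.0
    index = 0
    while t < run_length:
        schedule.append(ScheduledScan(index, ScanLevel.MS1, t))
        t += mean_ms1
        index += 1
        for _ in range(N):
            if t >= run_length:
                break
            schedule.append(ScheduledScan(index, ScanLevel.MS2, t))
            t += mean_ms2
            index += 1
    return schedule


def schedule_from_log(log: AcquisitionLog) -> list[ScheduledScan]:
    """The realized schedule of a simulated run (levels and start times)."""
    return [ScheduledScan(s.index, s.level, s.start_time) for s in log.scans]


@dataclass(frozen=True)
class BipartiteGraph:
    """MS2 scan slots (left) vs picked-peak boxes (right).

    ``edges[i]`` lists indices into ``boxes`` reachable from ``ms2_slots[i]``;
    adjacency is kept in deterministic (schedule, box) order.
    """

    ms2_slots: tuple[ScheduledScan, ...]
    boxes: tuple[PeakBoundingBox, ...]
    edges: tuple[tuple[int, ...], ...]

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.edges)


def build_graph(schedule: Sequence[ScheduledScan],
                boxes: Sequence[PeakBoundingBox],
                min_intensity: float,
                intensity_lookup: IntensityLookup) -> BipartiteGraph:
    """Add an edge (slot, box) for every potential fragmentation event.

    The three edge rules (all endpoint comparisons inclusive):

    i.   the MS2 slot time lies within the box's RT limits;
    ii.  the immediately preceding MS1 scan's time also lies within them;
    iii. the box's MS1 intensity at that preceding scan is at least
         ``min_intensity`` (missing intensity data counts as below floor).
    """
    ms2_slots = []
    preceding_ms1: list[float | None] = []
    last_ms1: float | None = None
    for s in schedule:
        if s.level is ScanLevel.MS1:
            last_ms1 = s.start_time
        else:
            ms2_slots.append(s)
            preceding_ms1.append(last_ms1)

    edges: list[tuple[int, ...]] = []
    for slot, t_ms1 in zip(ms2_slots, preceding_ms1):
        adj = []
        for bi, box in enumerate(boxes):
            if not box.rt_min <= slot.start_time <= box.rt_max:
                continue
            if t_ms1 is None or not box.rt_min <= t_ms1 <= box.rt_max:
                continue
            try:
                intensity = intensity_lookup(box, t_ms1)
            except Exception:
                logger.debug("no intensity for box %s at t=%.3f; "
                             "treated as below floor", box.id, t_ms1)
                continue
            if intensity >= min_intensity:
                adj.append(bi)
        edges.append(tuple(adj))
    return BipartiteGraph(ms2_slots=tuple(ms2_slots), boxes=tuple(boxes),
                          edges=tuple(edges))


@dataclass(frozen=True)
class Matching:
    """A set of (slot_index, box_index) pairs, no endpoint repeated."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def size(self) -> int:
        return len(self.pairs)


def hopcroft_karp(graph: BipartiteGraph) -> Matching:
    """Maximum matching of the slot-box graph via Hopcroft-Karp.

    Repeatedly finds a maximal set of vertex-disjoint shortest augmenting
    paths with a BFS layering and DFS augmentation; O(E sqrt(V)).  Node
    ordering is deterministic, so the returned matching (not just its size)
    is reproducible.
    """
    n_left = len(graph.edges)
    n_right = len(graph.boxes)
    INF = float("inf")
    match_l: list[int] = [-1] * n_left
    match_r: list[int] = [-1] * n_right
    dist = [INF] * n_left

    def bfs() -> bool:
        queue: deque[int] = deque()
        for u in range(n_left):
            if match_l[u] == -1:
                dist[u] = 0
                queue.append(u)
            else:
                dist[u] = INF
        found = False
        while queue:
            u = queue.popleft()
            for v in graph.edges[u]:
                w = match_r[v]
                if w == -1:
                    found = True
                elif dist[w] == INF:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        return found

    def dfs(u: int) -> bool:
        for v in graph.edges[u]:
            w = match_r[v]
            if w == -1 or (dist[w] == dist[u] + 1 and dfs(w)):
                match_l[u] = v
                match_r[v] = u
                return True
        dist[u] = INF
        return False

    while bfs():
        for u in range(n_left):
            if match_l[u] == -1:
                dfs(u)

    pairs = tuple((u, match_l[u]) for u in range(n_left) if match_l[u] != -1)
    return Matching(pairs=pairs)


# ---------------------------------------------------------------------------
# Intensity lookups for the two input regimes.

def mixture_intensity_lookup(mixture: Mixture) -> IntensityLookup:
    """Evaluate each box's chemical chromatogram directly (box ids must be
    chemical ids, as produced by :func:`ddasim.chem.ground_truth_boxes`)."""
    by_id = {c.id: c for c in mixture.chemicals}

    def lookup(box: PeakBoundingBox, t: float) -> float:
        return intensity_at(by_id[box.id], t)

    return lookup


def scans_intensity_lookup(ms1_scans) -> IntensityLookup:
    """Nearest-in-time MS1 scan, most intense centroid inside the box's m/z
    range — for schedules evaluated against full-scan acquisition data."""
    scans = sorted(ms1_scans, key=lambda s: s.start_time)
    times = [s.start_time for s in scans]

    def lookup(box: PeakBoundingBox, t: float) -> float:
        if not scans:
            raise LookupError("no MS1 scans")
        # nearest scan by |time difference|
        import bisect
        i = bisect.bisect_left(times, t)
        best = min((x for x in (i - 1, i) if 0 <= x < len(scans)),
                   key=lambda x: abs(times[x] - t))
        hits = [inten for mz, inten in scans[best].peaks
                if box.mz_min <= mz <= box.mz_max]
        if not hits:
            raise LookupError(f"no peak in box {box.id} at t={t}")
        return max(hits)

    return lookup


def optimal_performance(boxes: Sequence[PeakBoundingBox],
                        intensity_lookup: IntensityLookup,
                        mean_ms1: float, mean_ms2: float, N: int,
                        run_length: float,
                        min_intensity: float = DEFAULT_MIN_INTENSITY,
                        schedule: Sequence[ScheduledScan] | None = None,
                        ) -> int:
    """Theoretical maximum number of boxes fragmentable at least once.

    Builds the fixed-grid schedule (or uses a supplied one), forms the
    slot-box graph under the three edge rules, and returns the maximum
    matching size.
    """
    if schedule is None:
        schedule = build_schedule(mean_ms1, mean_ms2, N, run_length)
    graph = build_graph(schedule, boxes, min_intensity, intensity_lookup)
    return hopcroft_karp(graph).size
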