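"""Scoring acquisition runs against picked-peak boxes, plus grid search.

Two figures of merit:

* **coverage** — the number of picked peaks (bounding boxes) that contain at
  least one MS2 fragmentation event;
* **efficiency** — coverage divided by the number of MS2 scans; 1.0 means
  every fragmentation event hit one unique picked peak.

An event lies in a box when its precursor m/z and its scan time fall inside
the box rectangle (bounds inclusive).  By default an event landing in k
overlapping boxes credits all k (so efficiency can in principle exceed 1 on
pathological overlaps); ``single_credit=True`` credits only the box whose
m/z centre is nearest the precursor.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import Mixture, PeakBoundingBox, ground_truth_boxes
from .controllers import ControllerConfig, make_controller
from .instrument import AcquisitionLog, ScanTimingModel, run_acquisition


@dataclass(frozen=True)
class FragmentationEvent:
    """One MS2 scan reduced to the facts needed for box assignment."""

    ms2_scan_index: int
    time: float
    precursor_mz: float
    source_ms1_time: float | None = None


def events_from_log(log: AcquisitionLog,
                    use_source_ms1_time: bool = False
                    ) -> list[FragmentationEvent]:
    """One event per MS2 scan.  Event RT is the MS2 scan's own start time
    unless ``use_source_ms1_time`` asks for the triggering survey time."""
    ms1_times = {s.index: s.start_time for s in log.ms1_scans}
    events = []
    for s in log.ms2_scans:
        src_t = ms1_times.get(s.source_ms1_index)
        t = src_t if (use_source_ms1_time and src_t is not None) \
            else s.start_time
        events.append(FragmentationEvent(
            ms2_scan_index=s.index, time=t, precursor_mz=s.precursor_mz,
            source_ms1_time=src_t))
    return events


def assign_events(events: Sequence[FragmentationEvent],
                  boxes: Sequence[PeakBoundingBox],
                  single_credit: bool = False
                  ) -> dict[int, set[str]]:
    """Map each event (by MS2 scan index) to the box ids it falls into."""
    assignment: dict[int, set[str]] = {}
    for e in events:
        hits = [b for b in boxes if b.contains(e.precursor_mz, e.time)]
        if single_credit and len(hits) > 1:
            hits = [min(hits, key=lambda b: (
                abs((b.mz_min + b.mz_max) / 2 - e.precursor_mz), b.id))]
        assignment[e.ms2_scan_index] = {b.id for b in hits}
    return assignment


def coverage(events: Sequence[FragmentationEvent],
             boxes: Sequence[PeakBoundingBox],
             single_credit: bool = False) -> int:
    """Number of distinct boxes containing at least one event."""
    covered: set[str] = set()
    for hits in assign_events(events, boxes, single_credit).values():
        covered |= hits
    return len(covered)


def efficiency(n_covered: int, n_ms2: int) -> float:
    """Coverage per MS2 scan (the raw, unrounded ratio)."""
    if n_ms2 < 1:
        raise ValueError("efficiency undefined without MS2 scans")
    return n_covered / n_ms2


@dataclass
class EvaluationReport:
    """Coverage/efficiency summary of one acquisition run."""

    controller_name: str
    n_boxes: int
    n_ms1: int
    n_ms2: int
    coverage: int
    efficiency: float                  # nan when the run has no MS2 scans
    per_box_hits: dict[str, int] = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return self.n_ms1 + self.n_ms2

    def to_dict(self) -> dict:
        return {"controller": self.controller_name, "n_boxes": self.n_boxes,
                "total_scans": self.n_scans, "n_ms1": self.n_ms1,
                "n_ms2": self.n_ms2, "coverage": self.coverage,
                "efficiency": self.efficiency,
                "efficiency_2dp": (round(self.efficiency, 2)
                                   if not math.isnan(self.efficiency)
                                   else None)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def evaluate_log(log: AcquisitionLog, boxes: Sequence[PeakBoundingBox],
                 single_credit: bool = False,
                 use_source_ms1_time: bool = False) -> EvaluationReport:
    """Score one acquisition log against a set of picked-peak boxes."""
    events = events_from_log(log, use_source_ms1_time)
    assignment = assign_events(events, boxes, single_credit)
    per_box: dict[str, int] = {}
    for hits in assignment.values():
        for bid in hits:
            per_box[bid] = per_box.get(bid, 0) + 1
    n_ms2 = len(log.ms2_scans)
    cov = len(per_box)
    eff = efficiency(cov, n_ms2) if n_ms2 else math.nan
    return EvaluationReport(
        controller_name=log.controller_name, n_boxes=len(boxes),
        n_ms1=len(log.ms1_scans), n_ms2=n_ms2, coverage=cov,
        efficiency=eff, per_box_hits=per_box)


# ---------------------------------------------------------------------------
# Parameter grid search (coverage by default, any report field on request).

def grid_search(controller_name: str,
                param_grid: Mapping[str, Iterable],
                mixture: Mixture,
                timing: ScanTimingModel | None = None,
                boxes: Sequence[PeakBoundingBox] | None = None,
                base_cfg: ControllerConfig | None = None,
                objective: str = "coverage",
                seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over the cartesian product of ``param_grid``.

    One deterministic simulation per grid point, scored against ``boxes``
    (ground-truth boxes of the mixture by default).  Returns the argmax
    parameters (ties to earlier grid order) and the full heatmap-ready
    score table.
    """
    names = list(param_grid)
    values = [list(param_grid[k]) for k in names]
    if not names or any(len(v) == 0 for v in values):
        raise ValueError("param_grid must be non-empty in every dimension")
    base = base_cfg or ControllerConfig()
    if boxes is None:
        boxes = ground_truth_boxes(mixture, base.min_intensity)

    rows = []
    best: tuple[float, int] | None = None  # (score, -row) for argmax
    best_params: dict = {}
    for row_i, combo in enumerate(itertools.product(*values)):
        point = dict(zip(names, combo))
        cfg_kwargs = {**base.__dict__, **point}
        controller = make_controller(controller_name,
                                     ControllerConfig(**cfg_kwargs))
        log = run_acquisition(controller, mixture, timing, seed=seed)
        report = evaluate_log(log, boxes)
        score = getattr(report, objective)
        rows.append({**point, "coverage": report.coverage,
                     "efficiency": report.efficiency,
                     "n_ms1": report.n_ms1, "n_ms2": report.n_ms2})
        if best is None or score > best[0]:
            best = (score, row_i)
            best_params = point
    return best_params, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optional mzML support: mean MS1/MS2 scan times from a real acquisition,
# for seeding the fixed-grid optimal schedule.  Only two fields per spectrum
# are needed (ms level, scan start time), read directly from the cvParams.

def _iter_mzml_scan_records(path):
    """Yield (start_time_seconds, ms_level) per spectrum of an mzML file."""
    import xml.etree.ElementTree as ET

    def local(tag):
        return tag.rsplit("}", 1)[-1]

    for _, elem in ET.iterparse(str(path), events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        level, t_s = 1, None
        for cv in elem.iter():
            if local(cv.tag) != "cvParam":
                continue
            name = cv.get("name")
            if name == "ms level":
                level = int(cv.get("value"))
            elif name == "scan start time":
                t_s = float(cv.get("value"))
                if cv.get("unitName", "minute") == "minute":
                    t_s *= 60.0
        if t_s is not None:
            yield t_s, level
        elem.clear()


def mean_scan_times_from_mzml(path) -> tuple[float, float]:
    """Mean seconds between successive scan start times, split by the level
    of the earlier scan (the gap after a scan is the time it consumed)."""
    records = sorted(_iter_mzml_scan_records(path))
    gaps: dict[int, list[float]] = {1: [], 2: []}
    for (t0, lvl), (t1, _) in zip(records, records[1:]):
        gaps.setdefault(lvl, []).append(t1 - t0)
    if not gaps[1] or not gaps[2]:
        raise ValueError("need both MS1 and MS2 scans to estimate durations")
    return (sum(gaps[1]) / len(gaps[1]), sum(gaps[2]) / len(gaps[2]))
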