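"""Real-time region-of-interest (ROI) tracking across MS1 survey scans.

An ROI is a chain of m/z-consistent centroids over consecutive MS1 scans —
the unit that peak pickers build chromatographic peaks from, and the unit
the SmartROI controller prioritises for fragmentation.  The store is a pure
deterministic state machine: replaying the same scan sequence reproduces the
same final state.

SmartROI availability, evaluated on every survey scan for every live ROI:

1. the ROI's intensity in the most recent scan must be at least the minimum
   fragmentation intensity — otherwise it is unavailable, whatever its
   history;
2. an ROI never fragmented before is available;
3. a previously fragmented ROI is available again only if its intensity has
   either risen by a factor alpha over its intensity when last fragmented,
   or dropped to a fraction beta of its maximum since that fragmentation
   (so a second peak hiding in the same ROI is not missed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .chem import DEFAULT_MIN_INTENSITY
from .instrument import Scan, ScanLevel

DEFAULT_MZ_TOLERANCE_PPM = 10.0


@dataclass
class ROI:
    """A live (or retired) region of interest with SmartROI bookkeeping."""

    id: int
    mz_trace: list[float]
    rt_trace: list[float]
    intensity_trace: list[float]
    active: bool = True
    fragmented: bool = False
    frag_count: int = 0
    intensity_at_last_frag: float = 0.0
    max_intensity_since_last_frag: float = 0.0
    last_frag_time: float = -math.inf

    @property
    def mz(self) -> float:
        """Most recent m/z — the precursor used if the ROI is selected."""
        return self.mz_trace[-1]

    @property
    def current_intensity(self) -> float:
        return self.intensity_trace[-1]

    @property
    def n_points(self) -> int:
        return len(self.rt_trace)

    def extend(self, rt: float, mz: float, intensity: float) -> None:
        if self.rt_trace and rt <= self.rt_trace[-1]:
            raise ValueError("rt_trace must be strictly increasing")
        self.mz_trace.append(mz)
        self.rt_trace.append(rt)
        self.intensity_trace.append(intensity)
        if intensity > self.max_intensity_since_last_frag:
            self.max_intensity_since_last_frag = intensity

    def mark_fragmented(self, time: float) -> None:
        """Record a fragmentation event and reset the running maximum."""
        self.fragmented = True
        self.frag_count += 1
        self.intensity_at_last_frag = self.current_intensity
        self.max_intensity_since_last_frag = self.current_intensity
        self.last_frag_time = time


def smartroi_available(roi: ROI, min_intensity: float, alpha: float,
                       beta: float) -> bool:
    """Apply the three SmartROI availability rules to one ROI."""
    current = roi.current_intensity
    if current < min_intensity:          # rule 1 dominates
        return False
    if not roi.fragmented:               # rule 2
        return True
    # rule 3a: risen by factor alpha since last fragmentation
    if current >= alpha * roi.intensity_at_last_frag:
        return True
    # rule 3b: dropped to fraction beta of the post-fragmentation maximum
    if current <= beta * roi.max_intensity_since_last_frag:
        return True
    return False


@dataclass
class ROIStore:
    """All ROIs of a run: the live set plus retired ones kept for dumps.

    m/z matching uses a symmetric ppm tolerance on the ROI's most recent
    m/z.  Peaks and ROIs are matched greedily by smallest m/z distance, ties
    broken toward lower m/z; each peak extends at most one ROI and each ROI
    gains at most one peak per scan.  ROIs not extended by a scan are
    retired; retired ROIs shorter than ``min_points_to_keep`` are dropped
    from the dump entirely.
    """

    mz_tolerance_ppm: float = DEFAULT_MZ_TOLERANCE_PPM
    creation_intensity: float = DEFAULT_MIN_INTENSITY
    min_points_to_keep: int = 1
    active: list[ROI] = field(default_factory=list)
    discarded: list[ROI] = field(default_factory=list)
    _next_id: int = 0

    def _new_roi(self, rt: float, mz: float, intensity: float) -> ROI:
        roi = ROI(id=self._next_id, mz_trace=[mz], rt_trace=[rt],
                  intensity_trace=[intensity],
                  max_intensity_since_last_frag=intensity)
        self._next_id += 1
        return roi

    def update(self, scan: Scan) -> None:
        """Extend, retire and create ROIs from one MS1 scan."""
        if scan.level is not ScanLevel.MS1:
            raise ValueError("protocol error: ROI update needs an MS1 scan")
        mzs = [p[0] for p in scan.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("protocol error: MS1 peaks must be m/z-sorted")

        # Candidate (distance, peak_mz, roi) pairs within tolerance.
        candidates: list[tuple[float, float, int, int]] = []
        for pi, (mz, _) in enumerate(scan.peaks):
            for ri, roi in enumerate(self.active):
                tol = roi.mz * self.mz_tolerance_ppm * 1e-6
                d = abs(mz - roi.mz)
                if d <= tol:
                    candidates.append((d, mz, pi, ri))
        candidates.sort()  # by distance, then lower peak m/z, then index

        used_peaks: set[int] = set()
        used_rois: set[int] = set()
        for _, _, pi, ri in candidates:
            if pi in used_peaks or ri in used_rois:
                continue
            mz, intensity = scan.peaks[pi]
            self.active[ri].extend(scan.start_time, mz, intensity)
            used_peaks.add(pi)
            used_rois.add(ri)

        survivors: list[ROI] = []
        for ri, roi in enumerate(self.active):
            if ri in used_rois:
                survivors.append(roi)
            else:
                roi.active = False
                if roi.n_points >= self.min_points_to_keep:
                    self.discarded.append(roi)
        self.active = survivors

        for pi, (mz, intensity) in enumerate(scan.peaks):
            if pi not in used_peaks and intensity >= self.creation_intensity:
                self.active.append(
                    self._new_roi(scan.start_time, mz, intensity))
        self.active.sort(key=lambda r: r.mz)

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump (roi_id, point_index, rt, mz, intensity, status)
        for debugging and chromatogram plots."""
        rows = []
        for status, rois in (("active", self.active),
                             ("discarded", self.discarded)):
            for roi in rois:
                for j in range(roi.n_points):
                    rows.append((roi.id, j, roi.rt_trace[j], roi.mz_trace[j],
                                 roi.intensity_trace[j], status))
        return pd.DataFrame(
            rows, columns=["roi_id", "point_index", "rt", "mz", "intensity",
                           "status"]).sort_values(
            ["roi_id", "point_index"]).reset_index(drop=True)


def update_rois(store: ROIStore, scan: Scan) -> ROIStore:
    """Functional wrapper over :meth:`ROIStore.update` (mutates and returns
    the store)."""
    store.update(scan)
    return store
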