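"""Virtual LC-MS instrument: a simulated clock executing controller requests.

The event loop mirrors how a real-time acquisition API behaves from a
controller's point of view: the instrument completes a scan, hands any MS1
survey scan to the controller, and the controller answers with the MS2 scan
requests (and an optional shift directive) for the next duty cycle.  Scan
durations fold acquisition and controller-processing time into a single
per-level constant, so wall-clock effects of slower controllers are modelled
by a larger MS1 duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Protocol, Sequence

import pandas as pd

from .chem import Mixture, DEFAULT_MIN_INTENSITY

logger = logging.getLogger("ddasim")

ISOLATION_HALFWIDTH = 0.35  # Th; half of the 0.7 m/z isolation width

# Per-controller MS1 durations (seconds): scan time plus the controller's
# own processing time, measured between successive scan start times.
DEFAULT_MS1_DURATION = {
    "fullscan": 0.54,
    "topn": 0.56,
    "weighteddew": 0.61,
    "smartroi": 0.68,
}
DEFAULT_MS2_DURATION = 0.20


class ScanLevel(str, Enum):
    MS1 = "MS1"
    MS2 = "MS2"


@dataclass(frozen=True)
class Scan:
    """An executed scan.  MS1 scans carry centroided peaks; MS2 scans carry
    the isolated precursor m/z and the index of the survey scan that
    triggered them."""

    index: int
    level: ScanLevel
    start_time: float
    peaks: tuple[tuple[float, float], ...] = ()   # (mz, intensity), MS1 only
    precursor_mz: float | None = None             # MS2 only
    source_ms1_index: int | None = None           # MS2 only


@dataclass(frozen=True)
class ScanRequest:
    """A queued instruction for the instrument."""

    level: ScanLevel
    precursor_mz: float | None = None
    isolation_halfwidth: float = ISOLATION_HALFWIDTH
    source_ms1_index: int | None = None

    def __post_init__(self) -> None:
        if self.level is ScanLevel.MS2:
            if self.isolation_halfwidth <= 0:
                raise ValueError("isolation_halfwidth must be positive")
            if self.precursor_mz is None:
                raise ValueError("MS2 request needs a precursor m/z")


MS1_REQUEST = ScanRequest(level=ScanLevel.MS1)


@dataclass(frozen=True)
class ScanTimingModel:
    """Seconds consumed per scan, processing folded in."""

    ms1_duration: float = DEFAULT_MS1_DURATION["topn"]
    ms2_duration: float = DEFAULT_MS2_DURATION

    def __post_init__(self) -> None:
        if self.ms1_duration <= 0 or self.ms2_duration <= 0:
            raise ValueError("scan durations must be positive")


class Controller(Protocol):
    """The handle-scan contract consumed by :func:`run_acquisition`."""

    name: str
    shift_k: int

    def process_ms1(self, scan: Scan) -> list[ScanRequest]:
        """Return the MS2 requests derived from a completed MS1 scan."""
        ...


@dataclass
class AcquisitionLog:
    """Ordered record of every scan executed in one simulated injection."""

    scans: list[Scan]
    controller_name: str
    parameters: dict
    seed: int

    @property
    def ms1_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.level is ScanLevel.MS1]

    @property
    def ms2_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.level is ScanLevel.MS2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": [s.index for s in self.scans],
             "level": [s.level.value for s in self.scans],
             "start_time": [s.start_time for s in self.scans],
             "precursor_mz": [s.precursor_mz for s in self.scans],
             "source_ms1_index": [s.source_ms1_index for s in self.scans]})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def log_from_csv(path, controller_name: str = "unknown",
                 seed: int = 0) -> AcquisitionLog:
    df = pd.read_csv(path, float_precision="round_trip")
    scans = []
    for r in df.itertuples():
        level = ScanLevel(r.level)
        scans.append(Scan(
            index=int(r.index), level=level, start_time=float(r.start_time),
            precursor_mz=None if pd.isna(r.precursor_mz)
            else float(r.precursor_mz),
            source_ms1_index=None if pd.isna(r.source_ms1_index)
            else int(r.source_ms1_index)))
    return AcquisitionLog(scans=scans, controller_name=controller_name,
                          parameters={}, seed=seed)


def acquire_ms1(mixture: Mixture, t: float,
                detection_floor: float = DEFAULT_MIN_INTENSITY) -> Scan:
    """Synthesise the MS1 survey scan at time ``t``.

    Every chemical whose chromatogram is at or above ``detection_floor`` at
    ``t`` contributes one centroid at its true m/z; peaks are sorted by m/z.
    """
    if not 0.0 <= t <= mixture.run_length:
        raise ValueError(f"t={t} outside run [0, {mixture.run_length}]")
    inten = mixture.intensities_at(t)
    peaks = sorted(
        (float(mixture._mz[i]), float(inten[i]))
        for i in range(len(inten)) if inten[i] >= detection_floor)
    return Scan(index=-1, level=ScanLevel.MS1, start_time=t,
                peaks=tuple(peaks))


def apply_shift(requests: Sequence[ScanRequest],
                shift_k: int) -> list[ScanRequest]:
    """Order one duty cycle's queue, deferring ``shift_k`` MS2 scans past
    the next MS1 survey scan.

    With ``shift_k = 0`` the plan is the conventional duty cycle: all MS2
    scans, then the next MS1.  With ``shift_k = k`` the last ``k`` MS2
    requests execute *after* the next MS1 scan (they still derive from the
    triggering MS1), letting controller processing overlap acquisition.
    ``shift_k`` larger than the number of requests is clamped.
    """
    if shift_k < 0:
        raise ValueError("shift_k must be >= 0")
    n = len(requests)
    k = shift_k
    if k > n:
        logger.debug("shift_k=%d clamped to %d available MS2 requests",
                     shift_k, n)
        k = n
    head = list(requests[:n - k])
    tail = list(requests[n - k:])
    return head + [MS1_REQUEST] + tail


def run_acquisition(controller: Controller, mixture: Mixture,
                    timing: ScanTimingModel | None = None,
                    run_length: float | None = None,
                    detection_floor: float = DEFAULT_MIN_INTENSITY,
                    seed: int = 0) -> AcquisitionLog:
    """Execute ``controller`` against ``mixture`` on the simulated clock.

    The queue starts with a single MS1 request.  Each executed scan advances
    the clock by its level's duration; after each MS1 scan the controller is
    consulted and its requests are queued according to its ``shift_k``.  The
    loop ends when the next scan would start at or after ``run_length``.
    The result is fully deterministic for fixed inputs.
    """
    if timing is None:
        timing = ScanTimingModel(
            ms1_duration=DEFAULT_MS1_DURATION.get(
                controller.name, DEFAULT_MS1_DURATION["topn"]),
            ms2_duration=DEFAULT_MS2_DURATION)
    if run_length is None:
        run_length = mixture.run_length

    scans: list[Scan] = []
    queue: list[ScanRequest] = [MS1_REQUEST]
    clock = 0.0
    index = 0
    last_ms1_index: int | None = None

    while queue and clock < run_length:
        req = queue.pop(0)
        if req.level is ScanLevel.MS1:
            scan = acquire_ms1(mixture, min(clock, mixture.run_length),
                               detection_floor)
            scan = Scan(index=index, level=ScanLevel.MS1, start_time=clock,
                        peaks=scan.peaks)
            last_ms1_index = index
            scans.append(scan)
            clock += timing.ms1_duration
            requests = controller.process_ms1(scan)
            for r in requests:
                if r.source_ms1_index is None:
                    raise ValueError(
                        "protocol error: MS2 request lacks a source MS1")
            queue.extend(apply_shift(requests, controller.shift_k))
        else:
            if last_ms1_index is None:
                raise ValueError(
                    "protocol error: MS2 request before any MS1 scan")
            scans.append(Scan(index=index, level=ScanLevel.MS2,
                              start_time=clock,
                              precursor_mz=req.precursor_mz,
                              source_ms1_index=req.source_ms1_index))
            clock += timing.ms2_duration
        logger.debug("scan %d %s t=%.3f", index, scans[-1].level.value,
                     scans[-1].start_time)
        index += 1

    params = dict(getattr(controller, "parameters", {}) or {})
    params.update({"ms1_duration": timing.ms1_duration,
                   "ms2_duration": timing.ms2_duration,
                   "run_length": run_length,
                   "detection_floor": detection_floor})
    return AcquisitionLog(scans=scans, controller_name=controller.name,
                          parameters=params, seed=seed)
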