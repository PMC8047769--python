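"""DDA acquisition controllers behind a single handle-scan contract.

Four strategies are provided:

* **fullscan** — MS1 survey scans only; used to establish the peak set.
* **topn** — fragment the N most intense eligible ions of each survey scan,
  with a binary dynamic exclusion window (DEW) of ``t0`` seconds.
* **weighteddew** — TopN with the binary exclusion generalised to a weight
  that ramps linearly from 0 at ``t0`` to 1 at ``t1`` seconds after the last
  fragmentation of an m/z; ions are ranked by intensity x weight.  With
  ``t1 = t0`` this reduces exactly to the binary DEW.
* **smartroi** — tracks regions of interest in real time and fragments the
  N most intense *available* ROIs (availability rules in :mod:`ddasim.roi`),
  optionally with shifted scheduling to overlap its heavier processing with
  acquisition.

Selection ordering is deterministic: descending priority, ties broken by
higher m/z, then earlier peak index, so repeated runs are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

from .chem import DEFAULT_MIN_INTENSITY
from .instrument import (ISOLATION_HALFWIDTH, Scan, ScanLevel, ScanRequest)
from .roi import (DEFAULT_MZ_TOLERANCE_PPM, ROIStore, smartroi_available)

# Defaults carried over from the TopN optimisation of the earlier simulator
# validation (N and the 15 s exclusion window) and from the grid search for
# the two new strategies (alpha, beta, t0, t1).
DEFAULT_N = 10
DEFAULT_DEW = 15.0        # s; binary exclusion window / WeightedDEW t0
DEFAULT_T1 = 120.0        # s; WeightedDEW full-weight horizon
DEFAULT_ALPHA = 1000.0    # SmartROI re-fragmentation rise factor
DEFAULT_BETA = 0.1        # SmartROI post-maximum drop fraction


@dataclass
class ControllerConfig:
    """Parameter bundle understood by every controller."""

    N: int = DEFAULT_N
    min_intensity: float = DEFAULT_MIN_INTENSITY
    isolation_halfwidth: float = ISOLATION_HALFWIDTH
    mz_tolerance_ppm: float = DEFAULT_MZ_TOLERANCE_PPM
    t0: float = DEFAULT_DEW          # DEW window (binary and weighted)
    t1: float = DEFAULT_T1           # WeightedDEW horizon; t1 = t0 => binary
    alpha: float = DEFAULT_ALPHA     # SmartROI
    beta: float = DEFAULT_BETA       # SmartROI
    shift_k: int = 0                 # MS2 scans deferred past the next MS1

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.min_intensity <= 0:
            raise ValueError("min_intensity must be positive")
        if self.t1 < self.t0 or self.t0 < 0:
            raise ValueError("require t1 >= t0 >= 0")


@dataclass
class DEWState:
    """Dynamic-exclusion bookkeeping: the last fragmentation time per m/z.

    Matching is by ppm tolerance; when several records match, the most
    recent fragmentation time wins.  Re-fragmenting an m/z overwrites its
    matching record rather than appending a new one.
    """

    mz_tolerance_ppm: float = DEFAULT_MZ_TOLERANCE_PPM
    records: list[tuple[float, float]] = field(default_factory=list)  # (mz, t_f)

    def last_frag_time(self, mz: float) -> float | None:
        tol = mz * self.mz_tolerance_ppm * 1e-6
        times = [t_f for m, t_f in self.records if abs(m - mz) <= tol]
        return max(times) if times else None

    def record(self, mz: float, t: float) -> None:
        tol = mz * self.mz_tolerance_ppm * 1e-6
        for i, (m, _) in enumerate(self.records):
            if abs(m - mz) <= tol:
                self.records[i] = (mz, t)
                return
        self.records.append((mz, t))


def weighted_dew_weight(t: float, t_f: float, t0: float, t1: float) -> float:
    """Exclusion weight of an ion fragmented at ``t_f``, observed at ``t``.

    0 for the first ``t0`` seconds after fragmentation, then linear up to 1
    at ``t1``; with ``t1 = t0`` this is the binary DEW indicator.
    """
    if t < t_f:
        raise ValueError("protocol error: observation precedes fragmentation")
    if t1 < t0:
        raise ValueError("require t1 >= t0")
    elapsed = t - t_f
    if elapsed <= t0:
        return 0.0
    if elapsed >= t1:
        return 1.0
    return (elapsed - t0) / (t1 - t0)


def _rank_and_take(candidates: list[tuple[float, float, int]],
                   n: int) -> list[tuple[float, float, int]]:
    """Top ``n`` of (priority, mz, peak_index), descending priority with
    ties to higher m/z then earlier index."""
    return sorted(candidates, key=lambda c: (-c[0], -c[1], c[2]))[:n]


def topn_select(scan: Scan, cfg: ControllerConfig,
                dew: DEWState) -> list[ScanRequest]:
    """Binary-DEW TopN selection from one survey scan.

    Eligible peaks meet the intensity floor and are not excluded (an m/z is
    excluded while ``t - t_f <= t0`` for a matching DEW record).  The up-to-N
    most intense eligible peaks are requested and recorded in the DEW.
    """
    t = scan.start_time
    candidates = []
    for i, (mz, intensity) in enumerate(scan.peaks):
        if intensity < cfg.min_intensity:
            continue
        t_f = dew.last_frag_time(mz)
        if t_f is not None and t - t_f <= cfg.t0:
            continue
        candidates.append((intensity, mz, i))
    chosen = _rank_and_take(candidates, cfg.N)
    requests = []
    for _, mz, _ in chosen:
        dew.record(mz, t)
        requests.append(ScanRequest(
            level=ScanLevel.MS2, precursor_mz=mz,
            isolation_halfwidth=cfg.isolation_halfwidth,
            source_ms1_index=scan.index))
    return requests


def weighted_dew_select(scan: Scan, cfg: ControllerConfig,
                        dew: DEWState) -> list[ScanRequest]:
    """WeightedDEW selection: rank above-floor peaks by intensity x weight.

    Never-fragmented peaks have weight 1.  Only strictly positive priorities
    are requestable; the top N are selected and their fragmentation times
    recorded.
    """
    t = scan.start_time
    candidates = []
    for i, (mz, intensity) in enumerate(scan.peaks):
        if intensity < cfg.min_intensity:
            continue
        t_f = dew.last_frag_time(mz)
        w = 1.0 if t_f is None else weighted_dew_weight(t, t_f, cfg.t0, cfg.t1)
        priority = intensity * w
        if priority > 0.0:
            candidates.append((priority, mz, i))
    chosen = _rank_and_take(candidates, cfg.N)
    requests = []
    for _, mz, _ in chosen:
        dew.record(mz, t)
        requests.append(ScanRequest(
            level=ScanLevel.MS2, precursor_mz=mz,
            isolation_halfwidth=cfg.isolation_halfwidth,
            source_ms1_index=scan.index))
    return requests


def smartroi_select(store: ROIStore, cfg: ControllerConfig,
                    scan: Scan) -> list[ScanRequest]:
    """Request the N most intense available ROIs after a store update.

    Selected ROIs record the fragmentation (flag, intensity, time) and reset
    their running maximum; the precursor is the ROI's most recent m/z.
    """
    candidates = []
    for i, roi in enumerate(store.active):
        if smartroi_available(roi, cfg.min_intensity, cfg.alpha, cfg.beta):
            candidates.append((roi.current_intensity, roi.mz, i))
    chosen = _rank_and_take(candidates, cfg.N)
    requests = []
    for _, _, i in chosen:
        roi = store.active[i]
        roi.mark_fragmented(scan.start_time)
        requests.append(ScanRequest(
            level=ScanLevel.MS2, precursor_mz=roi.mz,
            isolation_halfwidth=cfg.isolation_halfwidth,
            source_ms1_index=scan.index))
    return requests


# ---------------------------------------------------------------------------
# Controller classes implementing the instrument's handle-scan contract.

class _BaseController:
    name = "base"

    def __init__(self, cfg: ControllerConfig | None = None) -> None:
        self.cfg = cfg or ControllerConfig()
        self.shift_k = self.cfg.shift_k

    @property
    def parameters(self) -> dict:
        return asdict(self.cfg)

    def process_ms1(self, scan: Scan) -> list[ScanRequest]:
        raise NotImplementedError


class FullScanController(_BaseController):
    """Survey scans only — no fragmentation."""

    name = "fullscan"

    def process_ms1(self, scan: Scan) -> list[ScanRequest]:
        return []


class TopNController(_BaseController):
    """Conventional TopN DDA with a binary dynamic exclusion window."""

    name = "topn"

    def __init__(self, cfg: ControllerConfig | None = None) -> None:
        super().__init__(cfg)
        self.dew = DEWState(mz_tolerance_ppm=self.cfg.mz_tolerance_ppm)

    def process_ms1(self, scan: Scan) -> list[ScanRequest]:
        return topn_select(scan, self.cfg, self.dew)


class WeightedDEWController(_BaseController):
    """TopN with linearly decaying exclusion (weights in [0, 1])."""

    name = "weighteddew"

    def __init__(self, cfg: ControllerConfig | None = None) -> None:
        super().__init__(cfg)
        self.dew = DEWState(mz_tolerance_ppm=self.cfg.mz_tolerance_ppm)

    def process_ms1(self, scan: Scan) -> list[ScanRequest]:
        return weighted_dew_select(scan, self.cfg, self.dew)


class SmartROIController(_BaseController):
    """ROI-tracking controller with availability-gated re-fragmentation."""

    name = "smartroi"

    def __init__(self, cfg: ControllerConfig | None = None) -> None:
        super().__init__(cfg)
        # Degenerate but legal regimes: alpha <= 1 re-fragments on any scan
        # via rule 3a; beta >= 1 via rule 3b.
        if self.cfg.alpha <= 1.0:
            warnings.warn(f"alpha={self.cfg.alpha} <= 1: rule 3a always "
                          "holds while above the floor", stacklevel=2)
        if self.cfg.beta >= 1.0:
            warnings.warn(f"beta={self.cfg.beta} >= 1: rule 3b always "
                          "holds while above the floor", stacklevel=2)
        self.store = ROIStore(mz_tolerance_ppm=self.cfg.mz_tolerance_ppm,
                              creation_intensity=self.cfg.min_intensity)

    def process_ms1(self, scan: Scan) -> list[ScanRequest]:
        self.store.update(scan)
        return smartroi_select(self.store, self.cfg, scan)


CONTROLLERS = {
    "fullscan": FullScanController,
    "topn": TopNController,
    "weighteddew": WeightedDEWController,
    "smartroi": SmartROIController,
}


def make_controller(name: str,
                    cfg: ControllerConfig | None = None) -> _BaseController:
    """Construct a controller by name (``CONTROLLERS`` keys)."""
    try:
        cls = CONTROLLERS[name]
    except KeyError:
        raise ValueError(f"unknown controller {name!r}; "
                         f"choose from {sorted(CONTROLLERS)}") from None
    return cls(cfg)
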