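"""Synthetic chemical mixtures with known chromatographic ground truth.

Every downstream stage of the framework (virtual instrument, controllers,
optimal-coverage bound, evaluation) is exercised against mixtures produced
here, so the generator doubles as the test fixture factory.  Each analyte is
a single charged species with a fixed m/z and a Gaussian elution profile; the
"true" picked-peak bounding boxes follow in closed form from the profile and
a detection floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# Default study conditions, shared across the package so that ground-truth
# boxes and controller eligibility stay consistent (a box exists exactly when
# the controllers could in principle fragment the analyte).
DEFAULT_MIN_INTENSITY = 5e3      # minimum MS1 intensity for fragmentation
DEFAULT_MZ_BOX_HALFWIDTH = 0.01  # Th; half-width of a picked-peak box in m/z
DEFAULT_MZ_RANGE = (70.0, 1000.0)      # Th, positive-mode metabolomics window
DEFAULT_INTENSITY_RANGE = (1e4, 1e7)   # log-uniform apex intensities
DEFAULT_WIDTH_RANGE = (3.0, 10.0)      # seconds (Gaussian sigma)


@dataclass(frozen=True)
class Chemical:
    """A ground-truth analyte: one m/z with a Gaussian chromatogram."""

    id: str
    mz: float                 # Th
    rt_apex: float            # seconds
    max_intensity: float      # arbitrary ion-count units
    width_sigma: float        # seconds; chromatogram standard deviation

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.max_intensity <= 0:
            raise ValueError("max_intensity must be positive")
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")


@dataclass(frozen=True)
class PeakBoundingBox:
    """A picked chromatographic peak: a rectangle in (m/z, RT) space."""

    id: str
    mz_min: float
    mz_max: float
    rt_min: float
    rt_max: float
    apex_intensity: float | None = None

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("require mz_min < mz_max")
        if not self.rt_min < self.rt_max:
            raise ValueError("require rt_min < rt_max")

    def contains(self, mz: float, rt: float) -> bool:
        """Inclusive containment test used for event-to-box assignment."""
        return (self.mz_min <= mz <= self.mz_max
                and self.rt_min <= rt <= self.rt_max)


@dataclass(frozen=True)
class Mixture:
    """An immutable collection of chemicals plus the run length (seconds)."""

    chemicals: tuple[Chemical, ...]
    run_length: float
    seed: int = 0
    # Parallel arrays for fast vectorised chromatogram evaluation.
    _mz: np.ndarray = field(init=False, repr=False, compare=False)
    _apex: np.ndarray = field(init=False, repr=False, compare=False)
    _max_i: np.ndarray = field(init=False, repr=False, compare=False)
    _sigma: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chemicals]
        if len(set(ids)) != len(ids):
            raise ValueError("chemical ids must be unique")
        for c in self.chemicals:
            if not 0.0 <= c.rt_apex <= self.run_length:
                raise ValueError(
                    f"rt_apex {c.rt_apex} of {c.id} outside run "
                    f"[0, {self.run_length}]")
        object.__setattr__(self, "_mz",
                           np.array([c.mz for c in self.chemicals]))
        object.__setattr__(self, "_apex",
                           np.array([c.rt_apex for c in self.chemicals]))
        object.__setattr__(self, "_max_i",
                           np.array([c.max_intensity for c in self.chemicals]))
        object.__setattr__(self, "_sigma",
                           np.array([c.width_sigma for c in self.chemicals]))

    def __len__(self) -> int:
        return len(self.chemicals)

    def intensities_at(self, t: float) -> np.ndarray:
        """Vectorised ``intensity_at`` over every chemical in the mixture."""
        if len(self.chemicals) == 0:
            return np.empty(0)
        z = (t - self._apex) / self._sigma
        return self._max_i * np.exp(-0.5 * z * z)


def intensity_at(chem: Chemical, t: float) -> float:
    """MS1 intensity of ``chem`` at time ``t`` (seconds).

    Gaussian elution profile: ``max_intensity * exp(-(t - rt_apex)^2 /
    (2 sigma^2))``, symmetric about the apex.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    z = (t - chem.rt_apex) / chem.width_sigma
    return chem.max_intensity * math.exp(-0.5 * z * z)


def generate_mixture(
    n_chems: int,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    rt_range: tuple[float, float] = (0.0, 400.0),
    intensity_range: tuple[float, float] = DEFAULT_INTENSITY_RANGE,
    width_range: tuple[float, float] = DEFAULT_WIDTH_RANGE,
    seed: int = 0,
) -> Mixture:
    """Draw a reproducible random mixture of ``n_chems`` chemicals.

    m/z, apex RT and Gaussian width are uniform over their ranges; apex
    intensities are log-uniform over ``intensity_range``, reflecting the wide
    dynamic range of real extracts.  The run length is ``rt_range[1]``.

    Coelution density is controlled by ``n_chems`` relative to the RT range:
    at any instant roughly ``n_chems * 6 * mean_sigma / span`` analytes elute
    simultaneously.
    """
    if n_chems < 0:
        raise ValueError("n_chems must be >= 0")
    for name, (lo, hi) in (("mz_range", mz_range), ("rt_range", rt_range),
                           ("intensity_range", intensity_range),
                           ("width_range", width_range)):
        if not lo < hi:
            raise ValueError(f"{name} must be a non-degenerate interval")
    if intensity_range[0] <= 0:
        raise ValueError("intensities must be positive")

    rng = np.random.default_rng(seed)
    mz = rng.uniform(*mz_range, size=n_chems)
    rt = rng.uniform(*rt_range, size=n_chems)
    log_i = rng.uniform(math.log(intensity_range[0]),
                        math.log(intensity_range[1]), size=n_chems)
    sigma = rng.uniform(*width_range, size=n_chems)
    chems = tuple(
        Chemical(id=f"chem_{i:05d}", mz=float(mz[i]), rt_apex=float(rt[i]),
                 max_intensity=float(math.exp(log_i[i])),
                 width_sigma=float(sigma[i]))
        for i in range(n_chems))
    return Mixture(chemicals=chems, run_length=float(rt_range[1]), seed=seed)


def ground_truth_boxes(
    mixture: Mixture,
    detection_floor: float = DEFAULT_MIN_INTENSITY,
    mz_box_halfwidth: float = DEFAULT_MZ_BOX_HALFWIDTH,
) -> list[PeakBoundingBox]:
    """True picked-peak boxes implied by the mixture and a detection floor.

    A chemical whose apex intensity exceeds ``detection_floor`` yields one
    box.  RT bounds are where the Gaussian crosses the floor,
    ``rt_apex +/- sigma * sqrt(2 ln(max/floor))``, clipped to the run; m/z
    bounds are ``mz +/- mz_box_halfwidth``.  Box ids equal chemical ids.
    """
    if detection_floor <= 0:
        raise ValueError("detection_floor must be positive")
    boxes: list[PeakBoundingBox] = []
    for c in mixture.chemicals:
        if c.max_intensity <= detection_floor:
            continue
        half = c.width_sigma * math.sqrt(
            2.0 * math.log(c.max_intensity / detection_floor))
        boxes.append(PeakBoundingBox(
            id=c.id,
            mz_min=c.mz - mz_box_halfwidth,
            mz_max=c.mz + mz_box_halfwidth,
            rt_min=max(0.0, c.rt_apex - half),
            rt_max=min(mixture.run_length, c.rt_apex + half),
            apex_intensity=c.max_intensity,
        ))
    return boxes


# ---------------------------------------------------------------------------
# CSV serialisation.  RT is seconds everywhere inside the package; MZmine2
# exports minutes, hence the rt_minutes import flag.

def mixture_to_csv(mixture: Mixture, path) -> None:
    df = pd.DataFrame(
        {"id": [c.id for c in mixture.chemicals],
         "mz": [c.mz for c in mixture.chemicals],
         "rt_apex": [c.rt_apex for c in mixture.chemicals],
         "max_intensity": [c.max_intensity for c in mixture.chemicals],
         "width_sigma": [c.width_sigma for c in mixture.chemicals]})
    df.to_csv(path, index=False, float_format="%.17g")


def mixture_from_csv(path, run_length: float | None = None,
                     seed: int = 0) -> Mixture:
    df = pd.read_csv(path, float_precision="round_trip")
    chems = tuple(
        Chemical(id=str(r.id), mz=float(r.mz), rt_apex=float(r.rt_apex),
                 max_intensity=float(r.max_intensity),
                 width_sigma=float(r.width_sigma))
        for r in df.itertuples())
    if run_length is None:
        run_length = max((c.rt_apex for c in chems), default=0.0)
    return Mixture(chemicals=chems, run_length=float(run_length), seed=seed)


def boxes_to_csv(boxes: Sequence[PeakBoundingBox], path) -> None:
    df = pd.DataFrame(
        {"id": [b.id for b in boxes],
         "mz_min": [b.mz_min for b in boxes],
         "mz_max": [b.mz_max for b in boxes],
         "rt_min": [b.rt_min for b in boxes],
         "rt_max": [b.rt_max for b in boxes]})
    df.to_csv(path, index=False, float_format="%.17g")


def boxes_from_csv(path, rt_minutes: bool = False) -> list[PeakBoundingBox]:
    """Load picked-peak boxes from a CSV export.

    ``rt_minutes=True`` converts MZmine2-style minute RT columns to seconds.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    scale = 60.0 if rt_minutes else 1.0
    return [PeakBoundingBox(id=str(r.id), mz_min=float(r.mz_min),
                            mz_max=float(r.mz_max),
                            rt_min=float(r.rt_min) * scale,
                            rt_max=float(r.rt_max) * scale)
            for r in df.itertuples()]
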