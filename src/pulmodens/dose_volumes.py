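"""Dose-defined lung subvolumes.

The lung is partitioned by isodose levels expressed as % of the prescription
dose. *Total* volumes Vx% contain every lung voxel receiving at least x% of
the prescription; *differential* volumes V(a-b)% contain lung voxels
receiving at least b% but less than a% (half-open [b, a) intervals, so
consecutive differential volumes tile the lung exactly; a = Dmax means no
upper cut). All subvolumes are intersected with the lung mask; an optional
PTV mask can be carved out of the lung first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DMAX,
    PatientSeries,
    ScalarVolume,
    VolumeMask,
    VolumeRange,
    require_same_frame,
)


def standard_levels() -> list[float]:
    """The standard isodose ladder: 105% down to 5% in 10% decrements."""
    return [105.0, 95.0, 85.0, 75.0, 65.0, 55.0, 45.0, 35.0, 25.0, 15.0, 5.0]


def standard_differential_ranges() -> list[VolumeRange]:
    """Consecutive differential ranges (105-95, 95-85, ..., 15-5)."""
    lv = standard_levels()
    return [VolumeRange(high=a, low=b) for a, b in zip(lv[:-1], lv[1:])]


def triangle_ranges() -> list[VolumeRange]:
    """The correlation-triangle family: high in {Dmax, 95, 85, 75, 65},
    low in {95, 85, ..., 5} with low < high — 40 (high, low) cells."""
    highs: list[float] = [DMAX, 95.0, 85.0, 75.0, 65.0]
    lows = [95.0, 85.0, 75.0, 65.0, 55.0, 45.0, 35.0, 25.0, 15.0, 5.0]
    return [
        VolumeRange(high=h, low=lo)
        for h in highs
        for lo in lows
        if lo < h
    ]


def prediction_ranges() -> list[VolumeRange]:
    """Default 10-range family for the volume-size prediction analysis.

    Mid-dose differential ranges of varying width around the 45-65% window,
    matching a Bonferroni family size of 10.
    """
    pairs = [
        (95, 25), (85, 35), (85, 25), (75, 45), (75, 35),
        (75, 25), (65, 45), (65, 35), (65, 25), (55, 35),
    ]
    return [VolumeRange(high=float(a), low=float(b)) for a, b in pairs]


def effective_lung(lung: VolumeMask, ptv: Optional[VolumeMask], exclude_ptv: bool) -> VolumeMask:
    """Lung mask, optionally with the PTV carved out."""
    if exclude_ptv and ptv is not None:
        require_same_frame(lung, ptv, "lung/ptv")
        return VolumeMask(lung.values & ~ptv.values, spacing=lung.spacing, origin=lung.origin)
    return lung


def total_isodose_mask(
    dose: ScalarVolume,
    lung: VolumeMask,
    level_pct: float,
    prescription_gy: float,
) -> VolumeMask:
    """Lung voxels receiving at least ``level_pct``% of the prescription (inclusive)."""
    require_same_frame(dose, lung, "dose/lung")
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0")
    threshold = level_pct / 100.0 * prescription_gy
    sel = lung.values & (dose.values >= threshold)
    return VolumeMask(sel, spacing=dose.spacing, origin=dose.origin)


def differential_mask(
    dose: ScalarVolume,
    lung: VolumeMask,
    rng: VolumeRange,
    prescription_gy: float,
) -> VolumeMask:
    """Lung voxels with dose in [low, high) % of prescription; high=Dmax → no upper cut."""
    require_same_frame(dose, lung, "dose/lung")
    lo_gy = rng.low / 100.0 * prescription_gy
    sel = lung.values & (dose.values >= lo_gy)
    if not rng.is_open_top:
        hi_gy = rng.high / 100.0 * prescription_gy
        sel = sel & (dose.values < hi_gy)
    return VolumeMask(sel, spacing=dose.spacing, origin=dose.origin)


def measure(mask: VolumeMask, lung: VolumeMask) -> tuple[float, float]:
    """(absolute volume in mL, relative size in % of the lung volume)."""
    require_same_frame(mask, lung, "mask/lung")
    n_lung = lung.count
    if n_lung == 0:
        raise ValueError("lung mask is empty; relative size undefined")
    volume_ml = mask.count * mask.voxel_volume_mm3 / 1000.0
    relative_pct = 100.0 * mask.count / n_lung
    return volume_ml, relative_pct


@dataclass
class DoseVolumeSet:
    """All requested subvolume masks and sizes for one patient."""

    patient_id: str
    ranges: list[VolumeRange]
    masks: dict[VolumeRange, VolumeMask] = field(repr=False)
    volumes_ml: dict[VolumeRange, float]
    relative_size_pct: dict[VolumeRange, float]


def build_dose_volume_set(
    patient: PatientSeries,
    ranges: Sequence[VolumeRange],
    exclude_ptv: bool = False,
) -> DoseVolumeSet:
    """Differential masks and sizes for one patient over the requested ranges.

    Masks are computed once on the planning frame and reused for every CT
    time point (all volumes share the frame by construction).
    """
    lung = effective_lung(patient.lung, patient.ptv, exclude_ptv)
    masks: dict[VolumeRange, VolumeMask] = {}
    vols: dict[VolumeRange, float] = {}
    rels: dict[VolumeRange, float] = {}
    for rng in ranges:
        m = differential_mask(patient.dose, lung, rng, patient.prescription_dose)
        masks[rng] = m
        vols[rng], rels[rng] = measure(m, lung)
    return DoseVolumeSet(
        patient_id=patient.patient_id,
        ranges=list(ranges),
        masks=masks,
        volumes_ml=vols,
        relative_size_pct=rels,
    )


def volume_table(
    cohort: Sequence[PatientSeries],
    ranges: Sequence[VolumeRange],
    exclude_ptv: bool = False,
) -> pd.DataFrame:
    """Tidy cohort table of subvolume sizes: patient_id, range, volume_ml,
    relative_size_pct."""
    rows = []
    for patient in cohort:
        dvs = build_dose_volume_set(patient, ranges, exclude_ptv=exclude_ptv)
        for rng in ranges:
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "range": rng.label,
                    "volume_ml": dvs.volumes_ml[rng],
                    "relative_size_pct": dvs.relative_size_pct[rng],
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "range", "volume_ml", "relative_size_pct"]
    )


def dose_band_labels(
    dose: ScalarVolume,
    lung: VolumeMask,
    prescription_gy: float,
    levels: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, list[float]]:
    """Label each lung voxel with the index of its isodose band.

    Levels (descending, % of prescription) split the dose axis into
    ``len(levels)+1`` bands: band 0 is dose >= levels[0], band i is
    [levels[i], levels[i-1]), and the last band is below the lowest level.
    Returns the flat label array over lung voxels plus the level list; any
    differential-range statistic over the standard ladder can then be reduced
    to sums over these bands.
    """
    require_same_frame(dose, lung, "dose/lung")
    lv = sorted(levels if levels is not None else standard_levels(), reverse=True)
    thresholds = np.array([l / 100.0 * prescription_gy for l in lv])
    d = dose.values[lung.values]
    # band index = number of thresholds strictly above the voxel dose,
    # which keeps the lower bound of every band inclusive
    labels = np.searchsorted(-thresholds, -d, side="left")
    return labels, lv
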