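"""Mean HU and the relative density number n_rho per dose subvolume.

CT density in the lung depends on acquisition conditions (inspiration level,
contrast agent, protocol), so the mean HU of a dose-defined subvolume is
normalized by the mean HU of the whole lung on the *same* scan:

    n_rho = mean_HU(subvolume) / mean_HU(whole lung)

Aerated lung is strongly negative (~ -750 HU), so n_rho is positive and
typically below 1 for tissue more transparent than it is dense, and it
*decreases* (towards zero and into negative values) as the subvolume
densifies. A post-RT density increase therefore shows up as a drop in n_rho.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_volumes import dose_band_labels, effective_lung
from .types import (
    TIMEPOINTS,
    DensitySample,
    PatientSeries,
    ScalarVolume,
    VolumeMask,
    VolumeRange,
    require_same_frame,
)

logger = logging.getLogger(__name__)

#: Refuse to normalize when |mean lung HU| is below this floor (HU): a lung
#: that dense indicates an input problem, and the ratio becomes unstable.
LUNG_MEAN_FLOOR_HU = 50.0


def mean_hu(ct: ScalarVolume, mask: VolumeMask) -> float:
    """Arithmetic mean of the CT values over the mask voxels."""
    require_same_frame(ct, mask, "ct/mask")
    if mask.count == 0:
        raise ValueError("mask is empty; mean HU undefined")
    return float(ct.values[mask.values].mean())


def relative_density(
    ct: ScalarVolume,
    mask: VolumeMask,
    lung: VolumeMask,
    floor_hu: float = LUNG_MEAN_FLOOR_HU,
) -> float:
    """n_rho = mean HU over ``mask`` divided by mean HU over the whole lung."""
    mu_lung = mean_hu(ct, lung)
    if abs(mu_lung) < floor_hu:
        raise ValueError(
            f"whole-lung mean HU is {mu_lung:.1f}, within {floor_hu} HU of zero; "
            "normalization undefined (is the lung mask aerated lung?)"
        )
    return mean_hu(ct, mask) / mu_lung


def density_timeseries(
    patient: PatientSeries,
    ranges: Sequence[VolumeRange],
    exclude_ptv: bool = False,
    floor_hu: float = LUNG_MEAN_FLOOR_HU,
) -> list[DensitySample]:
    """One DensitySample per (range, available CT time point).

    Time points without a CT yield no sample (logged); empty subvolumes raise
    with the patient/range identity. For ranges drawn from a shared isodose
    ladder the per-voxel work is done once per scan via dose-band sums, which
    is exact: the mean over [b, a) is the count-weighted mean of the
    consecutive bands it spans.
    """
    lung = effective_lung(patient.lung, patient.ptv, exclude_ptv)
    if lung.count == 0:
        raise ValueError(f"patient {patient.patient_id}: lung mask is empty")

    # all band edges needed by the requested ranges
    edges = sorted(
        {r.low for r in ranges} | {r.high for r in ranges if not r.is_open_top},
        reverse=True,
    )
    labels, levels = dose_band_labels(
        patient.dose, lung, patient.prescription_dose, levels=edges
    )
    n_bands = len(levels) + 1
    counts = np.bincount(labels, minlength=n_bands).astype(float)
    # band index span covered by a range: bands strictly below `high` down to
    # (and including) the band whose lower edge is `low`
    level_pos = {lv: i for i, lv in enumerate(levels)}

    def band_span(r: VolumeRange) -> slice:
        lo_band = level_pos[r.low]  # band with lower edge == r.low
        hi_band = 0 if r.is_open_top else level_pos[r.high] + 1
        return slice(hi_band, lo_band + 1)

    samples: list[DensitySample] = []
    for tp in TIMEPOINTS:
        ct = patient.ct.get(tp)
        if ct is None:
            logger.info("patient %s: no CT at %s, skipping", patient.patient_id, tp)
            continue
        require_same_frame(patient.dose, ct, f"dose/ct[{tp}] of {patient.patient_id}")
        hu = ct.values[lung.values]
        sums = np.bincount(labels, weights=hu, minlength=n_bands)
        mu_lung = float(hu.mean())
        if abs(mu_lung) < floor_hu:
            raise ValueError(
                f"patient {patient.patient_id} at {tp}: whole-lung mean HU "
                f"{mu_lung:.1f} is within {floor_hu} HU of zero; cannot normalize"
            )
        for r in ranges:
            sp = band_span(r)
            n = counts[sp].sum()
            if n == 0:
                raise ValueError(
                    f"patient {patient.patient_id}, range {r.label} at {tp}: "
                    "subvolume is empty"
                )
            mu = float(sums[sp].sum() / n)
            samples.append(
                DensitySample(
                    patient_id=patient.patient_id,
                    range=r,
                    timepoint=tp,
                    mean_hu_volume=mu,
                    mean_hu_lung=mu_lung,
                    n_rho=mu / mu_lung,
                )
            )
    return samples


def density_table(
    cohort: Sequence[PatientSeries],
    ranges: Sequence[VolumeRange],
    exclude_ptv: bool = False,
) -> pd.DataFrame:
    """Tidy cohort density table: patient_id, range, timepoint, means, n_rho."""
    rows = []
    for patient in cohort:
        for s in density_timeseries(patient, ranges, exclude_ptv=exclude_ptv):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "range": s.range.label,
                    "timepoint": s.timepoint,
                    "mean_hu_volume": s.mean_hu_volume,
                    "mean_hu_lung": s.mean_hu_lung,
                    "n_rho": s.n_rho,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "range",
            "timepoint",
            "mean_hu_volume",
            "mean_hu_lung",
            "n_rho",
        ],
    )
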