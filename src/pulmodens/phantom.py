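"""Synthetic thorax-cohort generator with known ground truth.

Each phantom patient consists of a planning dose grid, a two-ellipsoid lung
mask, three CT volumes (baseline, 3 and 6 months post-RT) and PFT records,
all on one shared frame. The generative model plants exactly the structure
the analysis is built to detect, with every knob exposed:

* **Dose**: prescription inside a spherical tumor, exponential falloff with
  distance from the tumor surface (length scale ``falloff_mm``).
* **Injury**: post-RT HU increase inside the lung following a sigmoid in
  local dose (midpoint ``injury_midpoint_pct`` % of prescription, width
  ``injury_width_pct``), scaled by a per-patient lognormal susceptibility
  and partially recovered at 6 months (``recovery_factor`` of the 3-month
  injury remains).
* **Function**: DLCO/FEV1 decline proportionally (coupling ``gamma``) to the
  injury *burden*, the volume-weighted mean sigmoid response over the lung;
  ``gamma = 0`` is the exact null scenario. Multiplicative measurement noise
  on top.
* **Confounders** that real follow-up CTs carry and that limit which dose
  bands stay informative: spatially correlated scan noise (texture with a
  correlation length of a few voxels, so thin shells average fewer
  independent patches), a dense tumor mass whose radius and apparent
  position change unpredictably between scans (regression/consolidation and
  residual registration error), which decorrelates the high-dose bands from
  function — the same reason the clinical analysis finds its signal in the
  mid-dose range rather than inside the target volume.

All randomness flows from one seed through per-patient ``SeedSequence``
substreams, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .types import (
    TIMEPOINTS,
    PatientSeries,
    PFTRecord,
    ScalarVolume,
    VolumeMask,
)


@dataclass(frozen=True)
class PhantomSpec:
    """All parameters of the synthetic cohort. Defaults define the reference
    study conditions used throughout the test-suite and worked examples."""

    # geometry
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)  # mm
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (14.0, 24.0, 24.0),
        (34.0, 24.0, 24.0),
    )  # voxels
    lung_semiaxes: tuple[tuple[float, float, float], ...] = (
        (8.0, 11.0, 17.0),
        (8.0, 11.0, 17.0),
    )  # voxels
    tumor_center: tuple[float, float, float] = (33.0, 24.0, 24.0)  # voxels
    tumor_radius_vox: float = 4.0

    # treatment
    prescription_dose: float = 66.0  # Gy
    fraction_dose: float = 3.0  # Gy
    falloff_mm: float = 25.0  # exponential dose falloff length scale
    falloff_sigma: float = 0.3  # lognormal per-patient spread of the falloff
    # (plan conformity varies between patients; a shallower falloff puts more
    # lung into the mid-dose range *and* increases the injury burden)

    # baseline tissue
    lung_hu_mean: float = -750.0
    lung_hu_sd: float = 40.0
    soft_tissue_hu_mean: float = 40.0
    soft_tissue_hu_sd: float = 20.0
    noise_correlation_vox: float = 2.5  # Gaussian smoothing sigma of scan noise

    # radiation injury
    injury_max_dhu: float = 300.0  # HU at full susceptibility, saturated dose
    injury_midpoint_pct: float = 55.0  # % of prescription
    injury_width_pct: float = 10.0
    recovery_factor: float = 0.8  # fraction of 3-month injury present at 6 months
    susceptibility_sigma: float = 0.4  # lognormal sd of per-patient susceptibility

    # tumor dynamics between scans (uncorrelated with function)
    tumor_mass_median_factor: float = 0.85  # median radius factor per follow-up
    tumor_mass_factor_sigma: float = 0.5  # lognormal sigma of that factor
    tumor_mass_max_factor: float = 1.15  # sub-acute growth is bounded; true
    # progression within six months is the (separately flagged) relapse case
    tumor_jitter_sd_vox: float = 1.5  # apparent position shift per follow-up scan
    # erratic remodeling (consolidation/necrosis evolution) of the high-dose
    # region: per-scan lognormal factor on the injury, weighted by a sigmoid
    # in dose so that only near-target bands are affected
    remodel_sigma: float = 0.8
    remodel_midpoint_pct: float = 80.0
    remodel_width_pct: float = 8.0
    # peritumoral atelectasis: a collapsed dense rim around the tumor at
    # baseline (thickness per patient ~ U(min, max)); at each follow-up it
    # either persists or resolves completely (the obstructed airway reopens
    # or it does not), and once resolved it stays resolved. Density near the
    # target can therefore move in either direction, unlike the mid-dose lung
    atelectasis_hu: float = -150.0
    atelectasis_min_mm: float = 2.0
    atelectasis_max_mm: float = 10.0
    atelectasis_resolve_prob: float = 0.5  # per follow-up interval

    # per-patient anatomy variation
    tumor_center_jitter_vox: float = 2.0
    tumor_radius_sigma: float = 0.15  # lognormal sigma on tumor radius

    # pulmonary function
    gamma: float = 0.3  # coupling: relative PFT loss per unit injury burden
    dlco_baseline_median: float = 5.3  # mmol/min/kPa
    fev1_baseline_median: float = 2.2  # L
    pft_baseline_sigma: float = 0.3  # lognormal sigma of baselines
    pft_noise_sd: float = 0.03  # multiplicative measurement noise (3 %)

    # cohort
    n_patients: int = 40
    relapse_rate: float = 0.08

    def __post_init__(self) -> None:
        positive = {
            "prescription_dose": self.prescription_dose,
            "fraction_dose": self.fraction_dose,
            "falloff_mm": self.falloff_mm,
            "injury_width_pct": self.injury_width_pct,
            "tumor_radius_vox": self.tumor_radius_vox,
            "dlco_baseline_median": self.dlco_baseline_median,
            "fev1_baseline_median": self.fev1_baseline_median,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0 (0 is the null scenario)")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not all(
            0 <= c < s for c, s in zip(self.tumor_center, self.grid_shape)
        ):
            raise ValueError(
                f"tumor center {self.tumor_center} outside grid {self.grid_shape}"
            )

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per-patient latent variables of a generated cohort."""

    spec: PhantomSpec
    table: pd.DataFrame  # patient_id, susceptibility, burdens, tumor anatomy
    mean_sigmoid: float  # volume-weighted mean sigmoid response over the lung


def _coord_grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    return np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")


def lung_mask(spec: PhantomSpec) -> VolumeMask:
    """Two-ellipsoid lung mask on the phantom grid."""
    gx, gy, gz = _coord_grids(spec.grid_shape)
    sel = np.zeros(spec.grid_shape, dtype=bool)
    for (cx, cy, cz), (ax, ay, az) in zip(spec.lung_centers, spec.lung_semiaxes):
        sel |= (
            ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2
        ) <= 1.0
    return VolumeMask(sel, spacing=spec.spacing)


def _distance_mm_from_sphere(
    spec: PhantomSpec,
    center_vox: Sequence[float],
    radius_vox: float,
) -> np.ndarray:
    """Physical distance (mm) of every voxel centre from a sphere surface
    (0 inside the sphere)."""
    gx, gy, gz = _coord_grids(spec.grid_shape)
    sx, sy, sz = spec.spacing
    cx, cy, cz = center_vox
    d = np.sqrt(
        ((gx - cx) * sx) ** 2 + ((gy - cy) * sy) ** 2 + ((gz - cz) * sz) ** 2
    )
    return np.maximum(0.0, d - radius_vox * sx)


def generate_dose(
    spec: PhantomSpec,
    center_vox: Optional[Sequence[float]] = None,
    radius_vox: Optional[float] = None,
) -> ScalarVolume:
    """Prescription dose inside the tumor sphere, exponential falloff outside.

    Deterministic given the spec and tumor geometry. The 50%-isodose surface
    is the sphere at distance ``falloff_mm * ln 2`` from the tumor surface,
    which gives a closed form for isodose volumes on this phantom.
    """
    center = tuple(center_vox) if center_vox is not None else spec.tumor_center
    radius = radius_vox if radius_vox is not None else spec.tumor_radius_vox
    if not all(0 <= c < s for c, s in zip(center, spec.grid_shape)):
        raise ValueError(f"tumor center {center} outside grid {spec.grid_shape}")
    dist = _distance_mm_from_sphere(spec, center, radius)
    dose = spec.prescription_dose * np.exp(-dist / spec.falloff_mm)
    return ScalarVolume(dose, spacing=spec.spacing, kind="dose")


def dose_sigmoid(spec: PhantomSpec, dose_values: np.ndarray) -> np.ndarray:
    """Dose-response sigmoid in % of prescription (the injury spatial profile)."""
    pct = 100.0 * dose_values / spec.prescription_dose
    u = (pct - spec.injury_midpoint_pct) / spec.injury_width_pct
    return 1.0 / (1.0 + np.exp(-u))


def _correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int, int], sigma_vox: float
) -> np.ndarray:
    """Unit-variance noise field with a Gaussian correlation length (texture)."""
    w = rng.standard_normal(shape)
    if sigma_vox > 0:
        w = gaussian_filter(w, sigma_vox, mode="nearest")
        w /= w.std()
    return w


def _sphere_mask(
    spec: PhantomSpec, center_vox: Sequence[float], radius_vox: float
) -> np.ndarray:
    return _distance_mm_from_sphere(spec, center_vox, radius_vox) == 0.0


def generate_ct_series(
    spec: PhantomSpec,
    dose: ScalarVolume,
    lung: VolumeMask,
    susceptibility: float,
    rng: np.random.Generator,
    tumor_center_vox: Optional[Sequence[float]] = None,
    tumor_radius_vox: Optional[float] = None,
) -> dict[str, ScalarVolume]:
    """Three CT volumes for one patient.

    Baseline: textured soft tissue with aerated lung, the dense tumor and a
    partially collapsed (atelectatic) rim around it. Follow-ups add the
    dose-sigmoid injury (scaled by the patient's susceptibility; 6-month
    injury = ``recovery_factor`` x the 3-month injury, modulated near the
    target by the erratic remodeling factor), redraw the tumor mass with a
    random radius factor and sub-voxel position jitter per scan, and carry
    the atelectatic rim forward until it (irreversibly) resolves.
    """
    center = tuple(tumor_center_vox) if tumor_center_vox is not None else spec.tumor_center
    radius = tumor_radius_vox if tumor_radius_vox is not None else spec.tumor_radius_vox
    injury_profile = spec.injury_max_dhu * susceptibility * dose_sigmoid(
        spec, dose.values
    )
    pct = 100.0 * dose.values / spec.prescription_dose
    remodel_weight = 1.0 / (
        1.0 + np.exp(-(pct - spec.remodel_midpoint_pct) / spec.remodel_width_pct)
    )
    time_factor = {"tpre": 0.0, "t3m": 1.0, "t6m": spec.recovery_factor}
    surface_dist = _distance_mm_from_sphere(spec, center, radius)
    rim_mm = float(rng.uniform(spec.atelectasis_min_mm, spec.atelectasis_max_mm))
    rim_resolved = False

    out: dict[str, ScalarVolume] = {}
    for tp in TIMEPOINTS:
        noise = _correlated_noise(rng, spec.grid_shape, spec.noise_correlation_vox)
        hu = spec.soft_tissue_hu_mean + spec.soft_tissue_hu_sd * noise
        hu[lung.values] = (
            spec.lung_hu_mean + spec.lung_hu_sd * noise[lung.values]
        )
        if tp == "tpre":
            tumor_now = _sphere_mask(spec, center, radius)
            rim_now = rim_mm
        else:
            factor = min(
                float(
                    np.exp(
                        rng.normal(
                            math.log(spec.tumor_mass_median_factor),
                            spec.tumor_mass_factor_sigma,
                        )
                    )
                ),
                spec.tumor_mass_max_factor,
            )
            jitter = rng.normal(0.0, spec.tumor_jitter_sd_vox, size=3)
            tumor_now = _sphere_mask(
                spec, np.asarray(center) + jitter, radius * factor
            )
            if rim_resolved or rng.random() < spec.atelectasis_resolve_prob:
                rim_resolved = True
            rim_now = 0.0 if rim_resolved else rim_mm
        rim_mask = lung.values & (surface_dist > 0) & (surface_dist <= rim_now)
        if tp != "tpre":
            remodel = np.exp(
                rng.normal(0.0, spec.remodel_sigma) * remodel_weight
            )
            injured = lung.values & ~tumor_now & ~rim_mask
            hu[injured] += (
                time_factor[tp] * injury_profile[injured] * remodel[injured]
            )
            # density saturates at full consolidation: injured lung cannot
            # become denser than soft tissue
            hu[injured] = np.minimum(hu[injured], spec.soft_tissue_hu_mean)
        hu[rim_mask] = (
            spec.atelectasis_hu + spec.soft_tissue_hu_sd * noise[rim_mask]
        )
        hu[tumor_now] = spec.soft_tissue_hu_mean + spec.soft_tissue_hu_sd * noise[tumor_now]
        out[tp] = ScalarVolume(hu, spacing=spec.spacing, kind="ct")
    return out


def injury_burden(
    spec: PhantomSpec,
    dose: ScalarVolume,
    lung: VolumeMask,
    susceptibility: float,
) -> dict[str, float]:
    """Volume-weighted mean sigmoid response over the lung, per time point."""
    mean_sig = float(dose_sigmoid(spec, dose.values)[lung.values].mean())
    return {
        "tpre": 0.0,
        "t3m": susceptibility * mean_sig,
        "t6m": spec.recovery_factor * susceptibility * mean_sig,
    }


def generate_pft(
    spec: PhantomSpec,
    patient_id: str,
    burden: dict[str, float],
    rng: np.random.Generator,
    max_retries: int = 100,
) -> dict[str, PFTRecord]:
    """PFT records: baseline x (1 - gamma * burden) x (1 + noise), per parameter.

    DLCO and FEV1 share the mechanism but have independent baselines and
    noise. Non-positive draws are resampled (bounded retries).
    """
    baselines = {
        "dlco": spec.dlco_baseline_median
        * float(np.exp(rng.normal(0.0, spec.pft_baseline_sigma))),
        "fev1": spec.fev1_baseline_median
        * float(np.exp(rng.normal(0.0, spec.pft_baseline_sigma))),
    }
    records: dict[str, PFTRecord] = {}
    for tp in TIMEPOINTS:
        values = {}
        for name, base in baselines.items():
            mean = base * (1.0 - spec.gamma * burden[tp])
            for _ in range(max_retries):
                v = mean * (1.0 + rng.normal(0.0, spec.pft_noise_sd))
                if v > 0:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a positive {name} for {patient_id} at {tp}"
                )
            values[name] = v
        records[tp] = PFTRecord(
            patient_id=patient_id, timepoint=tp,
            dlco=values["dlco"], fev1=values["fev1"],
        )
    return records


def generate_patient(
    spec: PhantomSpec,
    patient_id: str,
    rng: np.random.Generator,
) -> tuple[PatientSeries, dict]:
    """One phantom patient plus its ground-truth row.

    Patient-level anatomy/plan variation: tumor position and radius jitter
    plus a lognormal factor on the dose falloff length scale. The burden (and
    therefore the planted PFT decline) is computed from the patient's own
    dose grid, so patients whose plans spill more dose into the lung both
    carry larger mid-dose volumes and lose more function.
    """
    lung = lung_mask(spec)
    center = np.asarray(spec.tumor_center, dtype=float) + rng.normal(
        0.0, spec.tumor_center_jitter_vox, size=3
    )
    center = np.clip(center, 0, np.asarray(spec.grid_shape) - 1)
    radius = spec.tumor_radius_vox * float(
        np.exp(rng.normal(0.0, spec.tumor_radius_sigma))
    )
    pspec = spec.with_(
        falloff_mm=spec.falloff_mm
        * float(np.exp(rng.normal(0.0, spec.falloff_sigma)))
    )
    susceptibility = float(np.exp(rng.normal(0.0, spec.susceptibility_sigma)))
    dose = generate_dose(pspec, center, radius)
    ct = generate_ct_series(
        pspec, dose, lung, susceptibility, rng,
        tumor_center_vox=center, tumor_radius_vox=radius,
    )
    burden = injury_burden(pspec, dose, lung, susceptibility)
    pft = generate_pft(spec, patient_id, burden, rng)
    ptv = VolumeMask(_sphere_mask(spec, center, radius * 1.25), spacing=spec.spacing)
    relapse = bool(rng.random() < spec.relapse_rate)
    patient = PatientSeries(
        patient_id=patient_id,
        dose=dose,
        lung=lung,
        ptv=ptv,
        ct=ct,
        pft=pft,
        prescription_dose=spec.prescription_dose,
        fraction_dose=spec.fraction_dose,
        relapse_flag=relapse,
    )
    truth = {
        "patient_id": patient_id,
        "susceptibility": susceptibility,
        "falloff_mm": pspec.falloff_mm,
        "tumor_radius_vox": radius,
        "tumor_center_x": center[0],
        "tumor_center_y": center[1],
        "tumor_center_z": center[2],
        "burden_t3m": burden["t3m"],
        "burden_t6m": burden["t6m"],
        "relapse": relapse,
    }
    return patient, truth


def generate_cohort(
    spec: PhantomSpec, seed: int
) -> tuple[list[PatientSeries], GroundTruth]:
    """A full phantom cohort, bit-reproducible from ``seed``.

    Per-patient RNG substreams are spawned from one ``SeedSequence`` so the
    cohort is identical whether patients are generated serially or not.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(spec.n_patients, 1))
    cohort: list[PatientSeries] = []
    rows: list[dict] = []
    for i in range(spec.n_patients):
        rng = np.random.default_rng(children[i])
        patient, truth = generate_patient(spec, f"P{i + 1:03d}", rng)
        cohort.append(patient)
        rows.append(truth)
    columns = [
        "patient_id", "susceptibility", "falloff_mm", "tumor_radius_vox",
        "tumor_center_x", "tumor_center_y", "tumor_center_z",
        "burden_t3m", "burden_t6m", "relapse",
    ]
    table = pd.DataFrame(rows, columns=columns)
    base_dose = generate_dose(spec)
    mean_sig = float(
        dose_sigmoid(spec, base_dose.values)[lung_mask(spec).values].mean()
    )
    return cohort, GroundTruth(spec=spec, table=table, mean_sigmoid=mean_sig)
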