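"""Core domain types shared by every analysis stage.

All volumes of one patient live on a single shared voxel grid (the planning
frame): the planning dose grid, the lung mask, and the three follow-up CT
series are assumed to be co-registered by upstream tooling. This package
therefore never resamples; it only *verifies* frame compatibility (shape,
voxel spacing and origin agreement within a small tolerance) and refuses
mixed frames.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

#: Canonical time point labels: baseline (pre-RT), three and six months post-RT.
TIMEPOINTS: tuple[str, str, str] = ("tpre", "t3m", "t6m")

#: Sentinel for "no upper isodose cut" (the physical maximum dose).
DMAX: float = math.inf

#: Default frame tolerance for spacing/origin agreement, in mm.
FRAME_TOL_MM: float = 1e-3


class FrameMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ScalarVolume:
    """A 3D scalar field (dose in Gy or CT in HU) on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values. Must be finite.
    spacing : (3,) float
        Voxel edge lengths in mm, all positive.
    origin : (3,) float
        Physical position of the first voxel, mm.
    kind : {"dose", "ct"}
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "ct"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.kind not in ("dose", "ct"):
            raise ValueError(f"kind must be 'dose' or 'ct', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VolumeMask:
    """A boolean field selecting a subvolume on the shared grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.values.ndim}D")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def frames_compatible(a, b, tol_mm: float = FRAME_TOL_MM) -> bool:
    """True iff two volumes/masks share shape, spacing and origin (within tol)."""
    return (
        a.shape == b.shape
        and all(abs(x - y) <= tol_mm for x, y in zip(a.spacing, b.spacing))
        and all(abs(x - y) <= tol_mm for x, y in zip(a.origin, b.origin))
    )


def require_same_frame(a, b, what: str = "volumes", tol_mm: float = FRAME_TOL_MM) -> None:
    if not frames_compatible(a, b, tol_mm):
        raise FrameMismatchError(
            f"{what} are not frame-compatible: "
            f"shape {a.shape} vs {b.shape}, spacing {a.spacing} vs {b.spacing}, "
            f"origin {a.origin} vs {b.origin}"
        )


@dataclass(frozen=True)
class VolumeRange:
    """A dose interval [low, high) in % of the prescription dose.

    ``high`` may be the sentinel :data:`DMAX`, meaning no upper cut
    (``VDmax-5%`` style ranges). The lower bound is inclusive, the upper
    bound exclusive, so that consecutive ranges tile the dose axis exactly.
    """

    high: float
    low: float

    def __post_init__(self) -> None:
        if self.low < 0:
            raise ValueError(f"low isodose level must be >= 0, got {self.low}")
        if not math.isinf(self.high) and self.high <= self.low:
            raise ValueError(f"need high > low, got {self.high} <= {self.low}")

    @property
    def is_open_top(self) -> bool:
        return math.isinf(self.high)

    @property
    def label(self) -> str:
        hi = "Dmax" if self.is_open_top else f"{self.high:g}"
        return f"V{hi}-{self.low:g}%"

    @classmethod
    def parse(cls, text: str) -> "VolumeRange":
        """Parse labels like ``V65-45%`` or ``VDmax-5%``."""
        m = re.fullmatch(r"V(Dmax|[\d.]+)-([\d.]+)%?", text.strip(), re.IGNORECASE)
        if not m:
            raise ValueError(f"cannot parse volume range {text!r}")
        hi = DMAX if m.group(1).lower() == "dmax" else float(m.group(1))
        return cls(high=hi, low=float(m.group(2)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class PFTRecord:
    """One pulmonary function measurement at one time point.

    dlco is the CO diffusing capacity in mmol/min/kPa, fev1 the forced
    expiratory volume in 1 s in litres; either may be missing (None).
    """

    patient_id: str
    timepoint: str
    dlco: Optional[float] = None
    fev1: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"invalid timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        for name in ("dlco", "fev1"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not math.isfinite(v) or v <= 0:
                    raise ValueError(
                        f"{name} must be positive when present, got {v} "
                        f"(patient {self.patient_id}, {self.timepoint})"
                    )
                setattr(self, name, v)

    def value(self, parameter: str) -> Optional[float]:
        if parameter not in ("dlco", "fev1"):
            raise ValueError(f"unknown PFT parameter {parameter!r}")
        return getattr(self, parameter)


@dataclass
class PatientSeries:
    """Everything the analysis needs for one patient, on one shared frame."""

    patient_id: str
    dose: ScalarVolume
    lung: VolumeMask
    ct: Mapping[str, ScalarVolume]
    pft: Mapping[str, PFTRecord]
    prescription_dose: float
    fraction_dose: float
    relapse_flag: bool = False
    ptv: Optional[VolumeMask] = None

    def __post_init__(self) -> None:
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")
        if self.fraction_dose <= 0:
            raise ValueError("fraction_dose must be > 0")
        for tp in self.ct:
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown CT timepoint {tp!r}")
        for tp, rec in self.pft.items():
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown PFT timepoint {tp!r}")
            if rec.timepoint != tp:
                raise ValueError(
                    f"PFT record timepoint {rec.timepoint!r} filed under {tp!r}"
                )
        require_same_frame(self.dose, self.lung, f"dose/lung of {self.patient_id}")
        if self.ptv is not None:
            require_same_frame(self.dose, self.ptv, f"dose/ptv of {self.patient_id}")
        for tp, vol in self.ct.items():
            require_same_frame(self.dose, vol, f"dose/ct[{tp}] of {self.patient_id}")

    @property
    def timepoints_with_ct(self) -> tuple[str, ...]:
        return tuple(tp for tp in TIMEPOINTS if tp in self.ct)

    def has_complete_series(self, parameter: str = "dlco") -> bool:
        """True iff CT and the given PFT parameter exist at all three time points."""
        return all(
            tp in self.ct and tp in self.pft and self.pft[tp].value(parameter) is not None
            for tp in TIMEPOINTS
        )


@dataclass
class DensitySample:
    """Relative density number for one (patient, range, time point) triple."""

    patient_id: str
    range: VolumeRange
    timepoint: str
    mean_hu_volume: float
    mean_hu_lung: float
    n_rho: float


@dataclass(frozen=True)
class FractionationScheme:
    """A radiotherapy fractionation: total dose D, dose/fraction d, tissue α/β (all Gy)."""

    total_dose: float
    dose_per_fraction: float
    alpha_beta: float = 10.0

    def __post_init__(self) -> None:
        if self.total_dose <= 0 or self.dose_per_fraction <= 0 or self.alpha_beta <= 0:
            raise ValueError(
                "total_dose, dose_per_fraction and alpha_beta must all be positive"
            )

    @property
    def n_fractions(self) -> float:
        return self.total_dose / self.dose_per_fraction
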