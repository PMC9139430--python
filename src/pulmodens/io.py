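"""Reading and writing volumes (NIfTI), PFT tables (CSV) and cohort configs (YAML).

The cohort config is a YAML mapping with per-patient file paths and treatment
metadata; :func:`assemble_cohort` loads it, enforces frame compatibility and
returns the usable patients together with an explicit exclusion report —
patients failing checks are reported, never silently dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    TIMEPOINTS,
    FrameMismatchError,
    PatientSeries,
    PFTRecord,
    ScalarVolume,
    VolumeMask,
    frames_compatible,
)

PathLike = Union[str, os.PathLike]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Union[ScalarVolume, VolumeMask], path: PathLike) -> None:
    """Write a volume or mask as NIfTI; masks are stored as uint8 {0, 1}."""
    if isinstance(volume, VolumeMask):
        data = volume.values.astype(np.uint8)
    else:
        data = volume.values
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: PathLike, kind: str = "ct") -> Union[ScalarVolume, VolumeMask]:
    """Read a NIfTI volume.

    kind ``"dose"`` / ``"ct"`` return a :class:`ScalarVolume`; ``"mask"``
    thresholds the stored values at > 0.5 and returns a :class:`VolumeMask`.
    Spacing and origin are taken from the image header/affine.
    """
    if kind not in ("dose", "ct", "mask"):
        raise ValueError(f"kind must be dose, ct or mask, got {kind!r}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if kind == "mask":
        return VolumeMask(data > 0.5, spacing=spacing, origin=origin)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite voxels")
    return ScalarVolume(data, spacing=spacing, origin=origin, kind=kind)


def read_pft_table(path: PathLike) -> list[PFTRecord]:
    """Read a PFT CSV with columns patient_id, timepoint, dlco, fev1.

    Empty cells mean the measurement is missing. Invalid rows raise with the
    1-based data row number so the offending line can be found.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "timepoint", "dlco", "fev1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PFT table {path} lacks columns: {sorted(missing)}")
    records: list[PFTRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                PFTRecord(
                    patient_id=str(row.patient_id),
                    timepoint=str(row.timepoint).strip(),
                    dlco=None if pd.isna(row.dlco) else float(row.dlco),
                    fev1=None if pd.isna(row.fev1) else float(row.fev1),
                )
            )
        except ValueError as exc:
            raise ValueError(f"PFT table {path}, row {i}: {exc}") from exc
    return records


def write_pft_table(records: Iterable[PFTRecord], path: PathLike) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "timepoint": r.timepoint,
            "dlco": r.dlco,
            "fev1": r.fev1,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient_id", "timepoint", "dlco", "fev1"]).to_csv(
        path, index=False
    )


def pft_dataframe(cohort: Sequence[PatientSeries]) -> pd.DataFrame:
    """Long-format PFT table for a cohort: patient_id, timepoint, dlco, fev1."""
    rows = []
    for p in cohort:
        for tp in TIMEPOINTS:
            rec = p.pft.get(tp)
            if rec is not None:
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "timepoint": tp,
                        "dlco": rec.dlco,
                        "fev1": rec.fev1,
                    }
                )
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "dlco", "fev1"])


@dataclass
class ExclusionReport:
    patient_id: str
    reason: str


def _load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"cohort config {path} must be a mapping")
    return cfg


def assemble_cohort(
    config: Union[PathLike, dict],
    base_dir: Optional[PathLike] = None,
) -> tuple[list[PatientSeries], list[ExclusionReport]]:
    """Build a cohort from a YAML config (or equivalent dict).

    Config layout::

        pft_table: pft.csv
        patients:
          P001:
            dose: P001/dose.nii.gz
            lung: P001/lung.nii.gz
            ptv:  P001/ptv.nii.gz        # optional
            ct: {tpre: ..., t3m: ..., t6m: ...}
            prescription_dose: 66.0
            fraction_dose: 3.0
            relapse: false

    Relative paths resolve against ``base_dir`` (default: the config file's
    directory). Patients whose volumes are unreadable or frame-incompatible
    are excluded with a per-patient reason, not silently dropped.
    """
    if isinstance(config, (str, os.PathLike)):
        cfg_path = Path(config)
        cfg = _load_yaml(cfg_path)
        root = Path(base_dir) if base_dir is not None else cfg_path.parent
    else:
        cfg = config
        root = Path(base_dir) if base_dir is not None else Path(".")

    pft_records = read_pft_table(root / cfg["pft_table"]) if "pft_table" in cfg else []
    pft_by_patient: dict[str, dict[str, PFTRecord]] = {}
    for rec in pft_records:
        pft_by_patient.setdefault(rec.patient_id, {})[rec.timepoint] = rec

    cohort: list[PatientSeries] = []
    excluded: list[ExclusionReport] = []
    for pid, entry in cfg.get("patients", {}).items():
        pid = str(pid)
        try:
            dose = read_volume(root / entry["dose"], kind="dose")
            lung = read_volume(root / entry["lung"], kind="mask")
            ptv = (
                read_volume(root / entry["ptv"], kind="mask")
                if entry.get("ptv")
                else None
            )
            ct = {
                tp: read_volume(root / p, kind="ct")
                for tp, p in entry.get("ct", {}).items()
            }
            for tp, vol in ct.items():
                if not frames_compatible(dose, vol):
                    raise FrameMismatchError(
                        f"dose and ct[{tp}] disagree in shape/spacing/origin"
                    )
            patient = PatientSeries(
                patient_id=pid,
                dose=dose,
                lung=lung,
                ptv=ptv,
                ct=ct,
                pft=pft_by_patient.get(pid, {}),
                prescription_dose=float(entry["prescription_dose"]),
                fraction_dose=float(entry["fraction_dose"]),
                relapse_flag=bool(entry.get("relapse", False)),
            )
        except (OSError, ValueError, KeyError, FrameMismatchError) as exc:
            excluded.append(ExclusionReport(patient_id=pid, reason=str(exc)))
            continue
        cohort.append(patient)
    return cohort, excluded


def exclude_relapse(cohort: Sequence[PatientSeries]) -> list[PatientSeries]:
    """Sensitivity-analysis filter: drop patients flagged with pulmonary relapse."""
    return [p for p in cohort if not p.relapse_flag]
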