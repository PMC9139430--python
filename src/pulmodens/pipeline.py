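"""One-shot orchestration: cohort -> subvolumes -> densities -> statistics.

``run_full_analysis`` produces six CSV tables plus a JSON manifest in the
output directory. Every table starts with a provenance comment line carrying
the package version, the seed and a hash of the configuration, so any result
can be traced to the run that produced it; identical configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .density import density_table
from .dose_volumes import prediction_ranges, triangle_ranges, volume_table
from .io import assemble_cohort, exclude_relapse, pft_dataframe
from .longitudinal import (
    change_tests,
    correlation_triangle,
    patient_correlations,
    volume_size_prediction,
)
from .phantom import PhantomSpec, generate_cohort
from .types import PatientSeries, VolumeRange

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``simulate`` (a PhantomSpec) or ``cohort_config`` (path to
    a YAML cohort description) must be given.
    """

    out_dir: Union[str, Path]
    seed: int = 0
    simulate: Optional[PhantomSpec] = None
    cohort_config: Optional[Union[str, Path]] = None
    pft_parameters: tuple[str, ...] = ("dlco", "fev1")
    focus_range: VolumeRange = field(
        default_factory=lambda: VolumeRange(high=65.0, low=45.0)
    )
    prediction_timepoint: str = "t3m"
    family_size: Optional[int] = None
    exclude_relapse: bool = False
    exclude_ptv: bool = False

    def config_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["cohort_config"] = (
            str(self.cohort_config) if self.cohort_config is not None else None
        )
        d["focus_range"] = self.focus_range.label
        return d

    def config_hash(self) -> str:
        """Hash of the result-affecting configuration (the output location is
        excluded: the same analysis written elsewhere is the same analysis)."""
        d = self.config_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance)
        df.to_csv(fh, index=False)


def _load_cohort(config: RunConfig) -> tuple[list[PatientSeries], list]:
    if (config.simulate is None) == (config.cohort_config is None):
        raise ValueError("give exactly one of simulate= or cohort_config=")
    if config.simulate is not None:
        cohort, _truth = generate_cohort(config.simulate, config.seed)
        return cohort, []
    cohort, excluded = assemble_cohort(config.cohort_config)
    for e in excluded:
        logger.warning("excluded patient %s: %s", e.patient_id, e.reason)
    return cohort, excluded


def run_full_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every analysis stage and write the report bundle.

    Tables written: volumes.csv, density.csv, patient_correlations.csv,
    triangle.csv, changes.csv, prediction.csv + manifest.json. Returns the
    tables as DataFrames keyed by file stem.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = (
        f"# pulmodens={__version__} seed={config.seed} "
        f"config_hash={config.config_hash()}\n"
    )

    cohort, excluded = _load_cohort(config)
    n_total = len(cohort)
    if config.exclude_relapse:
        cohort = exclude_relapse(cohort)
        logger.info(
            "relapse exclusion: %d of %d patients retained", len(cohort), n_total
        )
    if not cohort:
        raise ValueError("cohort is empty after loading/filtering")

    tri_ranges = triangle_ranges()
    pred_ranges = prediction_ranges()
    all_ranges = list(dict.fromkeys([*tri_ranges, *pred_ranges, config.focus_range]))

    logger.info("measuring subvolumes for %d patients", len(cohort))
    volumes = volume_table(cohort, all_ranges, exclude_ptv=config.exclude_ptv)
    logger.info("computing density time series")
    density = density_table(cohort, all_ranges, exclude_ptv=config.exclude_ptv)
    pft = pft_dataframe(cohort)

    corr_frames, tri_frames, pred_frames = [], [], []
    for parameter in config.pft_parameters:
        corr_frames.append(
            patient_correlations(density, pft, config.focus_range, parameter)
        )
        tri_frames.append(
            correlation_triangle(
                density, pft, parameter,
                pairs=tri_ranges, family_size=config.family_size,
            )
        )
        pred_frames.append(
            volume_size_prediction(
                volumes, pft, pred_ranges, parameter,
                timepoint=config.prediction_timepoint,
                family_size=config.family_size,
            )
        )
    correlations = pd.concat(corr_frames, ignore_index=True)
    triangle = pd.concat(tri_frames, ignore_index=True)
    prediction = pd.concat(pred_frames, ignore_index=True)
    changes = change_tests(
        density, pft,
        quantities=[*config.pft_parameters, config.focus_range.label],
    )

    tables = {
        "volumes": volumes,
        "density": density,
        "patient_correlations": correlations,
        "triangle": triangle,
        "changes": changes,
        "prediction": prediction,
    }
    for stem, df in tables.items():
        _write_csv(df, out / f"{stem}.csv", provenance)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.config_dict(),
        "n_patients_loaded": n_total,
        "n_patients_analyzed": len(cohort),
        "excluded": [
            {"patient_id": e.patient_id, "reason": e.reason} for e in excluded
        ],
        "tables": sorted(tables),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("report bundle written to %s", out)
    return tables
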