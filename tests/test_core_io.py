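import numpy as np
import pytest
import yaml

from pulmodens.io import (
    assemble_cohort,
    exclude_relapse,
    read_pft_table,
    read_volume,
    write_pft_table,
    write_volume,
)
from pulmodens.phantom import PhantomSpec, generate_dose
from pulmodens.types import (
    DMAX,
    FrameMismatchError,
    PatientSeries,
    PFTRecord,
    ScalarVolume,
    VolumeMask,
    VolumeRange,
    frames_compatible,
)


class TestVolumeRoundTrip:
    def test_write_read_identity(self, tmp_path, rng):
        vol = ScalarVolume(
            rng.normal(size=(4, 4, 4)),
            spacing=(1.5, 2.0, 3.0),
            origin=(-10.0, 5.0, 0.0),
            kind="dose",
        )
        write_volume(vol, tmp_path / "d.nii.gz")
        back = read_volume(tmp_path / "d.nii.gz", kind="dose")
        np.testing.assert_array_equal(back.values, vol.values)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.origin == pytest.approx(vol.origin)

    def test_mask_round_trip_thresholds(self, tmp_path, rng):
        mask = VolumeMask(rng.random((5, 5, 5)) > 0.5, spacing=(2, 2, 2))
        write_volume(mask, tmp_path / "m.nii.gz")
        back = read_volume(tmp_path / "m.nii.gz", kind="mask")
        np.testing.assert_array_equal(back.values, mask.values)

    def test_2d_image_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), str(tmp_path / "f.nii"))
        with pytest.raises(ValueError, match="expected 3D"):
            read_volume(tmp_path / "f.nii")

    def test_phantom_dose_round_trip_preserves_peak(self, tmp_path):
        spec = PhantomSpec()
        dose = generate_dose(spec)
        write_volume(dose, tmp_path / "dose.nii.gz")
        back = read_volume(tmp_path / "dose.nii.gz", kind="dose")
        assert back.values.max() == pytest.approx(spec.prescription_dose)
        np.testing.assert_array_equal(back.values, dose.values)


class TestDomainTypes:
    def test_scalar_volume_rejects_nonfinite_and_bad_spacing(self):
        with pytest.raises(ValueError):
            ScalarVolume(np.full((2, 2, 2), np.nan))
        with pytest.raises(ValueError):
            ScalarVolume(np.zeros((2, 2, 2)), spacing=(0, 1, 1))

    def test_frame_compatibility_tolerance(self):
        a = ScalarVolume(np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        b = ScalarVolume(np.zeros((3, 3, 3)), spacing=(1, 1, 1 + 5e-4))
        c = ScalarVolume(np.zeros((3, 3, 3)), spacing=(1, 1, 1.01))
        assert frames_compatible(a, b)
        assert not frames_compatible(a, c)

    def test_volume_range_labels_and_parsing(self):
        assert VolumeRange(65, 45).label == "V65-45%"
        assert VolumeRange(DMAX, 5).label == "VDmax-5%"
        assert VolumeRange.parse("V65-45%") == VolumeRange(65, 45)
        assert VolumeRange.parse("VDmax-5%").is_open_top
        with pytest.raises(ValueError):
            VolumeRange(45, 65)
        with pytest.raises(ValueError):
            VolumeRange(50, -1)

    def test_pft_record_validation(self):
        with pytest.raises(ValueError):
            PFTRecord("P1", "t9m", dlco=5.0)
        with pytest.raises(ValueError):
            PFTRecord("P1", "tpre", dlco=-1.0)
        rec = PFTRecord("P1", "tpre", dlco=5.3, fev1=2.2)
        assert rec.value("dlco") == 5.3
        assert rec.value("fev1") == 2.2


class TestPFTTable:
    def test_read_valid_rows(self, tmp_path):
        path = tmp_path / "pft.csv"
        path.write_text(
            "patient_id,timepoint,dlco,fev1\n"
            "P1,tpre,5.3,2.2\nP1,t3m,5.0,2.1\nP1,t6m,5.1,2.0\n"
            "P2,tpre,4.0,1.8\nP2,t3m,,1.7\nP2,t6m,3.9,\n"
        )
        records = read_pft_table(path)
        assert len(records) == 6
        assert records[0].dlco == 5.3 and records[0].fev1 == 2.2
        assert records[4].dlco is None  # empty cell means missing
        assert len({r.patient_id for r in records}) == 2

    def test_invalid_timepoint_reports_row(self, tmp_path):
        path = tmp_path / "pft.csv"
        path.write_text("patient_id,timepoint,dlco,fev1\nP1,t9m,5.0,2.0\n")
        with pytest.raises(ValueError, match="row 1"):
            read_pft_table(path)

    def test_round_trip(self, tmp_path):
        records = [PFTRecord("P1", tp, dlco=5.0, fev1=2.0) for tp in ("tpre", "t3m")]
        write_pft_table(records, tmp_path / "out.csv")
        back = read_pft_table(tmp_path / "out.csv")
        assert [(r.patient_id, r.timepoint, r.dlco) for r in back] == [
            ("P1", "tpre", 5.0),
            ("P1", "t3m", 5.0),
        ]


def _write_patient(tmp_path, pid, spacing=(3.0, 3.0, 3.0)):
    rng = np.random.default_rng(hash(pid) % 2**31)
    shape = (8, 8, 8)
    pdir = tmp_path / pid
    pdir.mkdir(exist_ok=True)
    write_volume(
        ScalarVolume(rng.random(shape) * 66, spacing=spacing, kind="dose"),
        pdir / "dose.nii.gz",
    )
    write_volume(
        VolumeMask(np.ones(shape, bool), spacing=spacing), pdir / "lung.nii.gz"
    )
    ct_paths = {}
    for tp in ("tpre", "t3m", "t6m"):
        write_volume(
            ScalarVolume(rng.normal(-750, 40, shape), spacing=spacing),
            pdir / f"ct_{tp}.nii.gz",
        )
        ct_paths[tp] = f"{pid}/ct_{tp}.nii.gz"
    return {
        "dose": f"{pid}/dose.nii.gz",
        "lung": f"{pid}/lung.nii.gz",
        "ct": ct_paths,
        "prescription_dose": 66.0,
        "fraction_dose": 3.0,
    }


class TestAssembleCohort:
    def _config(self, tmp_path, entries):
        rows = "patient_id,timepoint,dlco,fev1\n" + "".join(
            f"{pid},{tp},5.0,2.0\n"
            for pid in entries
            for tp in ("tpre", "t3m", "t6m")
        )
        (tmp_path / "pft.csv").write_text(rows)
        cfg = {"pft_table": "pft.csv", "patients": entries}
        with open(tmp_path / "cohort.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        return tmp_path / "cohort.yaml"

    def test_happy_path_two_patients(self, tmp_path):
        entries = {pid: _write_patient(tmp_path, pid) for pid in ("P1", "P2")}
        cohort, excluded = assemble_cohort(self._config(tmp_path, entries))
        assert len(cohort) == 2 and not excluded
        assert all(len(p.pft) == 3 for p in cohort)

    def test_frame_mismatch_is_reported_not_silent(self, tmp_path):
        entries = {"P1": _write_patient(tmp_path, "P1")}
        bad = _write_patient(tmp_path, "P2", spacing=(2.0, 2.0, 2.0))
        bad["dose"] = entries["P1"]["dose"]  # dose on a different grid spacing
        entries["P2"] = bad
        cohort, excluded = assemble_cohort(self._config(tmp_path, entries))
        assert [p.patient_id for p in cohort] == ["P1"]
        assert excluded[0].patient_id == "P2"

    def test_relapse_filter_arithmetic(self, small_cohort):
        cohort, _ = small_cohort
        kept = exclude_relapse(cohort)
        flagged = sum(p.relapse_flag for p in cohort)
        assert len(kept) + flagged == len(cohort)
        assert not any(p.relapse_flag for p in kept)


def test_patient_series_rejects_mixed_frames(small_cohort):
    cohort, _ = small_cohort
    p = cohort[0]
    wrong = ScalarVolume(
        np.zeros((8, 8, 8)), spacing=p.dose.spacing, kind="ct"
    )
    with pytest.raises(FrameMismatchError):
        PatientSeries(
            patient_id="bad",
            dose=p.dose,
            lung=p.lung,
            ct={"tpre": wrong},
            pft={},
            prescription_dose=66,
            fraction_dose=3,
        )
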