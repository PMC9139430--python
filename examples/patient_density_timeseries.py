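"""Relative density number n_rho over time for one phantom patient.

Shows the core quantity of the analysis: the mean HU of the mid-dose
subvolume V65-45%, normalized by the whole-lung mean of the same scan, at
baseline and three/six months after radiotherapy, next to the patient's
DLCO.
"""

from pulmodens import VolumeRange, density_timeseries
from pulmodens.phantom import PhantomSpec, generate_cohort

cohort, truth = generate_cohort(PhantomSpec(n_patients=1), seed=3)
patient = cohort[0]
samples = {
    s.timepoint: s for s in density_timeseries(patient, [VolumeRange(65, 45)])
}

print(f"patient {patient.patient_id} "
      f"(susceptibility {truth.table['susceptibility'][0]:.2f})")
print(f"{'time':>6} {'mean HU V65-45%':>16} {'mean HU lung':>13} "
      f"{'n_rho':>7} {'DLCO':>6}")
for tp in ("tpre", "t3m", "t6m"):
    s = samples[tp]
    print(f"{tp:>6} {s.mean_hu_volume:16.1f} {s.mean_hu_lung:13.1f} "
          f"{s.n_rho:7.3f} {patient.pft[tp].dlco:6.2f}")

print(
    "\nAfter RT the mid-dose subvolume densifies (mean HU rises), so n_rho"
    "\ndrops at t3m and partially recovers at t6m, mirroring the DLCO dip."
)
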