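# pulmodens

Dose-resolved CT lung density dynamics and their correlation with pulmonary
function after thoracic radiotherapy.

## The problem

After high-dose thoracic radiotherapy for lung cancer, lung tissue inside
the irradiated volume densifies on CT (inflammation, then fibrosis), and
pulmonary function — DLCO (gas exchange) and FEV1 (airflow) — may decline.
Not every part of the dose distribution is equally informative: inside and
near the target, tumor regression, consolidation and atelectasis change the
image for reasons unrelated to lung function. `pulmodens` implements the
analysis that localizes *which dose window* carries the functional signal:

1. cut the lung into isodose subvolumes — total volumes Vx% (lung receiving
   ≥ x% of the prescription) and differential volumes V(a−b)% (between b and
   a%) over the ladder 105% … 5%;
2. per subvolume, patient and time point (baseline, 3 and 6 months post-RT),
   compute the relative density number

   n_ρ = H̄U_subvolume / H̄U_whole lung,

   which normalizes out scan-level density shifts and *decreases* when the
   subvolume densifies;
3. per patient, correlate n_ρ(t) with PFT(t) over the three time points
   (Pearson r), Fisher-transform (z = atanh r), and test the cohort's mean z
   against zero with a one-sided t-test (null: no or negative correlation),
   Bonferroni-corrected over the family of subvolumes — producing a
   "correlation triangle" over (higher, lower) isodose pairs;
4. test the relative temporal change of n_ρ and PFTs against baseline; and
5. ask whether the *relative size* of a dose subvolume (% of lung) predicts
   the relative DLCO change across patients.

Dose-unit helpers convert fractionation schemes to EQD2
(D·(d + α/β)/(2 + α/β)) and isodose percentages to Gy — e.g. the 65–45%
window of a 66 Gy prescription is 42.9–29.7 Gy.

Because no clinical images are distributed, the package ships a phantom
thorax-cohort generator (`pulmodens.phantom`) with a dose-sigmoid injury
model coupled to PFT decline and known ground truth, used by the test-suite
to validate every stage (see `docs/methods.md`).

Intended users: medical-physics / radiation-oncology researchers analyzing
longitudinal CT + PFT follow-up, and anyone needing a reproducible reference
implementation of the subvolume-density methodology.

## Worked example

```python
from pulmodens import (
    PhantomSpec, generate_cohort, density_table, triangle_ranges,
    correlation_triangle, pft_dataframe, VolumeRange, patient_correlations,
)

cohort, truth = generate_cohort(PhantomSpec(), seed=1)   # 40 phantom patients
density = density_table(cohort, triangle_ranges())
pft = pft_dataframe(cohort)

tri = correlation_triangle(density, pft, "dlco")
print(tri.sort_values("p_raw").head(3)[["range", "n_patients", "mean_z", "p_raw", "tier"]])

pc = patient_correlations(density, pft, VolumeRange(65, 45), "dlco")
print("patients with positive z:", (pc["z"] > 0).mean())
```

prints (seed 1):

```
      range  n_patients    mean_z         p_raw  tier
35  V65-45%          40  1.563167  8.503903e-10  high
30  V75-35%          40  1.622360  1.040133e-09  high
34  V65-55%          40  1.711113  2.346505e-09  high
patients with positive z: 0.85
```

The most significant triangle cells sit in the mid-dose range (the phantom
plants its injury sigmoid at 55% of the prescription), and 85% of patients
show a positive density–DLCO correlation: a decline in DLCO is mirrored by
a drop in n_ρ of the mid-dose subvolume.

The same run from a shell:

```bash
pulmodens run-all out/ --n-patients 40 --seed 1
pulmodens convert --total-dose 66 --fraction-dose 3 --isodose 65 --prescription 66
```

`run-all` writes six CSV tables (volumes, density, patient correlations,
triangle, changes, prediction) plus a manifest; every table carries the seed
and a config hash, and reruns are byte-identical. See `examples/` for short
narrative scripts, one per capability.

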