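"""Full cohort analysis on a simulated 40-patient cohort.

Runs the statistical chain — per-patient Fisher z, the correlation triangle
over isodose pairs, temporal-change tests and the volume-size prediction —
and prints the headline results.
"""

from pulmodens import (
    VolumeRange,
    change_tests,
    correlation_triangle,
    density_table,
    patient_correlations,
    pft_dataframe,
    prediction_ranges,
    triangle_ranges,
    volume_size_prediction,
    volume_table,
)
from pulmodens.phantom import PhantomSpec, generate_cohort

cohort, _ = generate_cohort(PhantomSpec(), seed=1)
density = density_table(cohort, triangle_ranges())
pft = pft_dataframe(cohort)

tri = correlation_triangle(density, pft, "dlco").sort_values("p_raw")
print("strongest correlation-triangle cells (density dynamics vs DLCO):")
print(tri.head(5)[["range", "mean_z", "p_raw", "p_corrected", "tier"]].to_string(index=False))

pc = patient_correlations(density, pft, VolumeRange(65, 45), "dlco")
print(f"\npatients with positive Fisher z for V65-45%: {(pc['z'] > 0).mean():.0%}")

changes = change_tests(density, pft, quantities=["dlco", "fev1", "V65-45%"])
print("\nrelative change vs baseline (paired t-tests):")
print(changes.to_string(index=False))

sizes = volume_table(cohort, prediction_ranges())
pred = volume_size_prediction(sizes, pft, prediction_ranges(), "dlco")
row = pred.set_index("range").loc["V65-45%"]
print(f"\nvolume-size prediction: r = {row['r']:.3f} "
      f"(raw p = {row['p_raw']:.3g}, corrected = {row['p_corrected']:.3g})")

print(
    "\nThe strongest cells sit in the mid-dose range; most patients couple"
    "\ndensity to DLCO; and a larger mid-dose volume share predicts a larger"
    "\nDLCO decline (negative r), matching the planted ground truth."
)
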