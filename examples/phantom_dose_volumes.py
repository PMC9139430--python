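"""Build one phantom patient and measure its isodose subvolumes.

Generates the deterministic phantom dose field (prescription inside the
tumor sphere, exponential falloff) and reports the size of each consecutive
differential subvolume of the lung, in mL and in % of the total lung.
"""

from pulmodens import measure, differential_mask, standard_differential_ranges
from pulmodens.phantom import PhantomSpec, generate_dose, lung_mask

spec = PhantomSpec()
dose = generate_dose(spec)
lung = lung_mask(spec)

print(f"lung volume: {lung.count * lung.voxel_volume_mm3 / 1000:.0f} mL")
print(f"{'range':>10} {'mL':>8} {'% lung':>8}")
for rng in standard_differential_ranges():
    mask = differential_mask(dose, lung, rng, spec.prescription_dose)
    ml, pct = measure(mask, lung)
    print(f"{rng.label:>10} {ml:8.1f} {pct:8.1f}")

print(
    "\nEach row is a dose shell around the tumor: high-dose shells are small"
    "\nand hug the target, low-dose shells cover most of the lung."
)
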