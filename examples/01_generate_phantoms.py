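"""Generate a synthetic phantom cohort and write it as per-slice HDF5 files.

Each phantom carries an irregular tumor with class-specific interior texture
and a class-specific peri-tumoral annulus, on a noisy background; patients
own several slices of one class.
"""

from tumorcbir import PhantomParams, generate_cohort, write_cohort

params = PhantomParams(n_patients=12, n_classes=3, seed=0)
cohort = generate_cohort(params)
paths = write_cohort(cohort, "scratch/example_phantoms")

sizes = [c.tumor_mask.sum() for c in cohort]
print(f"cohort: {len(cohort)} slices from {params.n_patients} patients, "
      f"classes {sorted(cohort.class_set)}")
print(f"tumor sizes: min {min(sizes)} px, max {max(sizes)} px")
print(f"wrote {len(paths)} files to scratch/example_phantoms/")
# Every slice holds image, tumorMask, label and PID; the same reader also
# ingests the public brain CE-MRI benchmark's per-slice files.
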