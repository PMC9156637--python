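"""Generate a small phantom cohort and inspect its ground truth.

Builds 3 normal and 2 emphysema chest-CT phantoms, prints each
participant's label and exact %LAA (share of lung voxels below -950 HU),
and writes the cohort to disk as NIfTI volumes with a CSV manifest.
"""

from pathlib import Path

from minipae import generate_cohort, write_cohort

cohort = generate_cohort(n_normal=3, n_emphysema=2, seed=7)
for vol, truth in cohort:
    print(
        f"{vol.participant_id}: label={truth.label:<10} "
        f"%LAA={truth.expected_laa_pct:5.2f}%  "
        f"lesion voxels={int(truth.lesion_mask.sum())}"
    )

outdir = Path("scratch/example_cohort")
manifest = write_cohort(cohort, outdir)
print(f"\nwrote {len(manifest)} volumes to {outdir}/ (see manifest.csv)")
print("Normals sit near 1% LAA (noise tail of the parenchyma distribution);")
print("emphysema phantoms exceed the 5% cutoff thanks to planted lesions.")
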