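"""Minimum intensity projection at increasing slab thickness.

Projects one phantom at every default slab setting (1 to 11 mm) and shows
two effects the projection is used for: vessels (bright, tilted) are
progressively suppressed, and low-attenuation content (%LAA measured on
the slabs) grows because a minimum can only lower voxels.
"""

from minipae import PhantomSpec, generate_phantom, percent_laa, project_minip, slab_settings
from minipae.volume_io import CTVolume

vol, truth = generate_phantom(PhantomSpec(lesion_count=3, seed=5))
print(f"source volume: %LAA = {truth.expected_laa_pct:.2f}%\n")
print(f"{'slab':>6} {'k':>3} {'mean HU at vessels':>19} {'%LAA on slabs':>14}")
for t in slab_settings(None):
    stack = project_minip(vol, t)
    vessel_hu = stack.slabs[truth.vessel_mask].mean()
    laa = percent_laa(CTVolume(stack.slabs, vol.spacing_mm), truth.lung_mask).laa_pct
    print(f"{t:4.0f}mm {stack.slab_thickness_slices:3d} {vessel_hu:19.1f} {laa:13.2f}%")
print("\nThicker slabs pull vessel voxels toward parenchyma attenuation")
print("(suppression) while %LAA rises monotonically.")
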