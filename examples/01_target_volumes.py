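"""Reconstruct analysis target volumes from a resection-cavity mask.

Builds a small spherical cavity on a 1 mm grid, takes the convex hull of its
voxel centers as the clinical target volume (CTV) and expands it by 5 mm to
get the planning target volume (PTV), then prints the voxel counts and
physical volumes of each."""

import numpy as np

from recurmap import GridSpec, LabelVolume, build_target_volumes

grid = GridSpec.isotropic(41, spacing_mm=1.0)
idx = np.indices(grid.shape).reshape(3, -1).T
center = np.array([20.0, 20.0, 20.0])
cavity = (np.linalg.norm(idx - center, axis=1) <= 8.0).reshape(grid.shape)
cavity_vol = LabelVolume.from_mask(cavity, grid, name="cavity")

targets = build_target_volumes(cavity_vol, ptv_margin_mm=5.0)

vv = grid.voxel_volume_mm3
print(f"cavity: {cavity_vol.count} voxels ({cavity_vol.count * vv / 1000:.1f} cm^3)")
print(f"CTV   : {targets.ctv.count} voxels ({targets.ctv.count * vv / 1000:.1f} cm^3)")
print(f"PTV   : {targets.ptv.count} voxels ({targets.ptv.count * vv / 1000:.1f} cm^3)")
print("The CTV equals the cavity here (a ball is convex); the PTV adds a "
      "5 mm shell of setup margin around it.")
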