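"""Generate the digital mouse phantom and inspect its anatomy.

Builds the reference subject on the default 0.5 mm grid, prints organ
volumes and the target/integral-dose regions, and shows that the
kidneys sit against the spine — the adjacency that makes marrow
irradiation planning hard.
"""

import numpy as np
from scipy import ndimage

from soctmi import PhantomConfig, generate_phantom, integral_dose_region, ptv_mask

grid, structures = generate_phantom(PhantomConfig(seed=0))
vox_ml = grid.voxel_volume_mm3 / 1000.0

print(f"grid {grid.dims} at {grid.spacing[0]} mm")
for name in structures.names:
    print(f"  {name:9s} {structures[name].sum() * vox_ml:7.3f} ml")

ptv = ptv_mask(structures, margin_mm=0.0)
region = integral_dose_region(structures)
print(f"target (skeleton + spleen): {ptv.sum() * vox_ml:.3f} ml")
print(f"integral-dose region (body minus target): {region.sum() * vox_ml:.3f} ml")

dist = ndimage.distance_transform_edt(~structures["skeleton"], sampling=grid.spacing)
print(f"closest kidney voxel to the skeleton: {dist[structures['kidneys']].min():.2f} mm")
# a sub-millimetre gap: any beam treating the lumbar spine grazes the kidneys
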