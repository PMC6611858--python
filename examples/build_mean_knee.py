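"""Build the mean parametric knee and export its surfaces.

Constructs the four articular parts (femur/patella bone and 3 mm cartilage
layers) from the 12 cohort-mean scalars, verifies the cartilage offset, and
writes STL meshes for inspection.
"""

from pathlib import Path

import pfjsim as pj
from pfjsim.io import export_mesh

knee = pj.load_case("mean")
geo = pj.build_knee(knee)

print(f"mean knee: femur width {knee.femur_width} mm, "
      f"patella radius {knee.patella_radius} mm")
print(f"patellar cartilage nodes: {geo.patellar_cartilage.n_nodes}")
print(f"femoral cartilage nodes:  {geo.femoral_cartilage.n_nodes}")

errors = geo.cartilage_offset_errors()
print("cartilage offset error (should be < 0.05 mm): "
      f"patella {errors['patella']:.4f}, femur {errors['femur']:.4f}")
# the offset error measures how far each cartilage node deviates from the
# nominal 3 mm layer thickness over the subchondral bone

out = Path("scratch/meshes")
out.mkdir(parents=True, exist_ok=True)
for name, patch in [("femur_bone", geo.femur_bone),
                    ("femoral_cartilage", geo.femoral_cartilage),
                    ("patella_bone", geo.patella_bone),
                    ("patellar_cartilage", geo.patellar_cartilage)]:
    print("wrote", export_mesh(patch, out / f"{name}.stl"))
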