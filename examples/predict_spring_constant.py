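"""Predict a post's spring constant from geometry and PDMS properties.

A 1 mm steel post with 10 mm of active length above a 5 kPa PDMS mat is far
softer than its rigid-clamp limit because the soft foundation lets the
embedded segment translate and rotate; the compliance breakdown shows which
term dominates.
"""

import warnings

from microtension import (MaterialProps, PostGeometry,
                          foundation_spring_constant, parametric_sweep,
                          rigid_clamp_spring_constant)

geom = PostGeometry()          # d = 1 mm, 20 mm long, 10 mm active
mat = MaterialProps()          # steel post, 5 kPa PDMS, ν = 0.499

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # shallow embedment relative to 1/λ
    pred = foundation_spring_constant(geom, mat)

print(f"predicted k on 5 kPa PDMS : {pred.k:8.3f} µN/µm")
for name, c in pred.components.items():
    share = 100.0 * c * pred.k
    print(f"  {name:24s} {c:10.4g} µm/µN  ({share:5.1f}% of compliance)")
print(f"rigid-clamp upper bound   : {rigid_clamp_spring_constant(geom, mat):8.1f} µN/µm")

# how k scales with the foundation stiffness (the design's main dial)
sweep = parametric_sweep(geom, mat, "pdms_stiffness", [1, 5, 25, 125, 625])
print("\nPDMS stiffness sweep (kPa → µN/µm):")
for _, row in sweep.iterrows():
    print(f"  {row.axis_value:7.0f}  {row.k_uN_per_um:8.3f}")
print("k rises monotonically with PDMS stiffness: stiffer mats clamp the "
      "post harder, so the tissue feels a more rigid boundary.")
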