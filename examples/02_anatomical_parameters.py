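"""Measure the standard anatomical indexes of a reconstructed spine.

Cobb angle and curve structure in the coronal plane; sacral slope,
lumbar lordosis and thoracic kyphosis in the sagittal plane; the signed
maximum axial rotation; pelvic incidence from the femoral heads; and a
rule-based Roussouly type.
"""

from spineload import SpineRecipe, compute_parameters, generate_hips, generate_spine

recipe = SpineRecipe(
    cobb_deg=20.0, apex_level="T9", sacral_slope_deg=42.0,
    pelvic_tilt_deg=11.0, lordosis_deg=50.0, kyphosis_deg=38.0,
)
geometry = generate_spine(recipe)
params = compute_parameters(geometry, hips=generate_hips(recipe, geometry))

print(f"curves detected: {len(params.curves)}")
for c in params.curves:
    print(f"  {c.upper_end}-{c.apex}-{c.lower_end}: Cobb {c.cobb_deg:.1f} deg, convex {c.side}")
print(f"sacral slope     SS  = {params.SS:6.1f} deg")
print(f"pelvic incidence PI  = {params.PI:6.1f} deg   (SS + pelvic tilt)")
print(f"lumbar lordosis  LL  = {params.LL:6.1f} deg   (S1 to L1)")
print(f"thoracic kyphosis TK = {params.TK:6.1f} deg   (T1 to T12)")
print(f"max axial rotation   = {params.MAR:6.1f} deg  (signed, + is right-hand about the cranial axis)")
print(f"Roussouly type       = {params.RT} (automatic rule-based approximation)")
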