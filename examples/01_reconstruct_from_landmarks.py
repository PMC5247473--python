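"""Reconstruct 3D vertebral poses from biplanar landmarks.

Builds a mildly scoliotic synthetic subject, projects it onto the two
calibrated radiographic views with 0.5 mm landmarking noise, and
reconstructs every vertebra's position, dimensions and rotations by
fitting the 9-parameter box model.
"""

import numpy as np

from spineload import SpineRecipe, generate_spine, project_landmarks, reconstruct_spine

truth = generate_spine(SpineRecipe(cobb_deg=18.0, apex_level="T9", subject_id="demo"))
landmarks = project_landmarks(truth, noise_sigma_mm=0.5, seed=42, include_pedicles=True)
geometry = reconstruct_spine(landmarks)

print(f"subject {geometry.subject_id}: {len(geometry.vertebrae)} vertebrae reconstructed")
print("level   center (x, y, z) mm        coronal/lateral/axial deg   fit RMS mm")
for v in geometry.vertebrae[6:12]:  # the apex region of the curve
    c = v.center
    a = v.angles
    print(
        f"{v.label:>5}   ({c[0]:7.1f}, {c[1]:6.1f}, {c[2]:6.1f})   "
        f"{a[0]:6.2f} / {a[1]:6.2f} / {a[2]:6.2f}       {v.residual_rms:5.2f}"
    )
err = max(
    np.linalg.norm(t.center - r.center) for t, r in zip(truth.vertebrae, geometry.vertebrae)
)
print(f"\nlargest centre error vs the generating geometry: {err:.2f} mm")
print("(coronal/axial rotations around mid-curve reflect the scoliotic construction)")
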