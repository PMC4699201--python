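"""Recover breath-hold misalignment of the long-axis planes.

Perturbs each long-axis plane by a random rigid motion (<= 5 mm / 5 deg),
then registers its contour cloud back to the short-axis cloud with
mutual-subset filtering + trimmed ICP, and compares against the known truth.
"""

import numpy as np

from lheart import PhantomSpec, slice_study, perturb, register_pair
from lheart.contours_io import project_study_to_clouds
from lheart.registration import hausdorff_distance

contours, metas = slice_study(PhantomSpec())
pc, pm, truth = perturb(contours, metas, max_shift_mm=5.0, max_rot_deg=5.0, seed=3)
clouds = project_study_to_clouds(pc, pm)
sax = clouds["sax"].points

print("view   applied motion        residual after registration   d_H full -> subsets")
for view in ("2ch", "3ch", "4ch"):
    lax = clouds[view].points
    pre = hausdorff_distance(sax, lax)
    t, diag = register_pair(sax, lax, pair=f"sax-{view}")
    residual = t.compose(truth[view])  # identity if recovery were perfect
    center = lax.mean(axis=0)
    shift_err = np.linalg.norm(residual.apply(center[None])[0] - center)
    print(f"{view}:  {truth[view].rotation_angle_deg():4.1f} deg        "
          f"{residual.rotation_angle_deg():5.2f} deg / {shift_err:4.2f} mm            "
          f"{pre:5.1f} -> {diag.hausdorff_after:5.1f} mm")
print()
print("The residual columns show how much misalignment remains at the cloud")
print("centroid; the last column shows the filtered overlap subsets ending")
print("far closer to the short-axis cloud than the raw clouds started.")
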