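"""Generate a synthetic left-heart contour study.

Builds the analytic phantom (ellipsoidal LV, ellipsoidal LA, bent-tube
aorta), slices it into a short-axis stack (8 mm spacing) plus three
long-axis views at 1.43 mm pixel spacing, and writes the study JSON.
"""

from collections import Counter

from lheart import PhantomSpec, slice_study, write_study

spec = PhantomSpec()
contours, metas = slice_study(spec)
write_study("phantom_study.json", contours, metas)

inventory = Counter((metas[c.plane_id].view, c.label) for c in contours)
print(f"{len(metas)} imaging planes, {len(contours)} contours:")
for (view, label), count in sorted(inventory.items()):
    print(f"  {view:>4} / {label:<6} x{count}")
print()
print("Short-axis slices show the three clinical delineation cases:")
print("  LV only (mid-ventricle), LA + AO as two separate contours (atrial")
print("  level), and a single MERGED contour at the inflow/outflow junction.")
print("Study written to phantom_study.json")
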