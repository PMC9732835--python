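"""Stimulus geometry of virtual-distance face stimuli.

A 16-cm-wide face rendered on a screen 114 cm away subtends the same visual
angle as a real face at the simulated distance when its on-screen width is
face_width * screen_distance / virtual_distance; binocular disparity for a
6-cm interpupillary distance is realized as opposite per-eye mesh rotations.
"""

import columnscope as cs

geom = cs.ViewingGeometry()  # 114-cm screen, 16-cm face, 6-cm IPD

for d in (39.0, 57.0, 114.0, 300.0):
    p = cs.project_face(geom, d)
    print(f"virtual {d:5.0f} cm: screen width {p['screen_width_cm']:5.1f} cm, "
          f"angular width {p['angular_width_deg']:5.2f} deg, "
          f"disparity {p['disparity_angle_deg']:4.2f} deg "
          f"({p['rotation_deg']:4.2f} deg/eye)")

# the nine event-related distances for a subject with a 60-cm PS boundary
grid = cs.ps_distance_grid(60.0)
print("\ndistance grid (% of PS boundary -> cm):")
for pct, cm in zip(grid.percentages, grid.distances):
    print(f"  {pct:5.0f}% -> {cm:6.1f} cm")

# At 57 cm the 16-cm face fills 32 cm of screen and subtends ~6 deg of
# disparity (3 deg per eye); distances below 100% lie inside personal space.
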