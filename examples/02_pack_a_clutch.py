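"""Pack a clutch of eggs into the flask-shaped egg chamber.

Eggs are 46.7 mm spheres dropped sequentially under simulated gravity into
an axisymmetric chamber whose base sits at the nest depth.  The layout is
deterministic for a seed, overlap-free, and fills the chamber from the base
upward — the spatial arrangement that drives within-clutch temperature
differences.
"""

import numpy as np

from nestherm import build_domain, logger_positions, pack_eggs

geometry = build_domain(nest_depth=0.60, clutch_size=51)
layout = pack_eggs(geometry, 51, seed=1)

z = layout.egg_centres[:, 2]
print(f"packed {layout.clutch_size} eggs into a chamber at {geometry.nest_depth} m depth")
print(f"  neck length        : {geometry.neck_length*100:.0f} cm")
print(f"  chamber volume     : {geometry.chamber.volume()*1e3:.1f} L")
print(f"  clutch volume      : {51 * 4/3 * np.pi * layout.egg_radius**3 * 1e3:.1f} L")
print(f"  egg depth span     : {z.min():.3f} - {z.max():.3f} m")
print(f"  min centre spacing : {layout.min_separation()*1000:.2f} mm (egg diameter 46.70 mm)")

base, centre, top = logger_positions(geometry, layout)
print("logger positions (deepest egg / nearest-centroid egg / shallowest egg):")
for name, pos in (("base", base), ("centre", centre), ("top", top)):
    print(f"  {name:6s} z = {pos[2]:.3f} m")
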