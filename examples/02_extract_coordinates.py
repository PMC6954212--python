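"""Parse a serial-section reconstruction and extract 3D gold coordinates.

Expects the fixtures from 01_simulate_experiment.py in ./out_simulate/.
Each stamp mark is pushed through its section's affine transform, scaled
to nm by the pixel size, and placed at its section's mid-plane z.
"""

from pathlib import Path

import numpy as np

from immunogold3d import extract_points, parse_series, write_points_csv

series = parse_series(Path("out_simulate") / "fig1f_cell.ser")
pattern = extract_points(series, label_filter="gold", z_convention="midplane")
write_points_csv(pattern, "out_simulate/points.csv")

z = pattern.points[:, 2]
print(f"extracted points:   {pattern.n}")
print(f"z range:            {z.min():.0f}..{z.max():.0f} nm "
      f"({len(np.unique(z))} distinct section mid-planes)")
print(f"window volume:      {pattern.window.volume():.3g} nm^3")
# z is quantised to section mid-planes because a 50 nm slab localises a
# particle only to the slab; the in-plane (x, y) coordinates keep full
# pixel precision.
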