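"""Render digitally reconstructed topograms (DRTs) of the head phantom.

A topogram is the scout view acquired while the fan-beam source translates
along the scanner axis; the DRT engine reproduces it by exact Siddon ray
tracing with the virtual detector at the rotation axis.
"""

import numpy as np

from roomct.drt import ProjectionGeometry, project_point, render_topogram
from roomct.phantoms import add_texture, make_head_phantom, rasterize

spec, iso = make_head_phantom()
vol = add_texture(rasterize(spec, spec.default_grid(spacing=(2.0, 2.0, 2.0))))
print(f"head phantom: {vol.shape} voxels at {tuple(vol.spacing)} mm, isocenter {iso.coords}")

for name, alpha in (("LAT", 90.0), ("PA", 180.0)):
    geom = ProjectionGeometry.for_volume(vol, alpha, resolution=1.0, sad=570.0)
    topo = render_topogram(vol, geom)
    r, c = np.unravel_index(np.argmax(topo.pixels), topo.pixels.shape)
    pred = project_point(geom, iso)
    print(f"\n{name} view (alpha={alpha:.0f} deg, {geom.n_rows}x{geom.n_cols} px at 1 mm):")
    print(f"  max line integral: {topo.pixels.max():.1f} mm water-equivalent")
    print(f"  brightest pixel at (row {geom.row_coords()[r]:.1f}, col {geom.col_coords()[c]:.1f}) mm")
    print(f"  projected isocenter marker at (row {pred.row_y:.1f}, col {pred.col:.1f}) mm")

print(
    "\nThe brightest pixel is the dense isocenter sphere; it lands where the\n"
    "fan-beam point projector predicts, confirming renderer/projector\n"
    "consistency (rows map 1:1 to the longitudinal coordinate; columns are\n"
    "magnified by sad/(sad-d))."
)
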