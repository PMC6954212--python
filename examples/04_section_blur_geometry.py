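"""Section-plane geometry: cell-wall blur and the linkage-error sphere.

A section cut at distance s from the centre of a spherical cell shows a
shell of radius r as a circle of in-plane radius x = sqrt(r^2 - s^2);
two shell/plane pairs bound the blurred wall signal, whose radial width
is the blur extent D.
"""

from immunogold3d import BlurInput, LinkageSpec, blur_extent, linkage_ball, wall_band

# wall blur for a 500 nm cell cut by planes 300 and 400 nm off-centre
res = blur_extent(BlurInput(r1=500.0, r2=500.0, s1=300.0, s2=400.0))
print(f"in-plane radii:     x1 = {res.x1:.1f} nm, x2 = {res.x2:.1f} nm")
print(f"blur extent D:      {res.D:.1f} nm")
print(f"wall estimate:      {res.wall_estimate:.1f} nm (midpoint of x1, x2)")

# where wall signal can appear in a 50 nm slab near the equator
inner, outer = wall_band((0.0, 0.0, 0.0), 500.0, 20.0, (-25.0, 25.0))
print(f"wall annulus:       {inner:.1f}..{outer:.1f} nm in-plane radius")

# the 40 nm uncertainty sphere drawn around each gold particle
center, radius = linkage_ball((120.0, -40.0, 75.0), LinkageSpec())
print(f"linkage sphere:     radius {radius:.0f} nm around {center}")
# D grows as the section plane moves off the equator: an oblique cut
# crosses the wall shell over a wider radial band, so a sharp wall in an
# equatorial section looks smeared in a polar one.
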