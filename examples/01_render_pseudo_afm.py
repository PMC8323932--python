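"""Render a pseudo-AFM image of a synthetic molecule.

Builds a corrugated blob standing in for a large protein, grounds it on
its broadest face (as weak physisorption would), and scans it with a
2 nm / 15 degree probe tip.  Prints the image dimensions and the tallest
pixel, which for a tip resting on top of the molecule is the molecular
height plus nothing: the apex height at contact.
"""

import afmrigid as ar

model = ar.ground_on_stage(ar.make_blob(150, (12.0, 8.0, 5.0), seed=42))
probe = ar.ProbeShape(radius=2.0, half_angle_deg=15.0)
img = ar.render(model, probe, pixel_size=1.0)

print(f"image: {img.shape[0]} x {img.shape[1]} pixels at {img.pixel_size} nm/px")
print(f"max height: {img.heights.max():.2f} nm "
      f"(molecule top ~{model.positions[:, 2].max() + model.radii.max():.2f} nm)")

noisy = ar.add_noise(img, sigma=0.3, seed=1)
background = noisy.heights[img.heights == 0]
print(f"with 0.3 nm noise the background sd is {background.std():.2f} nm")
# The tallest pixel reads the molecule's top surface; the noisy variant is
# what a high-speed AFM frame of the same molecule would look like.
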