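"""Segment a frame and measure the six descriptors per etch pit.

The area histogram of an adequate capture-reaction scene peaks at
30-40 px; most pits are nearly circular (roundness ~ 1, aspect ~ 1.1).
"""

import numpy as np

from trackqc import simulate
from trackqc.features import describe, parameter_histograms, px_area_to_um2
from trackqc.segmentation import segment_image

pits = simulate.sample_pits(200, shape=(480, 640), rng_seed=1)
frame = simulate.render_image(pits, simulate.ADEQUATE, rng_seed=2, shape=(480, 640))
objects = segment_image(frame.pixels, threshold=120, split=True)
print(f"segmented {len(objects)} objects ({len(pits)} pits rendered)")

areas = [o.n_pixels for o in objects]
counts, edges = np.histogram(areas, bins=np.arange(0, 105, 5))
mode_lo = edges[np.argmax(counts)]
print(f"area mode bin: {mode_lo:.0f}-{mode_lo + 5:.0f} px "
      f"({px_area_to_um2(mode_lo):.2f}-{px_area_to_um2(mode_lo + 5):.2f} um^2)")

d = describe(objects[0])
print("first object:", {k: round(v, 3) for k, v in d.as_dict().items()})

hists = parameter_histograms(objects)
for name, (fractions, e) in hists.items():
    peak = e[np.argmax(fractions)]
    print(f"{name:>13}: distribution peak near {peak:.2f}")
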