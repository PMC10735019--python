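"""Simulate a synthetic autoradiographic frame with known ground truth.

Samples boron-neutron-capture decays, maps particle energies to mean
etched-pit areas through the calibration anchors, and renders an
adequate frame.
"""

import numpy as np

from trackqc import simulate

# the two capture channels and their branching intensities
draws = simulate.sample_bnc_decay(0, 10_000)
frac = sum(d[0] == "alpha1+Li1" for d in draws) / len(draws)
print(f"alpha1+Li1 channel frequency over 10k decays: {100 * frac:.2f}%  (tabulated 93.7%)")

for energy in (1.47, 1.0, 0.5):
    print(f"mean pit area at {energy:.2f} MeV: {simulate.energy_to_pit_area(energy):.0f} px")

pits = simulate.sample_pits(200, shape=(480, 640), rng_seed=1)
frame = simulate.render_image(pits, simulate.ADEQUATE, rng_seed=2, shape=(480, 640))
print(f"rendered {len(frame.truth)} pits on a {frame.pixels.shape} frame, label={frame.label}")
print("grey levels: background ~%d, darkest pit core %d" % (np.median(frame.pixels), frame.pixels.min()))
# the frame and its truth list can be written with simulate.save_dataset([frame], "out/")
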