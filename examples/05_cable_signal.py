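"""Two-channel cable-signal quantification on a synthetic movie.

Generates a cable-marker / cytosol-marker stack (17 z-slices at 0.7 µm)
with known per-bud cable amplitudes fluctuating frame to frame, removes
the cytosolic background by scaled-channel subtraction, and shows that
sibling asymmetry that looks large in single frames averages out over a
10-frame window.
"""

import numpy as np

from multibud import GeneratorParams, gen_two_channel_stack
from multibud.imaging import per_bud_cable_signal, subtract_cytosol, windowed_sibling_cv

p = GeneratorParams(
    seed=7, n_frames=60, cable_amplitudes=(30.0, 30.0, 30.0), amplitude_fluctuation=0.4
)
stack, masks, meta = gen_two_channel_stack(p)
corrected = subtract_cytosol(stack, masks)
signals = per_bud_cable_signal(corrected, masks)

res = windowed_sibling_cv(signals, window=10)
print(f"frames: {p.n_frames}, buds: {masks.nbud}, equal mean cable amplitudes")
print(f"mean instantaneous sibling CV: {res['mean_instantaneous_cv']:.3f}")
print(f"mean 10-frame windowed CV:    {res['mean_windowed_cv']:.3f}")
print(f"ratio: {res['mean_windowed_cv'] / res['mean_instantaneous_cv']:.3f} "
      f"(1/sqrt(10) = {1 / np.sqrt(10):.3f} for independent fluctuations; the")
print("per-frame channel scaling couples siblings and lowers it further here)")
print()
print("Snapshots overstate cable asymmetry between siblings; averaging over")
print("a 10-minute window reveals the underlying parity of the networks.")
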