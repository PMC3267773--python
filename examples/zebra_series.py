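"""ZEBRA two-site series: a single activation peak at 8 bp spacing.

The ZEBRA parameter set couples a short-range, high-amplitude steric
clash with steep recruitment distance attenuation, so phase modulation
is confined to small spacers: only the first opposite-face spacing
(8 bp between ZIIIB sites) survives as an interior activation peak.
"""

import numpy as np

from helixsynergy.activity_analysis import curve_from_table, detect_peaks
from helixsynergy.simulator import ZEBRA_MODEL_PARAMS, simulate_curve
from helixsynergy.synthetic import NoiseSpec, generate_activity_dataset

spacers = range(0, 21, 2)

noise_free = simulate_curve(spacers, factor="ZIIIB", params=ZEBRA_MODEL_PARAMS)
print("noise-free ZEBRA curve (relative activity):")
for s, a in zip(noise_free.spacers, noise_free.mean / noise_free.mean.max()):
    print(f"  spacer {int(s):2d} bp  {a:.3f}  {'#' * int(40 * a)}")
print("interior peaks:", detect_peaks(noise_free), "bp")

table = generate_activity_dataset(
    spacers=spacers, factor="ZIIIB", params=ZEBRA_MODEL_PARAMS,
    noise=NoiseSpec(cv=0.10, n_replicates=3, seed=3),
)
curve = curve_from_table(table)
peaks = detect_peaks(curve)
heights = [curve.mean[list(curve.spacers).index(p)] for p in peaks]
print("noisy triplicates: activation-maximal peak at",
      peaks[int(np.argmax(heights))], "bp")
print()
print("At 8 bp the two ZEBRA dimers bind opposite helix faces (folded phase")
print("180 deg for a 15 bp center-to-center distance); both assays place the")
print("activation/retardation optimum there.")
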