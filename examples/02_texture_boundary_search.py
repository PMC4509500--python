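"""Texture-statistic search for the thrombus boundary on one slice.

Builds a noise-free phantom slice, displaces a landmark 3 mm inward
from the true thrombus boundary, and shows how the five texture
statistics and their summed normalized metric relocate it.
"""

from dataclasses import replace

import numpy as np

from aaaseg.appearance import extract_region, score_candidates, texture_stats
from aaaseg.phantom import PhantomSpec, generate_study

spec = replace(PhantomSpec(), noise_sigma=0.0, background_texture_sigma=0.0)
study = generate_study(spec, 7)

i = 9  # middle slice
sl = study.pair.mri.get_slice(i)
centroid = study.seed_point[:2]
true_pt = study.contours["thrombus"][i].points[0]  # anterior boundary point

u = (true_pt - centroid) / np.linalg.norm(true_pt - centroid)
landmark = true_pt - 3.0 * u  # start 3 mm inside the boundary

region = extract_region(sl, landmark, centroid)
stats = texture_stats(region, 3.0)  # candidate at the true boundary
print("statistics at the true boundary (offset +3 mm):")
print(f"  dI      = {stats.dI:7.2f}   (mean in - mean out)")
print(f"  dm      = {stats.dm:7.2f}   (min in  - min out)")
print(f"  LmO     = {stats.LmO:7.2f}   (candidate - min out)")
print(f"  std_out = {stats.std_out:7.2f}")
print(f"  d_std   = {stats.d_std:7.2f}")

best, scores = score_candidates(region, ("dI", "dm", "LmO"))
moved = landmark + best * u
err = np.linalg.norm(moved - true_pt)
print(f"\nbest radial offset: {best:+.1f} mm (truth is +3.0 mm)")
print(f"relocated landmark misses the true boundary by {err:.2f} mm")

# The metric peaks where the interior stays bright-thrombus and the
# exterior picks up the dark wall: the proposal lands within a pixel of
# the true interface even from a 3 mm mis-initialization.
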