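"""Recover a known displacement between two vessel images.

Builds a synthetic vessel pattern, displaces it by a known similarity
transform (rotate 10 degrees, scale x1.05, translate (3, -2) px), and
recovers the displacement twice: from four matched landmarks (closed-form
least squares) and automatically by maximising mutual information.
"""

import numpy as np

import mesopipe as mp
from mesopipe import synthetic as syn

true = mp.SimilarityTransform(rotation_deg=10.0, scale=1.05,
                              translation=(3.0, -2.0), center=(47.5, 47.5))
reference, moved = syn.make_vessel_pair(syn.VesselSpec(seed=0), true)

src = np.array([(10.0, 10.0), (10.0, 80.0), (80.0, 80.0), (60.0, 20.0)])
fit, rms = mp.fit_landmarks(src, true.apply_points(src), center=(47.5, 47.5))
print("landmark fit:")
print(f"  rotation {fit.rotation_deg:+.6f} deg, scale {fit.scale:.6f}, "
      f"translation ({fit.translation[0]:+.6f}, {fit.translation[1]:+.6f}), "
      f"RMS {rms:.2e} px")

t, mi = mp.register_automatic(moved, reference)
rec = t.inverse()   # displacement of the moved frame relative to reference
print("automatic (mutual information) registration:")
print(f"  rotation {rec.rotation_deg:+.3f} deg (truth +10.000)")
print(f"  scale    {rec.scale:.4f} (truth 1.0500)")
print(f"  translation ({rec.translation[0]:+.2f}, {rec.translation[1]:+.2f}) "
      f"px (truth (+3.00, -2.00))")
print(f"  final MI {mi:.3f}")
print()
print("The returned transform aligns the moved frame back onto the")
print("reference; its inverse is therefore the displacement that was")
print("applied, which both methods recover to sub-pixel accuracy.")
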