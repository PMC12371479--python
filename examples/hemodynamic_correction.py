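"""Remove hemodynamic artifacts from a synthetic fluorescence recording.

Builds a small interleaved-illumination recording in which fluorescence is a
known linear mixture of two reflectance channels plus a clean neural signal,
then regresses the reflectance out pixel by pixel and reports how well the
generative coupling coefficients and the clean signal were recovered.
"""

import numpy as np

import mesopipe as mp
from mesopipe import synthetic as syn

spec = syn.HemoSpec(n_frames=600, height=32, width=32, seed=0)
fluo, reflectance, truth = syn.make_hemo_recording(spec)

result = mp.regress_hemodynamics(fluo, reflectance)

coeff_err = np.abs(result.coefficients[:, :, :2] - truth["coefficients"])
corrected = result.corrected.data - result.corrected.data.mean(axis=0)
clean = truth["clean"] - truth["clean"].mean(axis=0)
corr = (corrected * clean).sum(axis=0) / np.sqrt(
    (corrected ** 2).sum(axis=0) * (clean ** 2).sum(axis=0))

print(f"median |coefficient error|  : {np.median(coeff_err):.4f}")
print(f"pixels within +/-0.02       : {100 * (coeff_err <= 0.02).all(axis=2).mean():.1f}%")
print(f"median corr(corrected,clean): {np.median(corr):.4f}")
print(f"median per-pixel R^2        : {np.median(result.r_squared):.3f}")
print()
print("The corrected movie should carry the neural signal almost unchanged")
print("(correlation near 1) while the fitted betas match the generative")
print("hemodynamic coupling to within the noise-limited precision.")
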