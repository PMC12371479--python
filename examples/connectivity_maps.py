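"""Resting-state connectivity: seed-pixel map, ROI matrix and Fisher z.

Generates spontaneous activity in which four cortical regions share a
common latent factor with different loadings, then compares the empirical
ROI-pair Pearson correlations with the generator's closed-form prediction.
"""

import numpy as np

import mesopipe as mp
from mesopipe import synthetic as syn
from mesopipe.roi_manager import ROI, ROISet

spec = syn.ConnectivitySpec(seed=0)
stack, truth = syn.make_connected_recording(spec)

rois = ROISet([ROI(f"region{i}", "mask", {"mask": m})
               for i, m in enumerate(truth["region_masks"])])
mat = mp.correlation_matrix(stack, rois, fisher=True)

print("empirical r matrix:")
print(np.round(mat.r, 3))
print("closed-form prediction:")
print(np.round(truth["r"], 3))
print(f"max |empirical - predicted| : {np.abs(mat.r - truth['r']).max():.4f}")
print(f"Fisher z of r01             : {mat.z[0, 1]:.4f} "
      f"(arctanh({mat.r[0, 1]:.3f}))")

seed_map = mp.seed_correlation_map(stack, truth["region_masks"][0])
print(f"seed map: mean r inside region1 = "
      f"{np.nanmean(seed_map[truth['region_masks'][1]]):.3f}, "
      f"matrix r01 = {mat.r[0, 1]:.3f}")
print()
print("Regions loading on the shared latent factor correlate according to")
print("l_i l_j s_z^2 / sqrt((l_i^2 s_z^2 + s_i^2)(l_j^2 s_z^2 + s_j^2));")
print("at T=2000 frames the sampling error stays within a few hundredths.")
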