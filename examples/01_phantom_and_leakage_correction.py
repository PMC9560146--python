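"""Build a DSC phantom with contrast leakage and correct the CBV maps.

Enhancing tumour voxels leak gadolinium, which depresses the apparent
ΔR2* integral (T1-dominant extravasation). This script builds a
noise-free leaky phantom, computes uncorrected and leakage-corrected CBV
maps, and compares both against the constructed truth.
"""

import numpy as np

from dscfrac import PhantomSpec, build_phantom, compute_cbv_maps, wm_reference

spec = PhantomSpec(
    grid_shape=(48, 48, 12),
    lesion_fraction_hyper=0.4,
    k2_leakage=0.02,     # 1/s, unidirectional leakage rate in enhancing voxels
    noise_sigma=0.0,     # noise-free: correction should be exact
    lesion_radius_mm=10.0,
    seed=42,
)
series, truth = build_phantom(spec)

uncorrected, corrected, k2_map = compute_cbv_maps(
    series, truth.masks["brain"], truth.masks["lesion"]
)
ref = wm_reference(corrected.data, truth.wm_roi_masks)

leaking = truth.k2_map > 0
true_ratio = truth.true_cbv_map[leaking]
unc_ratio = uncorrected.data[leaking] / ref.reference
cor_ratio = corrected.data[leaking] / ref.reference

print(f"leaking voxels:                {leaking.sum()}")
print(f"true k2:                       {spec.k2_leakage:.3f} 1/s")
print(f"fitted k2 (median):            {np.median(k2_map[leaking]):.6f} 1/s")
print(f"uncorrected rCBV bias (median): {np.median(unc_ratio - true_ratio):+.3f}")
print(f"corrected rCBV bias (median):   {np.median(cor_ratio - true_ratio):+.3f}")
print(f"corrected max |rel err|:        {np.abs(cor_ratio / true_ratio - 1).max():.2e}")
# The uncorrected map underestimates rCBV in every leaking voxel; the
# corrected map recovers the constructed ratios to machine precision.
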