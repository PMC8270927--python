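"""Invert the 4-point Dixon signal model on a noisy phantom rendering.

Fits water, fat, fat-fraction and R2* maps voxel-by-voxel inside the
plaque mask, then compares the masked means against the known ground
truth.  FF is the lipid-rich-necrotic-core surrogate, R2* the
intraplaque-hemorrhage surrogate.
"""

import numpy as np

from plaquekit import dixon, phantom
from plaquekit.sample import neighborhood_average, whole_mask_mean

truth = phantom.make_phantom(seed=1)
series = phantom.render_dixon(truth, noise_sd=0.02, seed=2)  # 2% Rician
maps = dixon.fit_volume(series, mask=truth.plaque_mask_true)

mask = truth.plaque_mask()
ff = neighborhood_average(maps.fat_fraction, mask)
r2s = neighborhood_average(maps.r2star, mask)

print(f"fitted voxels: {int(maps.valid_mask.sum())}")
print(f"whole-plaque FF:   fitted {whole_mask_mean(ff, mask):.4f}  "
      f"truth {whole_mask_mean(truth.fat_fraction_map, mask):.4f}")
print(f"whole-plaque R2*:  fitted {whole_mask_mean(r2s, mask):.2f}  "
      f"truth {whole_mask_mean(truth.r2star_map, mask):.2f}  (s^-1)")
resid = maps.fit_residual[maps.valid_mask]
print(f"median fit residual: {np.median(resid):.2e} (sum of squares, a.u.)")
# At 2% noise the masked means track truth to a few percent; the residual
# reflects the injected noise level, not model mismatch.
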