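"""PSNR and components-form SSIM on a clean/degraded image pair.

Degrades a phantom reflectance with noise and reports MSE, PSNR (dB, higher
is better) and the SSIM luminance/contrast/structure decomposition (1 means
identical).
"""

import numpy as np

from retinexmed import evaluate_pair, make_reflectance

rng = np.random.default_rng(0)
clean = make_reflectance(128, 128, n_structures=6, seed=5).pixels * 255.0
noisy = np.clip(clean + rng.normal(0, 12.0, clean.shape), 0, 255)

rep = evaluate_pair(clean, noisy, bit_depth=8)
print(f"MSE  = {rep.mse:.2f}")
print(f"PSNR = {rep.psnr_db:.2f} dB   (identical images would be infinite)")
print(f"SSIM = {rep.ssim:.4f} = luminance {rep.luminance:.4f} "
      f"x contrast {rep.contrast:.4f} x structure {rep.structure:.4f}")
print("Noise leaves the means (luminance) intact but inflates the variance "
      "and decorrelates the images, which the contrast and structure "
      "components pick up.")
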