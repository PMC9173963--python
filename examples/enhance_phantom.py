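"""Center-surround enhancement of a bias-field phantom, scored against truth.

Builds a synthetic MRI-like slice I = S * R (piecewise-constant tissue
reflectance R under a smooth multiplicative bias field S plus noise), removes
the bias with single-scale and multiscale Retinex, and reports how much
closer each output is to the true reflectance.
"""

from retinexmed import generate, msr, recovery_scores, ssr

ph = generate(size=256, strength=0.5, noise_sigma=0.005, seed=7)
print(f"phantom: 256x256, bias strength 0.5, noise 0.005, "
      f"clipped fraction {ph.params['clipped_fraction']:.4f}")

obs = ph.observed.pixels
degraded, enhanced_ssr = recovery_scores(ph, ssr(obs, sigma=100.0))
_, enhanced_msr = recovery_scores(ph, msr(obs))

print(f"degraded input : SSIM vs truth = {degraded.ssim:.4f}, "
      f"PSNR = {degraded.psnr_db:.2f} dB")
print(f"SSR (sigma=100): SSIM vs truth = {enhanced_ssr.ssim:.4f}, "
      f"PSNR = {enhanced_ssr.psnr_db:.2f} dB")
print(f"MSR (25/75/150): SSIM vs truth = {enhanced_msr.ssim:.4f}, "
      f"PSNR = {enhanced_msr.psnr_db:.2f} dB")
print("Higher SSIM/PSNR than the degraded input means the enhancement "
      "recovered reflectance the bias field had obscured.")
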