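"""The evaluation protocol on a single simulated pair.

Shows the global fidelity metrics (SSIM / PSNR / NRMSE against the full-dose
reference), the lesion-level metrics (MAE and Weber contrast on annotated
ROIs), and a paired t-test comparing two degradation levels.
"""

import numpy as np

from petuq import generate_phantom, simulate_low_dose
from petuq import evaluation as ev

phantom = generate_phantom((64, 64), n_lesions=2, seed=11)
fd = phantom.image
dr = float(np.ptp(fd))

print("DRF    SSIM    PSNR(dB)  NRMSE   lesion MAE  Weber(ld)")
for drf in (4, 20, 100):
    ld = simulate_low_dose(fd, drf, seed=drf)
    mae = ev.lesion_mae(ld, fd, phantom.lesion_masks[0])
    wc = ev.weber_contrast(ld, phantom.lesion_masks[0], phantom.background_masks[0])
    print(f"{drf:4d}  {ev.ssim(ld, fd, dr):.4f}  {ev.psnr(ld, fd, dr):7.2f}  "
          f"{ev.nrmse(ld, fd):.4f}  {mae:9.1f}  {wc:8.2f}")

print("\nFull-dose reference Weber contrast:",
      round(ev.weber_contrast(fd, phantom.lesion_masks[0], phantom.background_masks[0]), 2))

# paired t-test: SSIM at DRF 20 vs DRF 100 over ten noise realizations
a = [ev.ssim(simulate_low_dose(fd, 20, seed=200 + k), fd, dr) for k in range(10)]
b = [ev.ssim(simulate_low_dose(fd, 100, seed=300 + k), fd, dr) for k in range(10)]
t, p = ev.paired_ttest(a, b)
print(f"\npaired t-test SSIM(DRF 20) vs SSIM(DRF 100): t = {t:.2f}, p = {p:.2e}")
print("Lower dose degrades every metric; the t-test shows the gap is systematic.")
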