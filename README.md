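# petuq — Bayesian low-dose PET reconstruction with uncertainty maps

`petuq` is a research package for people working on deep-learning
reconstruction of low-dose (LD) positron emission tomography: it
reconstructs a full-dose (FD) image from an LD input *and* says, pixel by
pixel, how uncertain that reconstruction is. Uncertainty that tracks the
actual degradation of the input is what makes a denoised image usable in a
clinical workflow, and producing it is the core of this package.

## Method

A residual U-Net `f_θ` (encoder widths 32/64/128, 3×3 kernels, leaky ReLU,
2×2 max pooling; a 1×1 tanh head added to the input) maps an LD slice to a
predicted FD slice, trained with the loss

```
L = L1(f_θ(I_LD), I_FD) + λ_gm · L1(‖∇ f_θ(I_LD)‖₂, ‖∇ I_FD‖₂)
```

Rather than a single point estimate of θ, training samples the posterior
over network weights with stochastic gradient Langevin dynamics (SGLD): at
each epoch `t` the loss gradient is perturbed,

```
g̃ᵗ ← gᵗ + eᵗ,   eᵗ ~ N(0, (sᵗ)²),   sᵗ = current Adam learning rate,
```

and Adam (lr 5e-4, weight decay 1e-10, plateau scheduler with factor 0.1 /
patience 10) updates the weights with the noisy gradient. The weight
vectors of the last `N` epochs `{θᵗ}` form an empirical posterior sample.
At inference the LD image is passed through all `N` snapshots:

```
Î_FD = (1/N) Σ f_θᵗ(I_LD)        — the reconstruction,
σ(x) = pixel-wise std of the N samples — the uncertainty map.
```

A Monte Carlo dropout benchmark (same backbone, p = 0.2 spatial dropout,
identical training without gradient noise, N stochastic test-time passes)
is included, along with the full evaluation protocol: SSIM / PSNR / NRMSE
against the FD reference, lesion MAE and Weber contrast on annotated ROIs,
per-DRF median uncertainty scores with the r² of a linear fit against the
dose reduction factor (DRF), and paired t-tests between methods.

No clinical data ships with the package. A phantom simulator generates
quantitative activity slices with focal hot lesions, and models dose
reduction as Poisson thinning with rescaling, `I_LD = DRF · Poisson(I_FD /
DRF)`, which preserves the mean and scales the variance by DRF — see
`docs/methods.md` for the full model description and its limitations.

## Worked example

```python
from petuq import (TrainConfig, build_model, make_dataset,
                   ensemble_predict_sgld, reduce_ensemble, train_sgld)

data = make_dataset(n_phantoms=40, drfs=[50, 100], seed=3)
cfg = TrainConfig(epochs=25, snapshots=8, batch_size=16, seed=3)
result = train_sgld(build_model(seed=3), data, cfg)
pair = data["eval"][1]
recon = reduce_ensemble(ensemble_predict_sgld(result.buffer, pair.ld))
```

This is `examples/train_and_reconstruct.py`; it prints (about two minutes
on one CPU):

```
trained 25 epochs: loss 0.3977 -> 0.0160; kept snapshots of epochs [18, ..., 25]

eval phantom at DRF 100:
  SSIM(low dose, full dose)       = 0.7959
  SSIM(posterior mean, full dose) = 0.9023
  uncertainty map: mean std 26.8, p95 85.7 (activity units)
```

The posterior mean recovers structure the Poisson noise destroyed (SSIM
0.80 → 0.90 against the full-dose reference), and the uncertainty map
summarizes where the 8 posterior samples disagree, in the same activity
units as the image. `examples/simulate_phantoms.py` prints the dose model
itself:

```
DRF   SSIM(ld, fd)   empirical var / (DRF * fd)
   4   0.9492         1.013
  10   0.8942         1.023
  20   0.8331         0.979
  50   0.7200         0.987
 100   0.6182         1.052
```

— the input degrades as the dose falls while the variance ratio stays near
1, confirming `Var = DRF · fd`. The remaining scripts show that the median
95th-percentile uncertainty rises with DRF and fits a line with r² ≈ 0.98
(`uncertainty_vs_dose.py`) and walk through the metrics protocol
(`metrics_protocol.py`); each prints its numbers with a line of
interpretation.

A CLI covers the same pipeline from the shell:

```bash
petuq simulate --out data/ --n-phantoms 60 --drfs 4,10,20,50,100 --seed 1
petuq train    --data data/ --method sgld --out runs/sgld
petuq infer    --run runs/sgld --input data/p0000_drf100_ld.nii.gz --out recon/
petuq evaluate --data data/ --run runs/sgld --dropout-run runs/dropout --out report/
```

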