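# denoise4d

Adaptive denoising of 4D (x, y, z, t) image volumes — for example
low-dose, cardiac-gated CT, where reduced X-ray exposure buys patient
safety at the price of heavy noise.  Instead of filtering each volume (or
each slice) independently, the algorithm treats the time-resolved volume as
a single 4D signal: structures that persist across slices and across the
periodic heart cycle are smoothed *along* their orientation, never across
it, so every added dimension contributes independent noise samples without
blurring the anatomy.

## Method

The core is local adaptive filtering steered by the structure tensor:

1. **Structure tensor.** A bank of 14 nonseparable monomial filters
   (4 odd first-order with directional responses û_m, 10 even second-order
   with responses û_m·û_n, all sharing a lognormal radial profile
   R(ρ) = exp(−4/(B² ln 2) · ln²(ρ/u₀)), u₀ = 3π/5, B = 2.5 octaves) is
   applied at half resolution.  The ten unique components of the symmetric
   4×4 tensor **T** are pointwise products of the responses,
   **T** = Q₁Q₁ᵀ + Q₂Q₂ᵀ; combining squared odd and even responses makes
   the estimate phase invariant.
2. **Control tensor, without eigensolves.**  The magnitude
   T_mag = ‖T⁸‖_F^{1/8} (built from three matrix squarings) is normalized
   over the dataset and mapped by the M-function
   γ = γ₀^β / (γ₀^{α+β} + σ^β) — a soft noise threshold σ with a
   controlled overshoot.  The normalized tensor T̂ = T/T_mag is remapped by
   the matrix polynomial C = γ·(I − (I − T̂_f)⁸(I + 8T̂_f)) with
   T̂_f = T̂²(3I − 2T̂), whose scalar transfer pushes small eigenvalues
   towards 0 and large ones towards 1 (no 4×4 eigendecomposition needed).
3. **Reconstruction.**  The denoised data is
   i_d = i_lp + Σ_k w_k C_k i_hp(k): an isotropic lowpass plus ten
   directional highpass filters (11 nonseparable 11⁴ kernels) weighted by
   the interpolated control tensor.  With C = I the bank is an exact
   allpass, so highpass detail is restored exactly where — and only where —
   the tensor says there is oriented structure.

Borders along z are preserved with normalized convolution
(c·s ∗ f)/(c ∗ f); the periodic time axis uses circular convolution.  Large
datasets are processed slab-wise along z with overlap margins chosen so the
concatenated output equals a monolithic run; a two-pass scheme keeps the
magnitude normalization dataset-global.  Both a spatial backend (windowed
7⁴/11⁴ kernels) and an FFT backend (exact frequency responses) are
provided.

## Worked example

```python
import numpy as np
from denoise4d import (PhantomSpec, PipelineConfig, denoise_4d,
                       make_fig1_phantom, plan_valid_slices, snr_db)

clean, noisy = make_fig1_phantom(
    PhantomSpec(extent=(64, 64, 24, 8), noise_sigma=0.5, seed=0))
plan = plan_valid_slices(24, use_normalized_conv=True)
print("half-res tensor slices:", plan.after_monomial)
print("denoised output slices:", plan.output_slices)

out = denoise_4d(noisy, PipelineConfig(backend="spatial"))
zlo, zhi = out.valid[2]
region = np.s_[:, :, zlo:zhi, :]
print(f"valid z-range: [{zlo}, {zhi})")
print(f"input SNR:    {snr_db(clean, noisy, region):6.2f} dB")
print(f"denoised SNR: {snr_db(clean, out, region):6.2f} dB")
```

prints

```
half-res tensor slices: 6
denoised output slices: 11
valid z-range: [6, 17)
input SNR:     -0.67 dB
denoised SNR:   7.17 dB
```

The phantom is a step/line/shading pattern replicated along z and t with
additive Gaussian noise at half the step amplitude; the planner shows how
the 7⁴ monomial margin (valid mode along z) and the 11⁴ reconstruction
margin reduce 24 input slices to 11 denoised slices, and the denoised SNR
rises by about 8 dB inside that region.

The same pipeline is available from the shell:

```sh
denoise4d phantom --kind fig1 --extent 64,64,24,8 --noise 0.5 --seed 0 --output noisy.raw
denoise4d run --input noisy.raw --output denoised.raw --backend spatial
denoise4d plan --slices 445 --slab-size 51
denoise4d cost --extent 512,512,445,20 --filters 11 --kernel 11
```

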