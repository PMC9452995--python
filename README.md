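# pbdw — compressed-sensing MRI reconstruction with patch-based directional wavelets

MRI acquires data in k-space (the 2-D Fourier domain); sampling below the
Nyquist rate shortens scans but makes the naive inverse-FFT reconstruction
alias. Compressed sensing recovers the image anyway by exploiting sparsity
in a transform domain. This package implements a *patch-based directional
wavelet* (PBDW) sparsifier and the reconstruction solver around it, for
single-coil Cartesian 2-D imaging:

- overlapping b×b patches `Q_i` (stride s, periodic wrap) cover every pixel
  exactly p = (b/s)² times, so `Σ Q_iᵀQ_i = p·I`;
- each patch's pixels are reordered along a locally selected geometric
  direction ξ_i (chosen from a small candidate set by minimizing the energy
  outside the E largest wavelet coefficients) and transformed by a 1-D
  orthonormal wavelet W, giving the analysis operator
  `B X = [W P(ξ_1) Q_1 X, …, W P(ξ_I) Q_I X]` — a tight frame with
  `(1/p)·BᵀB = I`;
- reconstruction from undersampled data y solves

  ```
  min_{X,∂}  Σ_i ‖∂_i‖₁ + (μ/2) Σ_i ‖∂_i − W P(ξ_i) Q_i X‖₂²
             + (β/2) ‖y − F_U X‖₂²
  ```

  by alternating exact block updates — soft thresholding at 1/μ for the
  coefficients, a closed-form Fourier-diagonal solve for the image — with
  continuation doubling μ from 2⁶ to 2²⁰ (β = 10⁸, inner tolerance 5·10⁻³);
- a conventional CS baseline (single global orthonormal 2-D wavelet, same
  solver loop) and the zero-filled inverse FFT serve as comparators;
- reconstructions are scored by a PSNR-style SNR (dB, 255 full scale),
  relative ℓ₂ norm error (RLNE), and the matching degree γ (in two
  documented variants — see `docs/methods.md`).

Synthetic phantoms (Shepp-Logan, oriented piecewise-constant stripes,
random shapes) and seeded sampling masks (variable-density random,
Cartesian lines, uniform random) make the whole pipeline self-contained —
no scanner data needed.

## Worked example

```python
import pbdw

truth = pbdw.make_shepp_logan(128)                       # 0–255 phantom
mask = pbdw.make_mask((128, 128), fraction=0.3, seed=1)  # 30% variable-density
y = pbdw.simulate_kspace(truth, mask)                    # undersampled k-space

recon = pbdw.reconstruct_pbdw(y)
report = pbdw.evaluate(truth, recon.magnitude)
print(f"RLNE {report.rlne:.4f}  SNR {report.snr_db:.2f} dB  "
      f"gamma_sim {report.gamma_similarity:.4f}")
```

prints

```
RLNE 0.0858  SNR 33.43 dB  gamma_sim 0.9963
```

i.e. from 30 % of k-space the directional-patch solver reconstructs the
phantom to 8.6 % relative error; the same data zero-filled gives RLNE 0.33
(`pbdw.rlne(truth, abs(pbdw.apply_FU_adjoint(y)))`) and the global-wavelet
baseline 0.19 (`pbdw.reconstruct_baseline`). The `gamma_similarity` of
0.996 says the reconstruction is nearly collinear with the truth (1.0 =
identical).

The same pipeline is available from a shell:

```sh
pbdw phantom --kind shepp_logan --size 128 --out truth.png
pbdw mask --shape 128x128 --fraction 0.3 --seed 1 --out mask
pbdw simulate --image truth.png --mask mask --out y
pbdw recon --kspace y --method pbdw --out-image recon.png --out-trace trace.csv
pbdw metrics --truth truth.png --recon recon.png
pbdw benchmark --out-dir results/          # full method-comparison grid
```

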