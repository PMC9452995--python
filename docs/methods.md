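# Methods

## Measurement model and operators

A 2-D complex image `X` (P×O) is observed through the Fourier
undersampling operator `F_U = M ∘ F`, where `F` is the *orthonormal* 2-D
DFT with DC at the array centre (fftshift convention) and `M` is a boolean
mask of acquired k-space locations. The orthonormal convention makes `F`
unitary, so `F_UᴴF_U` is exactly multiplication by the mask in the Fourier
domain — this is what turns the solver's image update into a closed-form
diagonal solve, and it is asserted to 1e-10 in the tests. Simulated
acquisition adds complex circular Gaussian noise (E|ε|² = σ² per acquired
sample) in k-space, the standard raw-data noise model for MRI; σ = 0 by
default since the benchmark isolates undersampling artifacts.

## The directional patch frame

Patches are b×b with stride s, b divisible by s, and *periodic wrap* at
the image borders. Wrapping is what makes the overlap exactly uniform:
every pixel is covered by exactly p = (b/s)² patches and
`Σ Q_iᵀQ_i = p·I` holds as an integer identity, so the analysis operator
is a tight frame and synthesis is the scaled adjoint `(1/p)Bᵀ`. Defaults
b = 8, s = 4 (p = 4, I = PO/16 patches): small enough that an 8×8 patch is
usually crossed by a single edge, overlapping enough to suppress blocking.

Within a patch, pixels are listed along lines parallel to a candidate
direction (the line through (r, c) with step (Δr, Δc) is indexed by
r·Δc − c·Δr; lines are ordered by their first pixel in row-major scan,
pixels within a line by their projection r·Δr + c·Δc). This traversal is a
permutation `P(ξ)` of the b² pixels — orthogonal by construction. The
candidate set is the 8 primitive integer directions
(0,1), (1,0), (1,1), (1,−1), (1,2), (2,1), (−1,2), (2,−1): the axis,
diagonal and "knight's move" orientations, the coarsest set that
distinguishes oblique edges a separable transform handles badly.

The 1-D transform `W` is an orthonormal multilevel wavelet decomposition
(periodized, so orthonormality is exact; decomposition depth capped by the
2-adic depth of b²). Default Daubechies-4; Haar is available as a config
key (`wavelet: haar | db4`). Because b² = 64 is small, `W` is materialized
once as an explicit 64×64 orthogonal matrix, which lets analysis of all I
patches run as one matrix product per direction group.

**Direction selection.** For each patch the candidate minimizing the
energy outside the E largest-magnitude coefficients of `W P(ξ) q` is
chosen; E defaults to ⌈b²/4⌉ = 16 (keep a quarter of the coefficients —
enough for the smooth content, few enough that edge alignment matters).
Selection operates on pixel *magnitudes* (iterates are complex; scoring
needs a real ordering). The residual is computed canonically as the sum of
the (b²−E) smallest squared magnitudes in ascending order, making the
score independent of which equal-magnitude coefficient a tie-break keeps
and bit-reproducible between the scalar and vectorized code paths; ties
across candidates go to the lowest candidate index.

## The solver

With auxiliary per-patch coefficients ∂_i, the objective

    Σ_i ‖∂_i‖₁ + (μ/2) Σ_i ‖∂_i − W P(ξ_i) Q_i X‖₂² + (β/2) ‖y − F_U X‖₂²

is minimized by exact alternating block updates:

* **coefficients** — `∂_i = soft(W P(ξ_i) Q_i X, 1/μ)`, the ℓ₁ prox
  (phase-preserving for complex input);
* **image** — the normal equations `(μp + β F_UᴴF_U) X = μ E_raw + β F_Uᴴy`
  with `E_raw = Σ Q_iᵀPᵀ(ξ_i)Wᵀ∂_i`, solved exactly in the Fourier domain:
  `F X = (μ·F(E_raw) + β·y) / (μp + β·mask)`. Off the mask this reduces to
  `F X = F(E_raw)/p`; at acquired locations β = 10⁸ dominates and pins the
  data. A conjugate-gradient oracle verifies this solve to 1e-6 in the
  tests.

Because both updates are exact minimizers, the objective at fixed μ and
fixed directions is non-increasing across inner iterations — asserted at
every iteration in the tests. The inner loop stops when the *relative*
image change `‖ΔX‖/‖X‖` falls below `tol = 5e-3` (an absolute threshold
would be meaningless without an intensity scale) or after
`max_inner_iters = 50` iterations. Continuation starts at μ = 2⁶ and
doubles μ per outer step up to μ_max = 2²⁰ (15 outer steps), warm-starting
each subproblem; the cap is what terminates the loop. Directions are
selected from the zero-filled image and, by default, re-estimated from the
current iterate at each outer step (`redetect_directions`) — cheap, since
selection is C·I small matrix products.

**Intensity normalization.** The threshold 1/μ is an absolute quantity
while the data scale is arbitrary, so the solver normalizes y such that
the zero-filled image has unit peak magnitude, solves, and rescales the
output (config key `normalize`, default on). This makes the default μ
schedule scale-free — thresholds of 1/2⁶…1/2²⁰ act on coefficients of
order one — and makes reconstruction exactly equivariant under y → c·y,
which is asserted to 1e-8 in the tests. Without it, thresholds that are
negligible against 0–255-scale coefficients would leave the ℓ₁ term
inert and the solver would return essentially the zero-filled image.

The **baseline** solver shares the loop verbatim but sparsifies with a
single global orthonormal 2-D wavelet (p = 1, no patches, no directions) —
the conventional CS formulation the directional transform is compared
against. All solvers are deterministic: identical inputs give bit-identical
outputs.

## Metrics

For magnitude images A (truth) and Ā (reconstruction) on a declared
intensity scale R (default 255, matching 8-bit display):

* `SNR = 10·log10(R²·O·P / Σ(A−Ā)²)` dB — a PSNR-style score; identical
  images report +infinity as a sentinel.
* `RLNE = ‖A−Ā‖₂/‖A‖₂` — scale-relative error, the primary comparison
  statistic here.
* Matching degree γ in **two variants**. The energy-ratio form
  `(‖Ā‖²−‖A‖²)/(‖Ā‖²+‖A‖²)` is 0 for a perfect reconstruction and compares
  only total energies, so a value near 1 cannot indicate a good match —
  yet near-1 values are conventionally reported as good. The package
  therefore also computes `gamma_similarity = 2⟨A,Ā⟩/(‖A‖²+‖Ā‖²)`, a
  normalized correlation equal to 1 iff Ā = A, and reports both columns
  (`gamma_printed`, `gamma_similarity`) so either convention can be read
  off. The energy form is implemented with squared norms; the unsquared
  reading changes its value on scaled pairs but is likewise 0 at a perfect
  match, so the interpretive caveat stands either way.

## Phantoms and what the benchmark shows

* `shepp_logan` — the standard piecewise-constant ellipse head phantom,
  rendered analytically at any size, scaled to [0, 255].
* `directional_stripes` — piecewise-constant square-wave stripes at
  requested angles in vertical bands (two-level, 55/200, so additive noise
  does not clip). Oblique sharp edges are exactly the structure where a
  per-patch directional ordering out-sparsifies a separable wavelet;
  a smooth (sinusoidal) profile would be nearly as sparse for the global
  transform and blur the comparison.
* `random_shapes` — seeded random ellipses, for unstructured regression
  surfaces.

The benchmark grid (method × sampling fraction × noise σ × mask seed;
defaults: Shepp-Logan 128², 30 % variable-density, σ = 0, 5 seeds)
reproduces the qualitative comparison the method is built for: median RLNE
orders directional-patch < global-wavelet < zero-filled. Passing it shows
the directional prior helps on piecewise-constant synthetic images with
simulated noiseless undersampling; it does not certify performance on
clinical scans, which have coil sensitivities, phase structure, complex
noise after magnitude reconstruction, and anatomy-dependent sparsity that
these phantoms do not emulate.

Undersampling defaults (30 % acquired, variable-density random with radial
density ∝ (1 + r/r₀)⁻³, r₀ = 10 % of the maximum radius, fully sampled
centre disc of 4 % radius, DC always acquired) are this package's
benchmark conditions, exposed in config. Pointwise patterns hit the
requested sample count exactly (weighted sampling without replacement);
`cartesian_lines` rounds to whole phase-encode lines, so its realized
fraction is exact only to one line.

## Numerical choices and degenerate inputs

- Orthonormal DFT and wavelets throughout; all frame/adjoint identities
  hold to ≤1e-10 relative and are regression-tested.
- Soft threshold at exactly |v| = t returns 0; complex thresholding keeps
  the phase.
- y = 0 reproduces the zero image (normalization guards the 0/0 with
  scale 1).
- Non-finite iterates abort with the outer step named in the error.
- keepE-style truncation keeps the earliest index on magnitude ties
  (stable sort).
- Metric guards: RLNE rejects an all-zero truth; γ rejects two zero
  images; SNR of identical images is the +infinity sentinel, serialized
  as `Infinity` in JSON and `inf` in CSV.

## Problem sizes

Tests and the acceptance script run at 16²–128² with 5 mask seeds — sizes
chosen so the full suite completes in seconds while every identity is
exercised at the default b = 8, s = 4 geometry and the benchmark ordering
is measured on the standard 128² phantom. The solver is O(I·b⁴) per inner
iteration (a few matrix products and two FFTs); a 128² reconstruction
takes ~0.3 s, so larger grids are a matter of patience, not design.

## Known limitations

- Single-coil, Cartesian, 2-D only; no parallel imaging, non-Cartesian
  trajectories, or 3-D.
- The ℓ₀ ideal is approached via its ℓ₁ prox with continuation; no global
  optimality claim.
- Direction candidates are the 8 primitive integer steps; finer angular
  resolution would need longer step vectors and larger patches.
- The benchmark's comparative conclusions are about synthetic phantoms
  (see above).
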