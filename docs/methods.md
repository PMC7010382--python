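# Methods

## Problem

Dynamic contrast-enhanced (DCE) MRI renography acquires a 2-D abdominal
slice every δt ≈ 1.5 s for about three minutes while a gadolinium bolus
perfuses the kidney. The clinical readout — the mean intensity of a fixed
kidney region of interest over time — is corrupted by breathing: the kidney
translates by a few pixels with a short, nearly fixed period, moving tissue
in and out of the ROI and imprinting high-frequency artefacts on the
time–intensity curve. Registration is awkward here because the tissue the
registration would lock onto is itself changing intensity as contrast
arrives. `wrdmd` instead removes the motion by spectral decomposition of the
sequence, with no registration and no manual delineation.

## Model

Vectorised frames are treated as snapshots of a linear dynamical system:
with `P1 = [x̄1 … x̄(N−1)]` and `P2 = [x̄2 … x̄N]`, an unknown propagator `A`
satisfies `P2 ≈ A·P1`. Dynamic mode decomposition (DMD) approximates the
spectrum of `A` without forming it: from the thin SVD `P1 = U Σ V*`, the
reduced operator `H̃ = U* P2 V Σ⁻¹` is diagonalised, `H̃ ω = ω σ`, and the
dynamic modes are `Ψ = P2 V Σ⁻¹ ω`. Each mode is a spatial image with a
complex eigenvalue `σ_j`; `μ_j = ln(σ_j)/δt` separates growth/decay (real
part) from oscillation (imaginary part). Slowly varying structure —
anatomy and contrast enhancement — lands in modes with eigenvalue phase
angle near zero; periodic motion and noise land in large-angle modes.

The pipeline is two-stage:

1. **W-DMD.** A window of `W` consecutive frames (default `W = 3`, matched
   to the breathing period) slides with stride 1. Each window's DMD yields
   `W − 1` modes; the one with `|μ|` nearest zero is the window's low-rank
   background image `c1`, the rest aggregate into the sparse image `c2`
   which carries the intra-window (breathing) change. Concatenating the
   `c1`s gives the C1 sequence of length `N − W + 1`; C2 is kept for
   inspection but discarded from the pipeline.
2. **DMD + R-DMD.** A full DMD of C1 produces `N − W` modes. One member of
   each complex-conjugate eigenvalue pair is dropped (the pair carries
   duplicate information for real data), the survivors are sorted by
   ascending `|phase angle|`, and the sequence is rebuilt from the `k` most
   significant modes (default `k = 3`) as
   `P̂2 = Ψ_sel · (ω⁻¹ Σ V*)_sel` — the full-rank identity
   `P̂2 = Ψ ω⁻¹ Σ V*` with only the selected modes' rows/columns retained.

### Numerical choices

- **Truncated inverse as row selection.** `ω` is the eigenvector matrix of a
  non-normal operator and is not orthogonal. Keeping the selected *rows of
  ω⁻¹* (the left eigenvectors) makes the truncation an exact spectral
  filter: discarded eigen-components vanish identically and `k = d`
  reproduces `P2` to machine precision. The alternative — a Moore–Penrose
  pseudo-inverse of the selected eigenvector *columns* — is an orthogonal
  projection in coefficient space that leaks discarded components back into
  the output scaled by ratios of singular values (which span several orders
  of magnitude on image data); in our experiments it re-amplified the very
  motion the truncation is meant to remove.
- **Background-mode identification** inside a window uses the smallest full
  `|μ|`, ties broken by largest `|σ|`. The real part of `μ` alone cannot
  work: a period-two alternation has `σ ≈ −1`, i.e. `Re(μ) ≈ 0` exactly
  like the true background, and would masquerade as it.
- **SVD truncation.** Singular values below `max(Σ)·1e−10` are dropped
  before inversion; near-zero singular values would amplify noise into the
  modes and the reduced operator.
- **Conjugate pairing.** Two eigenvalues pair when
  `|σ_a − conj(σ_b)| < 1e−8·(1 + |σ_a|)` and both imaginary parts are
  non-negligible at the same tolerance; numerically real eigenvalues never
  pair (so repeated real eigenvalues are all retained). The member with
  non-negative imaginary part is kept.
- **Mode scaling for C1/C2.** Dynamic modes are defined only up to complex
  scale, so raw mode images are not photometrically meaningful. Per window,
  amplitudes `b` solve `x̄1 ≈ Ψ b` by least squares and the emitted images
  are `Re(Ψ_bg b_bg)` and `Re(Σ_{j≠bg} Ψ_j b_j)`, which keeps C1 on the
  input intensity scale for downstream curve analysis.
- **Imaginary residue.** When a kept mode's conjugate partner was pruned the
  reconstruction acquires an imaginary part; its magnitude is logged at
  debug level and the real part is emitted.
- **Degenerate inputs.** All-zero frames raise a degenerate-input error; a
  window of identical frames yields a single background mode and a zero
  sparse image; a constant curve has an undefined smoothness score and
  returns `+inf` with a warning.

## Evaluation metrics

- **Block matching** (exhaustive full search). The reference frame is tiled
  into 15×15 blocks with 5-pixel overlap (partial border blocks skipped);
  for each block every displacement within ±5 pixels that stays inside the
  frame is scored by mean squared error (mean absolute difference
  available) and the minimum wins, ties resolving to the smallest norm and
  then row-major candidate order so the search is bit-reproducible against
  a brute-force oracle. The mean Euclidean displacement per frame pair,
  averaged over consecutive pairs, is the stability score (the mean over
  all blocks of all pairs is logged alongside); pairing every frame with
  the first instead exposes the breathing periodicity.
- **Window-length selection.** The motion-vs-first-frame series is
  detrended with a centred moving average (the contrast-enhancement
  envelope otherwise dominates), autocorrelated, and the first local
  maximum above 0.3 at lag ≥ 2 gives the period; an undetectable period
  falls back to `W = 3` with a warning. A one-sample lag is excluded — it
  carries no cycle information and every period in the package is ≥ 2.
- **Degree of smoothness** of a time–intensity curve: `D = std(t̃)/|mean(t̃)|`
  on the first differences `t̃`, sample standard deviation (`ddof = 1`).
  `D` is invariant to intensity scale and offset; smaller is smoother.

## Synthetic phantom

No public DCE-MRI renography set accompanies the method, so testing uses a
seeded generator that emulates the acquisition regime: 120 frames of 64×64
at δt = 1.5 s; a kidney ellipse whose intensity follows a gamma-variate
bolus curve (amplitude 100 over a background of 20, onset 7.5 s, peak at
67.5 s, α = 3); a liver band enhancing more slowly (60 / onset 15 s / peak
105 s / α = 2); a static smooth Gaussian-field texture (amplitude 10,
smoothing 3 px) standing in for anatomical structure — without spatial
texture, block matching in flat regions degenerates to arbitrary
displacements and motion metrics are meaningless; vertical rigid
translation of 2 px repeating `(0, a, a)` every 3 frames (a discrete
shallow-breathing cycle; a sampled sinusoid, horizontal axis, linear drift
and sub-pixel amplitudes are available); Gaussian noise with σ = 1 (1% of
peak enhancement). Translations are integer by default and realised by
cropping a padded canvas, so block-matching ground truth is exact. The
generator returns rest-position ROI masks, the true displacement trace and
the noiseless enhancement curves, and is bit-reproducible under its seed.

What the phantom does **not** model: MRI physics (coil sensitivity,
k-space sampling, T1 saturation), non-rigid and through-plane motion,
irregular breathing, and spatially varying enhancement within an organ.
Passing tests therefore demonstrate the algebra and the motion-removal
mechanism under the stated motion model, not clinical performance.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
64×64×120 phantom (full scanner-resolution 240×320 geometry is exercised
only for snapshot-matrix shape checks), exactness identities on random 16×16×10
stacks, and block-matching cross-checks on 20 random 32×32 pairs — sizes at
which every guarantee is exercised end-to-end in well under a minute each.

## Known limitations

- A near-linear enhancement ramp (gamma-variate mid-rise) makes the two
  eigenvalues of a 3-frame window degenerate toward 1: the fixed point of
  the local dynamics is poorly defined and part of the enhancement leaks
  into the sparse channel C2 (an `e′²/|e″|`-sized share). The full pipeline
  is insensitive to this — the later full-sequence DMD re-separates
  contrast from motion — but C1/C2 alone should not be read as a clean
  low-rank/sparse split during fast linear enhancement. An exponential
  saturation `e(t) = E(1 − ρ^t)`, whose window dynamics are exactly linear
  with eigenvalues `{1, ρ}`, splits cleanly.
- On the square-wave integer-shift phantom, W-DMD alone reduces measured
  motion only modestly (the per-window background is a phase-dependent
  blend of two frame positions); the bulk of the stabilisation comes from
  the k-mode reconstruction stage.
- `D` is undefined (returned as `+inf`) when the curve's net change is
  zero; comparisons should use curves with a nonzero trend, which contrast
  enhancement provides.
- The window length is global; sequences whose breathing period drifts
  would need per-segment selection, which is out of scope.
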