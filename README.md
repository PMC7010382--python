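# wrdmd

Registration-free motion correction for dynamic contrast-enhanced (DCE)
image sequences by **windowed and reconstruction dynamic mode decomposition
(WR-DMD)** — built for DCE-MRI renography, where breathing translates the
kidney by a few pixels with a short, nearly fixed period and corrupts the
ROI time–intensity curves that downstream perfusion analysis depends on.
Conventional registration struggles here because tissue intensity itself
changes as the contrast bolus passes; WR-DMD instead separates slow
contrast dynamics from fast periodic motion spectrally, with no reference
frame and no manual delineation.

## Method

Vectorised frames `x̄_1 … x̄_N` are snapshots of an assumed linear system
`P2 ≈ A·P1` (`P1`, `P2` the first/last `N−1` frames). The spectrum of `A`
is obtained on the SVD basis of `P1 = U Σ V*` via the reduced operator
`H̃ = U* P2 V Σ⁻¹`, `H̃ω = ωσ`, with dynamic modes `Ψ = P2 V Σ⁻¹ ω` and
frequencies `μ_j = ln(σ_j)/δt`. The pipeline:

1. **W-DMD** — slide a window of `W` consecutive frames (default `W = 3`,
   matched to the breathing period found by block matching); per window,
   keep the mode with `|μ| ≈ 0` as the low-rank image C1, discard the
   sparse remainder C2 that carries the intra-window breathing motion.
2. **R-DMD** — run a full DMD on the C1 sequence, drop one member of each
   complex-conjugate eigenvalue pair, sort modes by ascending `|phase
   angle|`, and rebuild the sequence from the `k = 3` most significant
   modes: `P̂2 = Ψ_sel (ω⁻¹ Σ V*)_sel`.

Stabilisation is quantified by exhaustive-search block matching (15×15
blocks, ±5 px search; mean displacement per consecutive frame pair) and by
the degree-of-smoothness `D = std(t̃)/|mean(t̃)|` of the first-differenced
ROI curve (smaller = smoother). A seeded synthetic renography phantom —
enhancing kidney and liver, static anatomical texture, periodic rigid
translation, noise, full ground truth — supports end-to-end testing.
See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```sh
wrdmd simulate --seed 1 --out sim
wrdmd correct sim/phantom.tif --window 3 --k 3 --out corrected.tif
wrdmd evaluate sim/phantom.tif corrected.tif \
      --mask sim/masks/kidney.png --out eval
```

prints

```text
wrote 120 frames to sim/phantom.tif
120 frames -> 117 corrected frames: corrected.tif
 sequence  n_frames  global_mean_motion_px  degree_of_smoothness
      raw       120               1.461119            139.507309
corrected       117               0.000000              8.484453
mean motion magnitude reduced by 100.00%
```

The phantom's 2-pixel period-3 breathing gives the raw sequence a global
mean block displacement of 1.46 px per consecutive frame pair; after
WR-DMD the block matcher finds no residual displacement. The kidney
time–intensity curve's smoothness score drops from 139.5 to 8.5 — the
motion-induced intensity spikes are gone while the enhancement curve's
shape (which is why `D` stays above zero: genuine contrast dynamics plus
residual noise) is preserved. The sliding window costs two frames and the
reconstruction one more, hence 117 output frames; `eval/` holds the motion
profiles and curves as CSV.

The same operations are available as a library:

```python
from wrdmd import default_renography_phantom, run_wrdmd

phantom = default_renography_phantom(seed=1)
corrected = run_wrdmd(phantom.stack, W=3, k=3)   # FrameStack of 117 frames
```

`read_sequence` ingests multi-page TIFF, directories of PNG/TIFF frames, or
NIfTI stacks with time on the third axis; `wrdmd decompose` exports the
eigenvalue table and galleries of the most/least significant mode images.

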