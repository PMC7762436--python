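# Methods

## Problem setting and assumptions

The package sizes single bioparticles from bright-field frames with exactly
one particle on a clean background — the imaging regime of flow cytometers
with per-event cameras. Two assumptions are load-bearing: (i) the particle
boundary is the strongest intensity edge in the frame, and (ii) particle
outlines are well approximated by ellipses (circles for beads and
*Cryptosporidium*-like oocysts, elongated ellipses for *Giardia*-like
ones). Frames violating either (debris clusters, touching particles,
out-of-focus halos stronger than the particle edge) are reported as
unsegmentable rather than guessed at.

## Segmentation chain

Stages, in order, with defaults:

| stage | parameters | default | why |
|---|---|---|---|
| resize | side | 120 px | fixed working resolution; per-axis factors retained so results are reported in original pixels |
| Gaussian blur | size, σ | 5 × 5, σ = 1.4 px | standard pre-Canny denoising scale for a 120 px frame |
| Canny | low, high | 50, 150 (0–255 scale) | classic 1:3 hysteresis ratio; Sobel 3-tap derivatives |
| morphology | kernel, iterations, order | 3 × 3, 1 dilate + 1 erode, dilate first | closes gaps in the edge ring; see below |
| speck gate | min area | 20 px² (filled, resized frame) | rejects noise blobs while keeping a ~4 px bead disk |
| shape fit | — | least-squares ellipse, ≥ 5 contour points | minimum-area rotated rectangle fallback below 5 points |

Numerical conventions: intensities are floats on the 0–255 scale after
preprocessing (0–1 inputs are scaled up); coordinates are 0-based, x right,
y down, contour points at pixel centres; convolution and morphology use
edge-repeating mirror ("reflect") padding, which avoids spurious border
edges and conserves total intensity; areas are computed on filled masks.
Non-maximum suppression breaks plateau ties asymmetrically (strict
comparison toward the forward neighbour) so an ideal step edge thins to a
single-pixel line. Components of equal filled area are disambiguated by
centroid distance to the frame centre.

**Morphology order.** The edge map leaving Canny is a one-pixel-wide ring;
eroding it with a 3 × 3 kernel before dilating would delete it entirely (the
minimum over any neighbourhood of a 1-px chain is background). The default
therefore applies morphological closing — dilate to bridge ring gaps, then
erode to restore thickness — and `morph_order="erode_first"` remains
available for inputs whose edge maps are thick enough to survive it.

**Known bias.** The traced boundary is the outer edge of the closed ring,
so raw pixel diameters run ~1.5 px large in the 120 px frame (~2–3 px after
mapping back through a 256→120 resize). This is deliberate: the bias is
absorbed by the learned converter's intercept, which is precisely why a
learned polynomial outperforms any fixed µm/pixel ratio on this chain. Raw
pixel outputs should not be multiplied by a nominal ratio when absolute
accuracy matters.

## Calibration models

Each segmented bead contributes one sample: x = (height + width)/2 in
original pixels (beads are spherical; `bead_axis="major"` switches to the
major axis), y = the certified class diameter. The quadratic
y = ax² + bx + c is solved through the explicit 3 × 3 normal-equation system
on the raw moments sₖ = Σxᵢᵏ; the linear model through the corresponding
2 × 2 system. Raw Vandermonde moments are ill-conditioned for large pixel
values, so the solver warns above condition number 1e8 (the test-suite
cross-checks against a QR solve). RMSE is in-sample over the training
beads — model selection compares nested models on identical data, so a
held-out split would change the comparison, not the ordering, and the
quadratic's training RMSE can never exceed the linear's. Ties select the
quadratic. Negative predictions (extrapolation below ~2 px) are clamped to
zero with a warning. Height and width of non-spherical particles are
converted independently through the same scalar model.

## Synthetic frames

The generator emulates: particle geometry (anti-aliased 4× supersampled
rasterisation, so sub-pixel diameters are meaningful), optics defocus
(Gaussian blur, default σ = 1 px), sensor noise (additive Gaussian on
intensity, default σ = 0.02, clipped to [0, 1]), bead manufacturing spread
(diameter CV 2 %), and position jitter (±2 px). Defaults: bright-field
contrast background 0.9 / foreground 0.15, frame 256 px at 0.33 µm/pixel —
contrast and noise chosen so the default segmentation config operates
comfortably, and both exposed in `OpticsSpec`. The ground-truth mask is the
≥ 50 %-coverage rasterisation *before* blur and noise. Oocyst presets draw
axis lengths from normal distributions (*Giardia*-like: 11.87 ± 1.99 µm by
7.92 ± 0.75 µm, axes swapped if a draw inverts their order;
*Cryptosporidium*-like: 5.03 ± 0.48 µm circles) at uniform orientation.

Determinism: a master seed expands to per-frame 31-bit seeds via
`SeedSequence([master, frame_index, stream])`, with separate streams for
size draws and rendering; the per-frame seed is recorded in the manifest,
so any single frame is reproducible in isolation.

What the generator does **not** emulate: physical point-spread functions or
diffraction, internal particle texture (oocyst walls, refractile bodies),
illumination gradients, motion blur, or multi-particle scenes. Passing
tests on synthetic frames therefore demonstrate the pipeline's geometric
and statistical correctness, not robustness to every real-world imaging
artefact; the published mean IoU on real oocyst images (84.4 %) is
data-dependent and is mirrored here only as a ≥ 0.80 property on seeded
synthetic beads.

## Problem sizes used in checks

The statistical checks run at sizes chosen to keep the suite quick while
leaving clear statistical margins: 50 frames (5 per bead class) for the
IoU benchmark, 300 frames (30 per class) for the learned-vs-fixed-ratio
comparison, 100 random sample sets for the least-squares nesting property,
and n = 1000 draws for generator moment convergence. The 3 µm class sits at
the chain's resolution limit (a ~4 px disk in the resized frame) and
occasionally fails the speck gate; batch drivers record such frames and
carry on, and calibration remains well-posed from the other classes.

## Limitations

- One particle per frame; no instance separation.
- The ellipse fit degrades for strongly non-elliptical or concave outlines.
- Calibration validity is bounded by the bead range (~9–55 px); the
  quadratic's vertex lies far outside it, but extrapolation beyond the
  range is unguarded apart from the non-negativity clamp.
- No uncertainty quantification beyond training RMSE and per-class SD.
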