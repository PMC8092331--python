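# Methods

This note documents the models, algorithms and numerical choices behind
`chromablend`, and what its tests do and do not establish.

## Compositing model

An endoscopic scene is treated as the rendering of two independent
components — an instrument foreground X_F and a tissue background X_B —
by an unknown ideal blending operator. Since that operator is not
available, blending is modelled probabilistically over a fixed basis
{φ_m} of M = 3 superimposition operators (trivial copy-paste, Gaussian
feathering, Laplacian pyramid blending). Labels are independent of the
operator: the composite's ground truth is always the binary foreground
mask, which is what makes arbitrary convex combinations of basis outputs
legitimate training images.

Two sampling schemes over the basis are implemented:

* **multi-blend** — for each foreground–background pair, emit all M
  basis blends (M images, identical labels);
* **mix-blend** — per visit of a pair, draw λ ~ Dir(α) and emit the
  single per-pixel convex combination Σ_m λ_m φ_m. A fresh λ is drawn at
  every visit and never cached, so the number of distinct blends of a
  pair grows with the number of stream iterations. Pairs are sampled
  uniformly with replacement.

With α = (1, 1, 1) (the default) λ is uniform over the 2-simplex. With a
tiny symmetric α the Dirichlet concentrates at the simplex corners
(α = 0.001 gives max λ_m > 0.99 in ≈ 99.1% of draws), recovering
multi-blend as a limiting case of mix-blend.

## Blending basis details

* **Feathering.** The binary mask is eroded with a k_e×k_e square
  element (k_e = 3; the frame outside is treated as foreground so a
  full-frame mask survives erosion), then blurred with an explicit
  k_b-tap separable Gaussian (k_b = 5) whose σ follows the conventional
  size rule σ = 0.3·((k_b−1)/2 − 1) + 0.8. The soft mask is clipped, not
  renormalised. The emitted label stays the original binary mask.
* **Laplacian pyramid.** 5-tap binomial kernel (1,4,6,4,1)/16, reflect
  border handling, L = 4 levels by default; inputs are padded to a
  multiple of 2^L and cropped after collapse. Upsampling inserts zeros
  and convolves with the doubled kernel, so the analysis/synthesis pair
  satisfies the collapse identity exactly in floats: blending two copies
  of the same image reproduces it to machine precision. The collapsed
  blend is clipped (not renormalised) to [0, 1]; clipping is local and
  cannot affect the label. Note that the pyramid's equivalent blending
  kernel has support ≈ 2(2^L − 1) pixels, so the three basis outputs
  only agree *approximately* beyond 2^L pixels from a mask edge; exact
  agreement with copy-paste holds for the feathered blend beyond
  k_e + k_b pixels, and for the pyramid the deviation falls below 1/255
  at roughly 3·2^L pixels.

## Chroma-key extraction

Foregrounds are segmented from green-screen frames in three stages:

1. **HSV threshold**: the green set is {hue ∈ [80°, 160°], S ≥ 0.25,
   V ≥ 0.15}; its complement is the tool candidate. Real recordings tune
   these per session; the defaults cover commodity chroma fabric and are
   fully configurable (a red-chroma session is just a different band).
2. **Component filter**: only the N_i largest 8-connected components are
   kept, N_i being the known number of instruments in frame. Area ties
   break toward the smaller label of a deterministic raster-scan
   labelling — ties are vanishingly rare in practice but determinism
   keeps runs reproducible. The filter runs *before* refinement, as
   noise reduction on the thresholded candidate.
3. **GrabCut refinement**: green pixels seed sure background; the
   candidate eroded by a 5-px disk seeds sure foreground (the erosion
   keeps halo pixels out of the foreground colour model); everything
   else is re-decided. Sure seeds are never relabelled.

Masks that fail the automated QC heuristics (component count ≠ N_i,
foreground fraction outside [0.005, 0.8], no border-touching component)
are flagged with a score of 1 − flags/3, never silently dropped;
exclusion is the caller's decision.

## GrabCut implementation

No suitable segmentation refiner being available as a library
dependency, the package ships its own GrabCut-style solver: per class, a
full-covariance Gaussian mixture (5 components, fitted by EM with
reg_covar = 1e−4) models pixel colour; the binary labelling of the
uncertain pixels minimises the usual energy with data terms
−log p(z | class) (clamped at 60 nats) and contrast-sensitive Potts
pairwise terms w = γ/dist · exp(−β‖z_i − z_j‖²) on the 8-neighbourhood,
γ = 50 and β = 1/(2⟨‖z_i − z_j‖²⟩). The cut is solved exactly by
max-flow on integer-scaled capacities (scale 256); only uncertain pixels
enter the graph, with sure-labelled neighbours folded into terminal
capacities, which enforces the hard constraints by construction rather
than by large finite weights. Five GMM-refit/cut rounds are run, with
early exit on a fixed point. GMM initialisation seeds come from the
caller's RNG stream, so results are deterministic per (seed, input).

## Probability-map refinement

A network's soft output is converted to seeds through certainty bands:
p < 0.2 is sure background, p ≥ 0.8 sure foreground (strict/inclusive
inequalities deliberately asymmetric), and the band in between is
re-decided by GrabCut, initialised as probable-foreground when p ≥ 0.5.
Guarantees: certain pixels always keep their seeded class (re-asserted
unconditionally on the output); an empty uncertain set short-circuits to
pure thresholding; absence of any sure-foreground pixel (no colour model
can be fitted) falls back to plain 0.5-binarization with a warning.

## Augmentation and standardization

Foreground tools are zoomed (×[0.7, 1.3]), rotated (±90°), flipped and
shifted (≤ 0.2 of the frame), always re-validating that every tool
component still touches an image border — draws that break the invariant
are resampled up to 10 times, then the geometric part falls back to
identity. Blood droplets (Poisson(3) count, radius 2–15 px, dark-red hue
±10°, alpha 0.3–0.8) are drawn strictly on tool pixels. Backgrounds get
flips, 90° rotations and brightness jitter, then *flying distractors* —
cutouts of donor backgrounds shaped like a randomly transformed tool
mask, blended with the *same* procedure (under mix-blend, the same
λ-weighted sum) as the real tools and contributing no label — and
*endoscopic padding*, a black rectangular frame (width ≤ 0.1·min(H, W))
or outside-of-disc region (radius 0.45–0.55·min(H, W)) with additive
Gaussian noise. Blended images receive cutout, smoke, shadow, JPEG
re-compression (4:4:4 sampling so quality alone controls the loss),
RGB/HSV shifts, additive/multiplicative/intensity-dependent noise, and
Gaussian/motion/median blur; each op fires independently with
probability 0.3 and none of them modifies the label (cutouts keep the
label even over tool pixels — standard cutout semantics). Magnitudes are
package defaults chosen to keep tools recognizable; all are
configurable. Padding is applied to the background before blending, so a
tool may overlap the black border; a `repad_after_blend` flag (default
off) would re-apply it afterwards.

Before blending, both elements of a pair are resized to a standard
640-pixel width (aspect preserved; bilinear for images, nearest +
re-binarization for masks) and the taller element is randomly cropped
vertically to the common height. If the crop would remove the tool
entirely, the window is recentred on the mask rows.

## Evaluation

Per-frame IoU is J = (|A∩B| + ε)/(|A∪B| + ε) with ε the float64 machine
epsilon, so two empty masks score 1 and J ∈ [0, 1] with J = 1 iff the
masks are equal. An alternative `denominator="sum"` (Σŷ + Σy, without
subtracting the intersection) is kept for comparison; it scores
identical masks at 0.5 and is not the default. Probability maps binarize
at p ≥ 0.5 with ties to foreground. Sequence scores are arithmetic means,
reported in percent. The cross-entropy uses the natural logarithm with a
1e−12 probability floor and the two-class single-map parameterisation
(P(background) = 1 − P(tool)).

## Synthetic fixtures: what they emulate and what they do not

The fixture generator emulates a chroma-key session: a green field
(hue ≈ 120° ± 15°, linear illumination gradient, Gaussian sensor noise)
with 1–3 capsule-shaped "instruments" entering from the borders with a
metallic gray axial gradient and a specular streak, plus a soft shadow
on the fabric that stays inside the chroma band and is deliberately
excluded from the ground-truth mask (the hard case thresholding must
survive). Backgrounds are red/pink multi-octave value-noise textures
with wet-tissue speculars and a vignette; their pixels essentially never
enter the green band. Tool placement scatters directions widely around
the inward border normal and shrinks capsules under retry pressure, so
1–3 non-overlapping border-connected shapes almost always fit; an
irrecoverable configuration raises a generation error. Probability-map
fixtures blur the truth mask and push a configurable fraction of pixels
uniformly into the uncertain band (0.2, 0.8).

These fixtures have exact masks by construction and colour-separable
classes. Passing tests therefore establish the *contracts* — mask
propagation, convexity, determinism, seed preservation, metric
definitions — and the correct behaviour of extraction/refinement on
separable colour statistics. They do not establish segmentation accuracy
on real endoscopic video, which depends on network training on the
generated data at scale (out of scope here: the package generates the
training stream; it does not train the network).

## Problem sizes and defaults

Tests and the acceptance script run at desk scale as a deliberate
package choice: 128×128 fixtures (320×320 for the 640-px standardization
path), 50-seed batteries for extraction and refinement, 10,000 Dirichlet
draws for moment checks and 100,000 for the corner-rate check (the
corner rate at α = 0.001 is ≈ 0.991, close to the 0.99 bound, so the
larger sample keeps the Monte Carlo error of the estimate an order of
magnitude below the margin). Dataset precomputation stores per-basis
blends and defers the Dirichlet weighting to load time, so one stored
dataset supports unlimited λ resampling.

## Known limitations

* GrabCut quality degrades when foreground and background colour
  distributions overlap heavily; the certainty bands then mostly
  preserve the network's own decisions.
* The component filter assumes N_i is known per frame, as in a recording
  session; it is not an automatic instrument counter.
* Fixtures are not photorealistic and make no claim of covering real
  tissue/instrument appearance; realism was explicitly not the goal of
  the compositing approach.
* Only binary (tool vs background) labels are supported; video decoding
  and DICOM are out of scope (the pipeline consumes extracted frames).
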