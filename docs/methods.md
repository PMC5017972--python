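# Methods

## Problem and model

Glaucomatous optic neuropathy enlarges the optic cup relative to the optic
disc. The package screens fundus photographs with two independent readers
and a referral rule:

* a **structural** reader that segments cup and disc, fits ellipses to
  their boundaries, and thresholds the area ratio CDR = A_cup / A_disc at
  0.5 (CDR ≤ 0.5 is read as healthy);
* a **non-structural** reader that classifies a texture/intensity feature
  vector of the disc region with PCA + a soft-margin linear SVM;
* a **fusion** rule: agreement keeps the shared label, disagreement — or
  any per-image processing failure — produces `suspect`. Suspects and
  glaucoma calls are referred. The design goal is screening sensitivity:
  a case is missed only when *both* readers independently call it healthy.

## Pipeline stages and their assumptions

**Localization.** The disc is assumed to be (a) among the brightest blobs
at the disc scale and (b) the convergence point of the retinal vessels.
A Laplacian-of-Gaussian filter at sigma = 0.05·min(H, W) (the disc
diameter scales with the frame) is thresholded to keep the brightest 40%
of response pixels; each connected component becomes a candidate anchored
at the response peak inside it (at a 40% keep-rate components can sprawl,
and a component's centroid may leave the disc while its peak does not).
Candidates are ranked purely by vessel density — vessel pixels in a
disc-sized window divided by the *full* window area, so windows
overhanging the frame are penalised rather than renormalised; the best
window within a small search radius of the candidate is used because the
dark vessel trunk displaces the blob peak slightly off the convergence
point. The winning centre is refined to the centroid of the Otsu-bright
region of a vessel-closed local window, then a fixed 155×175 ROI is
cropped (clamped at frame borders). The vessel cue is a black top-hat of
the green plane (flat disk, radius 7 at the large profile) with Otsu
thresholding and an absolute response floor of 0.05 so vessel-free frames
yield an empty map; the detector assumes dark vessels on a brighter
retina and fails by design on contrast-inverted input.

**Cup reader.** Works on the stretched green plane (the cup is most
distinct there). Vessels are erased by a gray-level opening with a
non-flat ball (radius 40 px, height 40/255 on the unit scale) applied to
the negative plane, so erosion removes the bright-in-negative vessels
first. Region growing starts at the global maximum (ties: smallest
(row, col)) and admits a frontier pixel iff its intensity is within 0.025
of the region's running mean *and* of an already-admitted 4-neighbour;
the frontier is scanned in row-major order and the mean updates after
each admission, making the stage fully deterministic. The grown region is
filled with its discrete convex hull, the outer contour is traced, and a
direct ellipse-specific least-squares fit (Fitzgibbon's constraint in the
numerically stable block form) smooths the boundary. Canny on the binary
mask is available but the contour trace is the default: it is bit-stable
and identical up to a pixel.

**Disc reader.** Works on the stretched HSV value plane. Pixels strictly
above the plane's arithmetic mean form the initial mask (the printed
threshold definition leaves pixels equal to the mean unassigned; they go
to background). Vessels crossing the disc cut this mask into fragments;
three passes of small-object removal (< 50 px²) and binary opening (flat
disk, radius 15) remove speckle, fragments whose centroid falls outside
the central half of the ROI are discarded as background (the ROI is
centred on the localized disc by construction), and the convex hull welds
the surviving fragments into the single convex disc region, which is then
ellipse-fitted.

**Feature bank.** Gabor wavelet energies (mean and sd of response
magnitude per scale × orientation; kernel φ = f²/(πγη)·exp(−(f²/γ²·x_r² +
f²/η²·y_r²))·exp(i2πf·x_r)); rotation-invariant uniform LBP (P = 8
neighbours at radius 12, bilinear sampling, s(x) = 1 iff x ≥ 0, histogram
over the P + 2 riu2 codes); Haralick's 14 statistics of a
direction-fused GLCM (displacements [0,Δ], [−Δ,Δ], [−Δ,0], [−Δ,−Δ];
matrices summed, divided by 4, normalised; entropies in bits); colour
moments (per-channel mean, sd, signed cube-root skewness); intensity
auto-correlograms (probability that a pixel at Chebyshev distance exactly
d from a colour-c pixel is also colour c). "Multi-wavelets" appear in the
source feature list without a definition and are implemented as a second
Gabor bank at half the base frequencies — an explicit interpretation.

**Classifier.** Features are standardised with training-fold statistics,
projected onto the leading principal components (default: 95% explained
variance; an explicit k is accepted), and separated by a linear SVM
(C = 1, conventional default). Evaluation is two-fold with stratified,
seeded fold assignment — with 26 positives in 100 images an unstratified
50/50 split can starve a fold of positives. Nothing from the test fold
enters any fit.

## Tunable constants

| constant | default | unit | origin |
|---|---|---|---|
| ROI size | 155 × 175 | px | stated operating point |
| LoG scale | 0.05·min(H, W) | px | chosen; disc scales with frame |
| bright fraction kept | 0.40 | — | stated |
| ball radius / height | 40 / 40/255 | px / unit | stated (8-bit levels) |
| region-grow threshold | 0.025 | unit scale | stated |
| disc opening radius × passes | 15 × 3 | px | stated |
| min object area | 50 | px² | chosen; below any disc fragment |
| CDR threshold | 0.5 | — | stated |
| LBP (P, R) | (8, 12) | — / px | stated |
| GLCM levels, Δ | 64, 1 | — | chosen, literature values |
| Gabor scales × orientations | {0.1, 0.2, 0.3} × 8 | cycles/px | chosen |
| correlogram colours, distances | 64, {1,3,5,7} | — | chosen |
| stretch bounds | 1st/99th percentile | — | chosen, robust |
| SVM C | 1.0 | — | chosen, conventional |
| PCA rule | 95% variance | — | chosen |

Two resolution profiles mirror the published datasets: `large`
(1504×1000) uses the stated constants verbatim; `small` (415×452) scales
the structuring elements by the image diagonal ratio (≈ 0.34 → ball 14,
disk 5) so a fixed 40 px ball does not swallow the proportionally smaller
disc. The ROI stays 155×175 in both profiles, which at the small profile
leaves more background around the disc than the published crops had —
the reason the disc reader discards non-central fragments.

## The synthetic world

The generator renders the cues the pipeline consumes and nothing else: a
bright elliptical disc (structure-plane level ≈ 0.75) containing a
brighter elliptical cup (≈ 0.9) on a textured background (≈ 0.35,
low-frequency noise, sd 0.015), dark quadratic-Bézier vessel strokes
converging on the disc centre that taper from the disc outwards (vessel
caliber peaks at the disc clinically — the very cue the density vote
relies on), a smooth multiplicative illumination gradient (default 10%
corner-to-corner) and additive Gaussian sensor noise (default sd 0.005 of
full scale; the "clean" evaluation profile uses 0). The structure plane
is the green channel; red = 0.25 + 0.75·green ≥ green ≥ blue gives the
fundus-like colour cast and makes the HSV value plane monotone in the
structure. True CDR is the exact area ratio of the stored ellipses; cup
axes are constructed from the disc axes so the requested ratio holds to
machine precision, and the class label is glaucoma iff CDR > 0.5. Cohort
CDRs are uniform on (0.20, 0.45) for healthy and (0.55, 0.85) for
glaucomatous eyes, spanning the clinically reported ranges on either side
of the decision boundary.

What the world does **not** contain — and hence what a green test does
not establish: gradual cup margins (edges are pixel-sharp; an optional
`blur_sigma` softens them and degrades the CDR accuracy measurably),
peripapillary atrophy, exudates and haemorrhages, vessel colour/central
reflex, camera vignetting, and any correlation between disc size and
disease. Results on this world bound the pipeline's geometric
correctness, not its clinical accuracy.

## Numerical choices

* All arithmetic on the unit intensity scale; integers only at file I/O,
  with round-half-up quantisation.
* The ellipse fit centres and isotropically scales the points, solves the
  ellipse-constrained eigenproblem in block form, and maps the conic back;
  the conic is stored with the x² coefficient fixed at 1.
* Reported metrics are truncated (floored) at two decimals, accuracy at
  integer percent — the only convention consistent with the published
  figures (73/74 → 0.98, 65/74 → 0.87).
* Region-growing ties and frontier order are fixed (row-major) so the
  whole structural branch is bit-reproducible; the feature branch is
  deterministic given the fold seed.
* Degenerate inputs fail loudly at module level (constant planes, empty
  masks, sub-5-point boundaries) but map to a `suspect` referral at the
  per-image screening level.

## Known limitations

* The localization invariant (≤ 10 px for ≥ 90% of clean frames) holds on
  the synthetic world; heavily decentred discs interact with ROI clamping
  and are only covered by the fail-safe referral path.
* The ML reader sees a fixed-size ROI, so absolute cup size — not the
  cup/disc ratio — dominates its features; the correlogram block supplies
  disc-scale information, which is why the screening default adds it to
  the published best hybrid (LBP + colour moments).
* CDR is reported in area mode by default; the vertical-diameter mode is
  provided because clinical CDR annotations are conventionally
  diameter-based, and the two are numerically incomparable (area ≈
  diameter² for concentric similar ellipses).
* With sensor noise well above the region-growing threshold (sd ≳ 0.01 of
  full scale) the cup reader under-segments; the threshold is the stated
  operating constant and is exposed in the configuration rather than
  auto-tuned.
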