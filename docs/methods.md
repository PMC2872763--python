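# Methods

## The model and its assumptions

A CT slice is modelled as draws from a Gaussian mixture over the 0–75 HU
analysis window.  Two components carry anatomical meaning: CSF
(N(μ₂, σ₂), mean expected in the 0–21 HU range) and combined white/grey
matter (WGM, N(μ₁, σ₁)).  Pixel intensities are treated as independent
within a tissue — no spatial correlation, no bias field.  A pixel on the
ventricle wall mixes the two tissues: with CSF fraction α its intensity
is z = (1−α)x + αy with x ~ WGM and y ~ CSF independent, which is again
Gaussian with

    μ_g = (1−α)μ₁ + αμ₂,    σ_g = sqrt((1−α)²σ₁² + α²σ₂²).

The ventricle boundary is assumed at most one pixel thick, and the PVE
population is far too small a fraction of the histogram to be fitted as
its own component — which is why the PVE moments are derived from the
fitted CSF/WGM components instead of estimated directly.

Segmentation is two-staged.  Globally, pixels at or below T_PVE = μ_g
(the most probable PVE intensity) are classed CSF; the inclusive
comparison matters because integer HU data sit exactly on thresholds.
Locally, for each background pixel q of the band B (the one-pixel layers
inside and outside the component contour), the CSF share β is solved
from the collinear triple p (CSF, component side), q, r (opposite side):
g(q) = (1−β)g(r) + βg(p), subject to p being CSF and g(q), g(r) > T_PVE
(otherwise β = 0).  q is accepted when its maximum β over the 8 compass
directions reaches α₀.  Taking the maximum gives each pixel its
best-supported share — the "possibility" reading of the decision.  The
image force e(x) = max(α₀·N(x|μ₁,σ₁)/N(μ₁|μ₁,σ₁), β) on B (0 elsewhere)
scores how boundary-like a pixel is and drives the contour smoothing.
The force evaluates the WGM Gaussian as its first branch; a config
switch (`force_distribution="pve"`) substitutes (μ_g, σ_g) for users who
prefer reading that branch as the PVE density.

α₀ is the minimum CSF fraction at which a rater calls a pixel CSF.  From
a ground-truth mask it is estimated by inverting the mean equation on
the mask's boundary pixels (mask pixels with an 8-connected background
neighbor): α₀ = (μ₁ − mean)/(μ₁ − μ₂).  The mean equation is preferred
over the σ_g equation because the sample SD inherits the sample mean's
error.  Without ground truth α₀ = ½.  Estimates outside [0, 1] (noisy or
inconsistent ground truth) are clamped with a warning rather than
rejected.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| analysis window | 0–75 HU | covers CSF and WGM; excludes air, bone, calcifications |
| CSF search range | 0–21 HU | where the CSF component mean must lie |
| mixture components | 3 | CSF, WGM, one absorber for remaining in-window tissue |
| histogram bin width | 1 HU | native resolution of integer HU data |
| α₀ | 0.5 | rater's mixing cutoff when no ground truth is given |
| σ floor | 0.5 HU | EM regularization against single-bin collapse |
| EM stopping | rel. ΔLL < 1e-6, ≤ 500 iter | |
| snake weights | 1 / 1.5 / 1.2 | continuity / curvature / image force |
| snake window, spacing | radius 1 px, 1.5 px | search window and resampling arc length |
| snake stopping | < 5% vertices move, ≤ 200 sweeps | |
| min component area | 50 px | noise-blob filter before refinement |

## Numerical choices

- **EM on the binned histogram.**  The mixture is fitted to bin centers
  weighted by counts, not to raw pixels: with 1-HU bins and integer data
  the two coincide, and the fit cost is independent of image size.
  Initialization is k-means++ seeding on intensities (count-weighted,
  fixed seed); three deterministic restarts are run and the best
  log-likelihood kept, which guards against occasional poor seedings on
  near-unimodal histograms.  Fits are bit-reproducible for a fixed seed.
- **Component identification.**  CSF = lowest-mean component inside the
  CSF range; WGM = highest-weight remaining component above it.  No
  component in range is an error (manual override advised) rather than a
  silent guess.
- **β clamping and degeneracy.**  Raw β outside [0, 1] has no meaning as
  a share and is clamped; the degenerate triple g(r) = g(p) yields β = 0
  (conservative rejection).  β is invariant under a common intensity
  shift of the triple and threshold.
- **Refinement is a single pass** over the original component: accepted
  pixels do not serve as CSF neighbors for further acceptances
  (no cascading); an opt-in flag iterates to a fixed point.  Refinement
  only adds pixels, and only within B, so
  component ⊆ refined ⊆ component ∪ B always holds.
- **Snake.**  Greedy per-vertex window search rather than variational
  descent: deterministic, robust with a discrete force field, and the
  natural host for the three published weights.  Each energy term is
  normalized to [0, 1] within the 3×3 candidate window before weighting,
  otherwise the weights are scale-meaningless; a vertex moves only on a
  strict improvement, so symmetric configurations (a circle under
  uniform force) are fixed points.  Because greedy choice on
  window-normalized terms does not theoretically guarantee descent of
  the raw total energy, each sweep is accepted only if the total energy
  did not increase — an increasing sweep is reverted and iteration
  stops — which makes the recorded energy trace non-increasing by
  construction (in practice the guard almost never fires).
- **Rasterization.**  The smoothed contour is filled by the even-odd
  rule (pixel centers inside or on the polygon); tracing a convex mask
  and rasterizing the trace reproduces the mask exactly.
  Self-intersecting contours are filled the same way with a warning.
- **Edge handling.**  The band B is undefined for components touching
  the image frame; the pipeline skips such components with a warning.
  Triples extending outside the frame skip that direction only.

## The phantom generator

The generator emulates the study conditions the method addresses: a
WGM background N(38, 5) HU, two mirrored elliptical "ventricles" of CSF
N(10, 4) HU (≈ 7 300 interior pixels on the default 256×256 frame), a
one-pixel border whose pixels mix the two tissues, an optional bright
distractor patch N(60, 6) HU so the 3-component fit is exercised, and
integer rounding of intensities as produced by CT reconstruction.

Border mixing fractions come from 8× supersampling of the analytic
geometry (each border pixel's α is its area fraction inside the shape).
The border layer is the set of curve-touched pixels plus every
non-interior pixel 8-adjacent to the interior: this closes the one-pixel
ring, so no pure-CSF pixel is exposed to the background through a
diagonal staircase and ground-truth boundary statistics are computed
over PVE pixels only.  The alternative `border_alpha_model=<float>`
fixes every border α to one value — the generative picture of a rater
whose marked boundary sits exactly at their implicit cutoff, used for
the α₀-recovery experiments.  `gt_at_alpha(α)` returns interior plus
border pixels with mixing ≥ α and is monotone in α by construction.

What the phantom does **not** emulate: skull and bone, beam hardening
and reconstruction-kernel correlation, intensity inhomogeneity, choroid
plexus and calcifications inside the ventricles, slice-thickness PVE in
the through-plane direction, and anatomically realistic ventricle
shapes.  Passing tests on phantoms therefore validate the statistical
machinery — moment formulas, threshold placement, the β decision rule,
energy descent — not clinical performance on real scans.

## Problem sizes used in the checks

The automated checks run the full mechanism at desk scale: 256×256
phantoms (≈ 500–650 border pixels, enough for the α₀ standard error to
sit well inside ±0.05), 10⁶-sample Monte-Carlo verification of the PVE
moments, 100 randomized phantoms for the EM likelihood-monotonicity and
mean-recovery sweep, and 96×96 phantoms for the exhaustive
per-pixel refinement oracle.

## Known limitations

- Strictly per-slice, 2-D; no use of adjacent slices.
- Refinement only grows the mask; a component over-segmented by the
  global threshold is not pruned.
- α₀ recovery inherits the bias of the fitted component means (≈ +0.02
  on the default phantom, where histogram truncation at 0 HU and the
  border population pull the fitted CSF mean slightly up).
- The snake assumes one closed contour per component; topology changes
  are out of scope.
- With nearly equal CSF/WGM means the threshold and β become
  unidentifiable; the code errors rather than guessing.
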