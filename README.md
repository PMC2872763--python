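# ventpve

Segmentation of cerebrospinal fluid (CSF) in the brain ventricles on 2-D
CT slices, built around an explicit model of the **partial volume effect
(PVE)**: a boundary pixel straddling the ventricle wall measures a mixture
of CSF and brain-tissue intensities, so neither a plain global threshold
nor the pixel's own value alone can decide where the boundary is.

The package is for researchers in medical image analysis who need a
transparent, statistically grounded baseline for ventricle extraction in
CT — and a fully synthetic test bed: a phantom generator renders slices
with exact, per-pixel ground truth of the sub-pixel mixing fractions, so
every stage of the method can be validated without clinical data.

## Model

The slice histogram over the 0–75 HU analysis window is a Gaussian
mixture f(x) = Σᵢ πᵢ N(x | μᵢ, σᵢ) fitted by EM (3 components by
default).  Two components are labelled white+grey matter (WGM, μ₁, σ₁)
and CSF (μ₂, σ₂; mean in the standard 0–21 HU CT range for CSF).

A boundary pixel with CSF fraction α has intensity
z = (1−α)·x + α·y with x ~ N(μ₁, σ₁), y ~ N(μ₂, σ₂) independent, hence

```
μ_g = (1−α)·μ₁ + α·μ₂          σ_g = √((1−α)²σ₁² + α²σ₂²)
```

**Stage 1 — global.**  T_PVE = μ_g is the most probable PVE intensity;
pixels not above T_PVE are classed CSF and the ventricle is taken as a
connected component.  α defaults to ½; given an expert ground-truth mask,
the rater's implicit cutoff α₀ is recovered by inverting the mean
equation on the mask's boundary pixels:
α₀ = (μ₁ − mean_boundary) / (μ₁ − μ₂).

**Stage 2 — local.**  In the band B of one-pixel layers inside and
outside the component contour, each outside pixel q is tested along the
8 compass directions using the collinear triple p (CSF), q, r:
g(q) = (1−β)·g(r) + β·g(p).  If the best-supported share β reaches α₀,
q joins the ventricle.  The same analysis defines an image force
e(x) ∈ [0, 1] on B, and a greedy active contour (weights: continuity 1,
curvature 1.5, image force 1.2) smooths the pixelwise boundary into an
anatomically plausible curve.

## Worked example

`python examples/full_pipeline.py` segments the default 256×256 phantom
(two mirrored elliptical ventricles, CSF N(10, 4) HU on a WGM N(38, 5) HU
background, plus a small bright distractor patch):

```
pixels in 0-75 HU window: 65493
mixture components (weight, mean HU, sigma HU):
  0.115   10.71   4.04
  0.840   38.48   5.06
  0.045   60.60   5.97
T_PVE = 24.60 HU at alpha0 = 0.5
threshold mask: 7825 px
ventricle 0: 3810 px, +47 added by local refinement, snake 2 iterations
ventricle 1: 3802 px, +40 added by local refinement, snake 1 iterations
Dice vs ground truth: refined 0.9926, smoothed 0.9861
```

The EM fit recovers the three generative tissue Gaussians from the
histogram alone; T_PVE ≈ 24.6 HU is the midpoint of the recovered CSF and
WGM means (α = ½); local refinement adds the boundary pixels whose
neighborhood triples imply a CSF share ≥ ½; and the final masks overlap
the generative ground truth at Dice ≈ 0.99.

Other walkthroughs: `examples/pve_threshold.py` (closed-form PVE moments
and the two profile-calibration shares), `examples/phantom_alpha0.py`
(recovering a rater's implicit cutoff α₀ = 0.6 from their mask), and
`examples/snake_smoothing.py` (energy descent of the greedy snake).

A thin CLI mirrors the stages: `ventpve fit-gmm | estimate-alpha |
segment | smooth | phantom | run` (see `ventpve --help`).

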