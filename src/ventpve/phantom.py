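"""Synthetic CT phantoms with controlled sub-pixel border mixing.

A phantom emulates one axial slice around the lateral ventricles: a
white/grey-matter background ~ N(mu1, sigma1), a CSF interior ~
N(mu2, sigma2), and a one-pixel border whose pixels are linear mixtures
(1-alpha)*x + alpha*y of independent WGM and CSF draws.  Per-pixel border
fractions come either from area-weighted supersampling of the analytic
geometry (each border pixel's alpha is the fraction of its area inside
the shape, sampled on an 8x8 subgrid) or are fixed to one value, which
emulates a rater whose marked boundary sits exactly at their implicit
mixing cutoff.

The exact ground truth is kept alongside the rendered slice, so every
pipeline stage can be scored without clinical data.  An optional
"distractor" patch of a third tissue-like Gaussian exercises the
3-component mixture fit beyond a 2-class toy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import GaussianParams, ImageSlice

_SUPERSAMPLE = 8  # subpixels per axis for area-fraction rendering


@dataclass
class PhantomSpec:
    """Geometry, tissue statistics, and rendering options of a phantom.

    Defaults place two mirrored vertical ellipses (lateral-ventricle
    stand-ins) at the slice center, CSF at N(10, 4) HU and WGM at
    N(38, 5) HU -- inside the 0-75 HU analysis window, with the CSF mean
    in the standard 0-21 HU CT range.
    """

    shape: tuple[int, int] = (256, 256)
    csf: GaussianParams = field(default_factory=lambda: GaussianParams(10.0, 4.0))
    wgm: GaussianParams = field(default_factory=lambda: GaussianParams(38.0, 5.0))
    geometry: str = "two_ellipses"  # "ellipse" | "two_ellipses" | "crescents"
    semi_axes: tuple[float, float] = (55.0, 22.0)  # (row, col) semi-axes
    separation: float | None = None  # center column offset; default w/8
    border_alpha_model: str | float = "supersample"  # or a fixed alpha in [0,1]
    include_distractor: bool = True
    distractor: GaussianParams = field(default_factory=lambda: GaussianParams(60.0, 6.0))
    round_to_int: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.csf.mu < self.wgm.mu:
            raise ValueError("phantom requires csf.mu < wgm.mu")
        for m in (self.csf.mu, self.wgm.mu):
            if not 0.0 <= m <= 75.0:
                raise ValueError("tissue means must lie inside [0, 75] HU")
        if isinstance(self.border_alpha_model, (int, float)):
            if not 0.0 <= float(self.border_alpha_model) <= 1.0:
                raise ValueError("fixed border alpha must be in [0, 1]")


@dataclass
class PhantomOutput:
    """Rendered slice plus exact ground truth."""

    slice: ImageSlice
    gt_interior: np.ndarray  # pure-CSF pixels
    border_mask: np.ndarray  # one-pixel mixing border
    border_alpha: np.ndarray  # per-pixel true CSF fraction (0 off-border)
    distractor_mask: np.ndarray
    spec: PhantomSpec

    def gt_at_alpha(self, alpha: float) -> np.ndarray:
        """Interior plus border pixels whose mixing fraction is >= alpha.

        Monotone in alpha: raising the cutoff can only shrink the mask.
        """
        return self.gt_interior | (self.border_mask & (self.border_alpha >= alpha))

    @property
    def n_border_pixels(self) -> int:
        return int(self.border_mask.sum())


def _inside(spec: PhantomSpec, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Analytic indicator of the CSF region at float (row, col) coordinates."""
    h, w = spec.shape
    a, b = spec.semi_axes
    cy = (h - 1) / 2.0
    cx = (w - 1) / 2.0
    sep = spec.separation if spec.separation is not None else w / 8.0

    def ellipse(y0, x0, ay, bx):
        return ((rr - y0) / ay) ** 2 + ((cc - x0) / bx) ** 2 <= 1.0

    if spec.geometry == "ellipse":
        return ellipse(cy, cx, a, b)
    if spec.geometry == "two_ellipses":
        return ellipse(cy, cx - sep, a, b) | ellipse(cy, cx + sep, a, b)
    if spec.geometry == "crescents":
        # each crescent: ellipse minus a copy shifted toward the midline
        left = ellipse(cy, cx - sep, a, b) & ~ellipse(cy, cx - sep + 0.8 * b, a, b)
        right = ellipse(cy, cx + sep, a, b) & ~ellipse(cy, cx + sep - 0.8 * b, a, b)
        return left | right
    raise ValueError(f"unknown geometry {spec.geometry!r}")


def _area_fractions(spec: PhantomSpec) -> np.ndarray:
    """Per-pixel CSF area fraction from 8x8 supersampling of the geometry."""
    h, w = spec.shape
    s = _SUPERSAMPLE
    sub = (np.arange(s) + 0.5) / s - 0.5
    rows = (np.arange(h)[:, None] + sub[None, :]).ravel()  # h*s subpixel rows
    cols = (np.arange(w)[:, None] + sub[None, :]).ravel()  # w*s subpixel cols
    inside = _inside(spec, rows[:, None], cols[None, :]).astype(float)
    return inside.reshape(h, s, w, s).mean(axis=(1, 3))


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomOutput:
    """Render a phantom slice with its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises if the geometry comes
    within 2 pixels of the frame edge.
    """
    spec = spec or PhantomSpec()
    h, w = spec.shape
    alpha = _area_fractions(spec)

    touched = alpha > 0
    if (
        touched[:2, :].any()
        or touched[-2:, :].any()
        or touched[:, :2].any()
        or touched[:, -2:].any()
    ):
        raise ValueError("geometry must fit strictly inside the frame (2 px margin)")

    interior = alpha >= 1.0
    # the PVE layer: curve-touched pixels plus any non-interior pixel
    # 8-adjacent to the interior, so the one-pixel ring is 8-closed and
    # no pure-CSF pixel is exposed to the background
    from scipy import ndimage

    ring = ndimage.binary_dilation(interior, structure=np.ones((3, 3), bool)) & ~interior
    border = (touched & ~interior) | ring
    if isinstance(spec.border_alpha_model, (int, float)):
        alpha = np.where(border, float(spec.border_alpha_model), alpha)
    elif spec.border_alpha_model != "supersample":
        raise ValueError(f"unknown border_alpha_model {spec.border_alpha_model!r}")
    border_alpha = np.where(border, alpha, 0.0)

    rng = np.random.default_rng(spec.seed)
    img = rng.normal(spec.wgm.mu, spec.wgm.sigma, size=(h, w))
    img[interior] = rng.normal(spec.csf.mu, spec.csf.sigma, size=int(interior.sum()))
    nb = int(border.sum())
    x = rng.normal(spec.wgm.mu, spec.wgm.sigma, size=nb)  # WGM share
    y = rng.normal(spec.csf.mu, spec.csf.sigma, size=nb)  # CSF share
    a = border_alpha[border]
    img[border] = (1.0 - a) * x + a * y

    distractor_mask = np.zeros((h, w), dtype=bool)
    if spec.include_distractor:
        r0, r1 = int(0.05 * h), int(0.20 * h)
        c0, c1 = int(0.05 * w), int(0.35 * w)
        distractor_mask[r0:r1, c0:c1] = True
        distractor_mask &= ~touched  # never overwrite the ventricle
        img[distractor_mask] = rng.normal(
            spec.distractor.mu, spec.distractor.sigma, size=int(distractor_mask.sum())
        )

    if spec.round_to_int:
        img = np.rint(img)
    return PhantomOutput(
        slice=ImageSlice(pixels=img),
        gt_interior=interior,
        border_mask=border,
        border_alpha=border_alpha,
        distractor_mask=distractor_mask,
        spec=spec,
    )


@dataclass(frozen=True)
class SegmentationScore:
    dice: float
    added_correct: int
    added_wrong: int


def score_segmentation(
    pred: np.ndarray, gt: np.ndarray, base: np.ndarray | None = None
) -> SegmentationScore:
    """Dice overlap of a predicted mask against ground truth.

    With ``base`` given (e.g. the pre-refinement component), the pixels
    ``pred & ~base`` added by refinement are book-kept against the ground
    truth as correct or wrong additions.  Two empty masks score Dice 1
    with a warning.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("masks must share a raster")
    denom = int(pred.sum()) + int(gt.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
        dice = 1.0
    else:
        dice = 2.0 * int((pred & gt).sum()) / denom
    added_correct = added_wrong = 0
    if base is not None:
        added = pred & ~np.asarray(base, dtype=bool)
        added_correct = int((added & gt).sum())
        added_wrong = int((added & ~gt).sum())
    return SegmentationScore(dice=float(dice), added_correct=added_correct, added_wrong=added_wrong)
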