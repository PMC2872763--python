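"""End-to-end two-stage segmentation pipeline.

histogram -> GMM fit -> CSF/WGM identification -> PVE distribution ->
global threshold -> connected components -> band B -> local beta
refinement -> contour tracing -> snake smoothing.  Each ventricle-sized
component is refined and smoothed independently; the final mask is their
union.  All stage counts and fitted parameters land in a JSON-ready
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from . import gmm, pve, segmentation, snake
from .phantom import score_segmentation
from .types import GaussianParams, ImageSlice


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    ``alpha0`` may be a fraction, or ``"auto"`` to estimate the rater's
    mixing cutoff from a supplied ground-truth mask.
    ``force_distribution`` selects the Gaussian used in the image force:
    the WGM component as printed in the model, or the PVE mixture.
    """

    hu_min: float = 0.0
    hu_max: float = 75.0
    bin_width: float = 1.0
    csf_hu_range: tuple[float, float] = (0.0, 21.0)
    n_components: int = 3
    alpha0: float | str = pve.DEFAULT_ALPHA0
    snake: snake.SnakeConfig = field(default_factory=snake.SnakeConfig)
    seed: int = 0
    min_component_area: int = 50  # pixels; smaller blobs are noise
    iterate_refinement: bool = False
    force_distribution: str = "wgm"  # "wgm" | "pve"

    def __post_init__(self) -> None:
        if not self.hu_min < self.hu_max:
            raise ValueError("hu_min must be less than hu_max")
        lo, hi = self.csf_hu_range
        if not (self.hu_min <= lo < hi <= self.hu_max):
            raise ValueError("csf_hu_range must lie inside the analysis window")
        if self.force_distribution not in ("wgm", "pve"):
            raise ValueError("force_distribution must be 'wgm' or 'pve'")


@dataclass
class PipelineResult:
    report: dict
    threshold_mask: np.ndarray
    refined_mask: np.ndarray
    smoothed_mask: np.ndarray
    force_field: np.ndarray
    contours: list[snake.Contour]
    model: pve.PVEModel
    fit: gmm.GMMFit
    decisions: list[segmentation.LocalDecision]


def _candidate_components(mask: np.ndarray, min_area: int) -> list[np.ndarray]:
    """Ventricle-sized 8-connected components, largest first.

    Components touching the image edge are skipped (the band B is
    undefined there) with a warning.
    """
    labels = label(mask, connectivity=2)
    h, w = mask.shape
    out = []
    for region in sorted(regionprops(labels), key=lambda r: -r.area):
        if region.area < min_area:
            continue
        rmin, cmin, rmax, cmax = region.bbox
        if rmin == 0 or cmin == 0 or rmax == h or cmax == w:
            warnings.warn(
                f"component of area {region.area} touches the image edge; skipped",
                stacklevel=2,
            )
            continue
        out.append(labels == region.label)
    return out


def run_pipeline(
    config: PipelineConfig,
    image: ImageSlice,
    gt_mask: np.ndarray | None = None,
) -> PipelineResult:
    """Run the two-stage segmentation on one slice.

    With ``gt_mask`` given, the report includes Dice of the refined and
    smoothed masks against it; with ``alpha0="auto"`` the mask also
    calibrates the mixing cutoff.
    """
    report: dict = {"seed": config.seed}

    hist = gmm.build_histogram(image, config.hu_min, config.hu_max, config.bin_width)
    report["n_pixels_in_window"] = hist.n_pixels

    fit = gmm.fit_gmm_em(hist, n_components=config.n_components, seed=config.seed)
    report["gmm"] = fit.to_dict()

    tissues = gmm.identify_tissue_components(fit, config.csf_hu_range)

    if config.alpha0 == "auto":
        if gt_mask is None:
            raise ValueError('alpha0="auto" requires a ground-truth mask')
        boundary_mean = pve.gt_boundary_intensity_mean(image, gt_mask)
        alpha0 = pve.estimate_alpha0(boundary_mean, tissues.csf, tissues.wgm)
        report["gt_boundary_mean"] = boundary_mean
    else:
        alpha0 = float(config.alpha0)
    report["alpha0"] = alpha0

    model = pve.PVEModel.from_components(tissues.csf, tissues.wgm, alpha0)
    report["pve"] = model.to_dict()
    t = pve.global_threshold(model)

    threshold_mask = segmentation.threshold_csf(image, t)
    report["n_threshold"] = int(threshold_mask.sum())

    force_gauss: GaussianParams = model.wgm if config.force_distribution == "wgm" else model.pve

    components = _candidate_components(threshold_mask, config.min_component_area)
    if not components:
        raise RuntimeError("segmentation: no ventricle-sized component found")

    refined_mask = np.zeros(image.shape, dtype=bool)
    smoothed_mask = np.zeros(image.shape, dtype=bool)
    force_field = np.zeros(image.shape)
    contours: list[snake.Contour] = []
    decisions: list[segmentation.LocalDecision] = []
    per_component = []
    for comp in components:
        res = segmentation.refine_boundary(
            image, comp, t, alpha0, force_gauss, iterate=config.iterate_refinement
        )
        traced = snake.trace_contour(res.refined)
        smooth = snake.snake_smooth(traced, res.force_field, config.snake)
        raster = snake.rasterize_contour(smooth.contour, image.shape)
        refined_mask |= res.refined
        smoothed_mask |= raster
        force_field = np.maximum(force_field, res.force_field)
        contours.append(smooth.contour)
        decisions.extend(res.decisions)
        per_component.append(
            {
                "n_component": int(comp.sum()),
                "n_band": int(res.band.member.sum()),
                "n_refined": int(res.refined.sum()),
                "n_added": int(res.refined.sum()) - int(comp.sum()),
                "snake_iterations": smooth.n_iter,
                "snake_converged": smooth.converged,
            }
        )
    report["components"] = per_component
    report["n_refined"] = int(refined_mask.sum())
    report["n_smoothed"] = int(smoothed_mask.sum())

    if gt_mask is not None:
        report["dice_refined"] = score_segmentation(refined_mask, gt_mask).dice
        report["dice_smoothed"] = score_segmentation(smoothed_mask, gt_mask).dice

    return PipelineResult(
        report=report,
        threshold_mask=threshold_mask,
        refined_mask=refined_mask,
        smoothed_mask=smoothed_mask,
        force_field=force_field,
        contours=contours,
        model=model,
        fit=fit,
        decisions=decisions,
    )
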