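"""Global thresholding and local boundary refinement of the ventricle mask.

Stage one classifies every pixel at or below T_PVE as CSF and extracts the
ventricle as an 8-connected component.  Stage two inspects the band B --
the one-pixel layers just inside and outside the component contour -- and
decides, per outside pixel q, whether its intensity is consistent with
carrying at least an alpha0 share of CSF.  The share beta is solved from
three consecutive collinear pixels p (CSF, on the contour), q, r along one
of the 8 compass directions:

    g(q) = (1-beta)*g(r) + beta*g(p)   =>   beta = (g(r)-g(q)) / (g(r)-g(p))

q joins the ventricle when its best beta over the 8 directions reaches
alpha0.  The same pass produces the image force e(x) on B that later
drives the snake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from .types import GaussianParams, ImageSlice

_FOOTPRINT8 = np.ones((3, 3), dtype=bool)

# 8 compass directions as (drow, dcol), clockwise from north
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
DIRECTION_NAMES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def threshold_csf(image: ImageSlice, t_pve: float) -> np.ndarray:
    """Binary CSF mask: pixel is CSF iff intensity is not above T_PVE."""
    return image.pixels <= t_pve


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one in-frame 8-connected background neighbor."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FOOTPRINT8, border_value=1)
    return mask & ~eroded


def extract_ventricle_component(
    mask: np.ndarray, seed: tuple[int, int] | None = None
) -> np.ndarray:
    """Select a single 8-connected component of the CSF mask.

    With a ``seed`` pixel, the component containing it; otherwise the
    largest component whose centroid lies in the central third of the
    frame (ventricles are central anatomy).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labels = label(mask, connectivity=2)
    if seed is not None:
        r, c = seed
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            raise ValueError(f"seed pixel {seed} is not on a mask pixel")
        return labels == labels[r, c]
    h, w = mask.shape
    best_label, best_area = None, -1
    for region in regionprops(labels):
        cr, cc = region.centroid
        if h / 3 <= cr <= 2 * h / 3 and w / 3 <= cc <= 2 * w / 3:
            if region.area > best_area:
                best_label, best_area = region.label, region.area
    if best_label is None:
        raise ValueError(
            "no connected component with centroid in the central third of "
            "the frame; pass an explicit seed pixel"
        )
    return labels == best_label


@dataclass
class BoundaryBand:
    """The band B: one-pixel layers inside and outside a component contour.

    ``contour`` is the inner layer (component pixels with a background
    8-neighbor), ``outer`` the background pixels 8-adjacent to the
    component, and ``member = contour | outer``.
    """

    member: np.ndarray
    contour: np.ndarray
    outer: np.ndarray


def boundary_band(component: np.ndarray) -> BoundaryBand:
    """Build the band B around an 8-connected component.

    The component must lie strictly inside the image frame (the outer
    layer is undefined at the edge).
    """
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("component is empty")
    if (
        component[0, :].any()
        or component[-1, :].any()
        or component[:, 0].any()
        or component[:, -1].any()
    ):
        raise ValueError("component touches the image edge; band undefined there")
    dilated = ndimage.binary_dilation(component, structure=_FOOTPRINT8)
    inner = component & ndimage.binary_dilation(~component, structure=_FOOTPRINT8)
    outer = dilated & ~component
    return BoundaryBand(member=inner | outer, contour=inner, outer=outer)


def beta_share(
    gp: float, gq: float, gr: float, t_pve: float, p_is_csf_in_b: bool
) -> float:
    """CSF mixing share of q solved from the collinear triple (p, q, r).

    Requires p to be a CSF pixel of B while q and r are above T_PVE;
    otherwise (or on the degenerate triple g(r) == g(p), where the share
    is unidentifiable) the share is 0.  The raw solution is clamped to
    [0, 1]: values outside arise from noise and have no meaning as a
    share.
    """
    if not (p_is_csf_in_b and gq > t_pve and gr > t_pve):
        return 0.0
    denom = gr - gp
    if denom == 0:
        return 0.0
    return float(min(max((gr - gq) / denom, 0.0), 1.0))


def image_force(
    x: float,
    in_b: bool,
    beta: float,
    alpha0: float,
    wgm: GaussianParams,
) -> float:
    """Image force e(x) in [0, 1]; higher means more probably on the boundary.

    Zero outside B; inside, the larger of the WGM Gaussian density peak-
    normalized to [0, alpha0] (how PVE-like the intensity is) and the
    locally solved CSF share beta.
    """
    if not in_b:
        return 0.0
    if not 0.0 <= alpha0 <= 1.0:
        raise ValueError("alpha0 must be in [0, 1]")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    return float(max(alpha0 * wgm.peak_normalized(x), beta))


@dataclass(frozen=True)
class LocalDecision:
    """Outcome of the beta test at one band pixel."""

    pixel: tuple[int, int]
    beta: float
    direction: str  # compass name of the best-supported direction
    accepted: bool
    force: float


@dataclass
class RefinementResult:
    refined: np.ndarray
    decisions: list[LocalDecision]
    force_field: np.ndarray
    band: BoundaryBand


def refine_boundary(
    image: ImageSlice,
    component: np.ndarray,
    t_pve: float,
    alpha0: float,
    wgm: GaussianParams,
    iterate: bool = False,
) -> RefinementResult:
    """Second-stage local refinement of the component boundary.

    For each non-CSF pixel q of the band B, the triple (p, q, r) is formed
    in each of the 8 directions with p the neighbor on the component side
    and r the diametrically opposite neighbor; q is added to the mask when
    its maximal beta over directions reaches alpha0.  A single pass over
    the original component by default (``iterate=True`` repeats until no
    pixel is added).  Directions whose triple leaves the frame are
    skipped.

    Returns the refined mask, the per-pixel decisions, and the force field
    e(x) over B (zero elsewhere).
    """
    component = np.asarray(component, dtype=bool)
    px = image.pixels
    h, w = px.shape
    refined = component.copy()

    while True:
        band = boundary_band(refined)
        beta_max = np.zeros((h, w))
        decisions: list[LocalDecision] = []
        added = []
        for r0, c0 in zip(*np.nonzero(band.outer)):
            best_beta, best_dir = 0.0, DIRECTION_NAMES[0]
            for (dr, dc), name in zip(DIRECTIONS, DIRECTION_NAMES):
                pr, pc = r0 + dr, c0 + dc
                rr, rc = r0 - dr, c0 - dc
                if not (0 <= pr < h and 0 <= pc < w and 0 <= rr < h and 0 <= rc < w):
                    continue
                b = beta_share(
                    px[pr, pc], px[r0, c0], px[rr, rc], t_pve, bool(refined[pr, pc])
                )
                if b > best_beta:
                    best_beta, best_dir = b, name
            beta_max[r0, c0] = best_beta
            accepted = best_beta >= alpha0
            if accepted:
                added.append((r0, c0))
            decisions.append(
                LocalDecision(
                    pixel=(int(r0), int(c0)),
                    beta=best_beta,
                    direction=best_dir,
                    accepted=accepted,
                    force=image_force(px[r0, c0], True, best_beta, alpha0, wgm),
                )
            )
        if not iterate or not added:
            break
        for r0, c0 in added:
            refined[r0, c0] = True

    force_field = np.where(
        band.member,
        np.maximum(alpha0 * wgm.peak_normalized(px), beta_max),
        0.0,
    )
    for r0, c0 in added:
        refined[r0, c0] = True
    return RefinementResult(
        refined=refined, decisions=decisions, force_field=force_field, band=band
    )
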