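"""Partial-volume-effect mixture model and the global CSF threshold.

A boundary pixel containing a fraction ``alpha`` of CSF and ``1 - alpha``
of white/grey matter has intensity z = (1-alpha)*x + alpha*y with
x ~ N(mu1, sigma1) (WGM) and y ~ N(mu2, sigma2) (CSF) independent, hence

    mu_g    = (1-alpha)*mu1 + alpha*mu2
    sigma_g = sqrt((1-alpha)^2 sigma1^2 + alpha^2 sigma2^2)

The most probable PVE intensity mu_g is used as the global threshold
T_PVE: a pixel is classed CSF iff its intensity is not above T_PVE.

``alpha0`` is the minimum CSF fraction at which a rater calls a pixel CSF.
It is recovered from an expert ground-truth mask by inverting the mean
equation on the mask's boundary pixels; without ground truth the neutral
convention alpha0 = 1/2 is used.

The module also carries two calibration analytics relating classical
vessel-profile thresholding rules to background share under the same
linear-mixing model: the equal-area-rectangle fit (cutoff mu +/- sigma *
sqrt(pi/2), i.e. a ~10.5% one-sided Gaussian tail) and the full width at
half maximum (50% background share at the cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .types import GaussianParams, ImageSlice

DEFAULT_ALPHA0 = 0.5


def pve_distribution(
    csf: GaussianParams, wgm: GaussianParams, alpha: float
) -> GaussianParams:
    """Gaussian of the linear mixture (1-alpha)*WGM + alpha*CSF.

    ``alpha`` is the CSF fraction of the pixel, in [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    mu = (1.0 - alpha) * wgm.mu + alpha * csf.mu
    sigma = np.sqrt((1.0 - alpha) ** 2 * wgm.sigma**2 + alpha**2 * csf.sigma**2)
    return GaussianParams(float(mu), float(sigma))


@dataclass(frozen=True)
class PVEModel:
    """CSF/WGM components, the mixing fraction, and the derived threshold."""

    csf: GaussianParams  # mu2, sigma2
    wgm: GaussianParams  # mu1, sigma1
    alpha: float
    pve: GaussianParams  # mu_g, sigma_g

    @property
    def t_pve(self) -> float:
        """Global threshold: the most probable PVE intensity mu_g."""
        return self.pve.mu

    @classmethod
    def from_components(
        cls, csf: GaussianParams, wgm: GaussianParams, alpha: float = DEFAULT_ALPHA0
    ) -> "PVEModel":
        return cls(csf=csf, wgm=wgm, alpha=float(alpha),
                   pve=pve_distribution(csf, wgm, alpha))

    def to_dict(self) -> dict:
        return {
            "csf": {"mu": self.csf.mu, "sigma": self.csf.sigma},
            "wgm": {"mu": self.wgm.mu, "sigma": self.wgm.sigma},
            "alpha": self.alpha,
            "pve": {"mu": self.pve.mu, "sigma": self.pve.sigma},
            "t_pve": self.t_pve,
        }


def global_threshold(model: PVEModel) -> float:
    """T_PVE = mu_g.  Classification contract: CSF iff intensity <= T_PVE."""
    return model.t_pve


def estimate_alpha0(
    gt_boundary_mean: float, csf: GaussianParams, wgm: GaussianParams
) -> float:
    """Invert the PVE mean equation for the rater's mixing cutoff.

    alpha0 = (mu1 - mean) / (mu1 - mu2) where ``mean`` is the average
    intensity over the ground-truth boundary pixels.  The mean equation is
    preferred over the variance one because the sample SD compounds the
    error of the sample mean.  Estimates outside [0, 1] (possible with
    noisy ground truth) are clamped with a warning.
    """
    denom = wgm.mu - csf.mu
    if denom == 0:
        raise ValueError("csf.mu == wgm.mu: alpha0 is unidentifiable")
    alpha0 = (wgm.mu - gt_boundary_mean) / denom
    if not 0.0 <= alpha0 <= 1.0:
        warnings.warn(
            f"alpha0 estimate {alpha0:.3f} outside [0, 1]; clamping",
            stacklevel=2,
        )
        alpha0 = min(max(alpha0, 0.0), 1.0)
    return float(alpha0)


def gt_boundary_intensity_mean(image: ImageSlice, gt_mask: np.ndarray) -> float:
    """Mean slice intensity over the ground-truth mask's boundary pixels.

    Boundary pixels are mask pixels with at least one 8-connected
    background neighbor inside the frame (pixels beyond the frame are not
    treated as background, so a mask covering the whole image has no
    boundary and raises).
    """
    from .segmentation import mask_contour  # local import: no cycle at runtime

    gt_mask = np.asarray(gt_mask, dtype=bool)
    if gt_mask.shape != image.shape:
        raise ValueError("ground-truth mask raster does not match the slice")
    if not gt_mask.any():
        raise ValueError("ground-truth mask is empty")
    contour = mask_contour(gt_mask)
    if not contour.any():
        raise ValueError("mask covers the entire image: no boundary pixels")
    return float(image.pixels[contour].mean())


def rectangle_fit_tail_share() -> float:
    """Background tail (percent) beyond the equal-area-rectangle cutoff.

    Fitting a rectangle of equal area to a unit-peak Gaussian profile
    gives half-width sigma*sqrt(pi/2); the one-sided standard-normal tail
    mass beyond sqrt(pi/2) is ~10.5%.
    """
    return float(100.0 * norm.sf(np.sqrt(np.pi / 2.0)))


def fwhm_background_share(peak_fraction: float = 0.5) -> float:
    """Background share (percent) at a given fraction of the profile peak.

    Under linear mixing value = (1-b)*peak + b*background with background
    level 0, a profile point at ``peak_fraction`` of the maximum carries a
    background share b = 1 - peak_fraction.  The full-width-at-half-maximum
    cutoff (``peak_fraction=0.5``) therefore admits up to 50% background.
    """
    if not 0.0 <= peak_fraction <= 1.0:
        raise ValueError("peak_fraction must be in [0, 1]")
    return float(100.0 * (1.0 - peak_fraction))
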