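"""Histogram construction and Gaussian-mixture fitting of CT tissue intensities.

The slice histogram over the HU analysis window (default 0-75 HU, covering
cerebrospinal fluid and combined white/grey matter) is modelled as a mixture
of Gaussians f(x) = sum_i pi_i N(x | mu_i, sigma_i) fitted by
expectation-maximization.  The EM runs on the binned histogram with per-bin
count weights rather than on raw pixels; with integer HU data and 1-HU bins
the two are equivalent up to half-bin rounding, and the binned fit is
independent of image size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .types import GaussianParams, GMMFit, Histogram, ImageSlice

# Regularization floor for component standard deviations (HU).  Integer-valued
# HU data can otherwise collapse a component onto a single bin.
SIGMA_FLOOR = 0.5


def build_histogram(
    image: ImageSlice,
    hu_min: float = 0.0,
    hu_max: float = 75.0,
    bin_width: float = 1.0,
) -> Histogram:
    """Histogram of slice intensities restricted to ``[hu_min, hu_max]``.

    Pixels outside the window are excluded, not clipped.  Raises
    ``ValueError`` when no pixel falls inside the window.
    """
    if not hu_min < hu_max:
        raise ValueError("hu_min must be less than hu_max")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    values = image.pixels[(image.pixels >= hu_min) & (image.pixels <= hu_max)]
    if values.size == 0:
        raise ValueError(
            f"no pixels in the analysis window [{hu_min}, {hu_max}] HU"
        )
    n_bins = int(np.ceil((hu_max - hu_min) / bin_width))
    edges = hu_min + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hu_max)  # last edge covers the window exactly
    counts, _ = np.histogram(values, bins=edges)
    return Histogram(bin_edges=edges, counts=counts, hu_min=hu_min, hu_max=hu_max)


def _as_weighted_sample(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, Histogram):
        keep = data.counts > 0
        return data.centers[keep], data.counts[keep].astype(float)
    values = np.asarray(data, dtype=float).ravel()
    return values, np.ones_like(values)


def _log_gauss(x: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """(n_components, n_points) matrix of log N(x | mu_i, sigma_i)."""
    z = (x[None, :] - means[:, None]) / sigmas[:, None]
    return -0.5 * z * z - np.log(sigmas[:, None]) - 0.5 * np.log(2.0 * np.pi)


def _em_once(
    values: np.ndarray,
    weights: np.ndarray,
    n_components: int,
    tol: float,
    max_iter: int,
    seed: int,
    sigma_floor: float,
) -> GMMFit:
    total = weights.sum()
    # k-means++ seeding on intensities, count-weighted, deterministic per seed
    centers, _ = kmeans_plusplus(
        values.reshape(-1, 1),
        n_clusters=n_components,
        sample_weight=weights,
        random_state=seed,
    )
    means = np.sort(centers.ravel())
    global_std = np.sqrt(np.average((values - np.average(values, weights=weights)) ** 2, weights=weights))
    global_std = max(global_std, sigma_floor)

    # hard-assignment initial moments
    assign = np.argmin(np.abs(values[None, :] - means[:, None]), axis=0)
    sigmas = np.empty(n_components)
    pis = np.empty(n_components)
    for i in range(n_components):
        w_i = weights[assign == i]
        v_i = values[assign == i]
        if w_i.sum() <= 0:
            pis[i] = 1.0 / n_components
            sigmas[i] = global_std
            continue
        pis[i] = w_i.sum() / total
        m = np.average(v_i, weights=w_i)
        sigmas[i] = max(np.sqrt(np.average((v_i - m) ** 2, weights=w_i)), sigma_floor)
    pis = pis / pis.sum()

    trace = []
    degenerate = False
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_comp = _log_gauss(values, means, sigmas) + np.log(pis)[:, None]
        log_mix = logsumexp(log_comp, axis=0)
        ll = float(np.dot(weights, log_mix))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        resp = np.exp(log_comp - log_mix[None, :])  # responsibilities
        wr = resp * weights[None, :]
        mass = wr.sum(axis=1)
        mass = np.maximum(mass, 1e-300)
        pis = mass / total
        means = wr @ values / mass
        var = (wr * (values[None, :] - means[:, None]) ** 2).sum(axis=1) / mass
        sigmas = np.sqrt(var)
        if np.any(sigmas < sigma_floor):
            degenerate = True
            sigmas = np.maximum(sigmas, sigma_floor)
    return GMMFit(
        weights=pis,
        means=means,
        sigmas=sigmas,
        log_likelihood_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        degenerate=degenerate,
    )


def fit_gmm_em(
    data,
    n_components: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_init: int = 3,
    sigma_floor: float = SIGMA_FLOOR,
) -> GMMFit:
    """Fit an ``n_components`` Gaussian mixture by EM.

    Parameters
    ----------
    data
        A :class:`~ventpve.types.Histogram` (fitted with per-bin count
        weights) or a 1-D array of raw intensities.
    n_components
        Number of mixture components (default 3: CSF, white/grey matter,
        and a third component absorbing remaining tissue).
    tol
        Relative log-likelihood change below which EM stops.
    seed
        Seeds the k-means++ initialization; fits are bit-reproducible for a
        fixed seed.
    n_init
        Number of deterministic restarts (seeds ``seed .. seed+n_init-1``);
        the fit with the best final log-likelihood is returned.

    Components whose standard deviation collapses below ``sigma_floor`` are
    clamped and the fit is flagged ``degenerate``.  If EM has not converged
    at ``max_iter`` the best fit so far is returned with ``converged=False``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    values, weights = _as_weighted_sample(data)
    if np.unique(values).size < n_components:
        raise ValueError(
            f"need at least {n_components} distinct intensity values, "
            f"got {np.unique(values).size}"
        )
    best: GMMFit | None = None
    for k in range(max(1, n_init)):
        fit = _em_once(values, weights, n_components, tol, max_iter, seed + k, sigma_floor)
        if best is None or fit.log_likelihood_trace[-1] > best.log_likelihood_trace[-1]:
            best = fit
    return best


@dataclass(frozen=True)
class TissueComponents:
    """CSF and WGM components identified in a mixture fit, with indices."""

    csf: GaussianParams
    wgm: GaussianParams
    csf_index: int
    wgm_index: int


def identify_tissue_components(
    fit: GMMFit, csf_hu_range: tuple[float, float] = (0.0, 21.0)
) -> TissueComponents:
    """Label the CSF and WGM components of a fitted mixture.

    CSF is the component whose mean lies inside ``csf_hu_range`` (the
    standard CSF window in CT is roughly 0-21 HU); on multiple candidates
    the lowest mean wins.  WGM is the highest-weight remaining component
    with mean above the CSF mean.
    """
    if fit.n_components < 2:
        raise ValueError("need at least 2 components to identify CSF and WGM")
    low, high = csf_hu_range
    in_range = [i for i in range(fit.n_components) if low <= fit.means[i] <= high]
    if not in_range:
        raise ValueError(
            f"no component mean inside the CSF range [{low}, {high}] HU; "
            "override the CSF component manually"
        )
    csf_i = min(in_range, key=lambda i: fit.means[i])
    above = [i for i in range(fit.n_components) if fit.means[i] > fit.means[csf_i]]
    if not above:
        raise ValueError("no component with mean above the CSF component")
    wgm_i = max(above, key=lambda i: fit.weights[i])
    return TissueComponents(
        csf=GaussianParams(float(fit.means[csf_i]), float(fit.sigmas[csf_i])),
        wgm=GaussianParams(float(fit.means[wgm_i]), float(fit.sigmas[wgm_i])),
        csf_index=csf_i,
        wgm_index=wgm_i,
    )
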