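"""Shared domain containers.

Intensities are in Hounsfield units (HU) throughout: water = 0 HU,
air = -1000 HU.  Binary masks are plain boolean ``numpy`` arrays on the
same raster as their source slice; coordinates are 0-based ``(row, col)``
with row increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GaussianParams:
    """Mean and standard deviation of one tissue-intensity Gaussian (HU)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def pdf(self, x):
        """Gaussian density N(x | mu, sigma)."""
        x = np.asarray(x, dtype=float)
        z = (x - self.mu) / self.sigma
        return np.exp(-0.5 * z * z) / (self.sigma * np.sqrt(2.0 * np.pi))

    def peak_normalized(self, x):
        """N(x|mu,sigma) / N(mu|mu,sigma) — the density scaled to peak 1."""
        x = np.asarray(x, dtype=float)
        z = (x - self.mu) / self.sigma
        return np.exp(-0.5 * z * z)


@dataclass
class ImageSlice:
    """A single 2-D CT slice in Hounsfield units."""

    pixels: np.ndarray
    pixel_spacing: float | None = None  # mm per pixel, informational

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise ValueError("slice must be at least 3x3")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Histogram:
    """Intensity histogram over the HU analysis window.

    Pixels outside ``[hu_min, hu_max]`` are excluded (not clipped) before
    counting, so ``counts.sum()`` equals the number of in-window pixels.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    hu_min: float
    hu_max: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts length must equal number of bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass
class GMMFit:
    """A fitted Gaussian mixture with convergence metadata.

    ``weights[i]`` is the mixing proportion of component ``i`` (sums to 1);
    ``log_likelihood_trace`` is non-decreasing by the EM guarantee.
    """

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    log_likelihood_trace: np.ndarray
    n_iter: int
    converged: bool
    degenerate: bool = False  # a sigma hit the regularization floor

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def components(self) -> list[tuple[float, GaussianParams]]:
        return [
            (float(w), GaussianParams(float(m), float(s)))
            for w, m, s in zip(self.weights, self.means, self.sigmas)
        ]

    def to_dict(self) -> dict:
        return {
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "sigmas": [float(s) for s in self.sigmas],
            "log_likelihood": float(self.log_likelihood_trace[-1]),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
        }
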