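"""Classical honeycomb-removal baselines.

Three comparison methods: a 7x7 median filter, a Gaussian filter
(sigma 3), and the calibrated interpolation workflow — detect core centers
on the white reference, sample the raw image at those centers, and fill
the field of view by barycentric interpolation over a Delaunay
triangulation of the cores.  Filtering blurs cores and cladding alike;
interpolation preserves core intensities but depends on accurate core
detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage.feature import peak_local_max

from .bundlesim import WhiteReference

__all__ = [
    "CoreMap",
    "median_restore",
    "gaussian_restore",
    "gaussian_kernel",
    "detect_cores",
    "sample_cores",
    "interpolation_restore",
]


@dataclass
class CoreMap:
    """Detected core centers with optional per-core samples/triangulation.

    ``centers`` are subpixel (row, col) positions; ``values`` are image
    intensities sampled at the centers; ``triangulation`` lists Delaunay
    simplices as index triples over ``centers``.
    """

    centers: np.ndarray
    values: np.ndarray | None = None
    triangulation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be (N, 2)")


def median_restore(image: np.ndarray, size: int = 7) -> np.ndarray:
    """Per-pixel median over a size x size window, replicate borders."""
    if size < 3 or size % 2 == 0:
        raise ValueError("median size must be odd and >= 3")
    return ndimage.median_filter(np.asarray(image, dtype=np.float64),
                                 size=size, mode="nearest")


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel truncated at radius ceil(3*sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(np.ceil(3.0 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(k1, k1)
    return kernel / kernel.sum()


def gaussian_restore(image: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Convolution with the normalized Gaussian kernel, replicate borders."""
    kernel = gaussian_kernel(sigma)
    return ndimage.correlate(np.asarray(image, dtype=np.float64), kernel,
                             mode="nearest")


def _subpixel_refine(image: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Quadratic (parabolic) refinement of integer peak positions."""
    h, w = image.shape
    refined = peaks.astype(np.float64).copy()
    for k, (r, c) in enumerate(peaks):
        for axis, (lo, hi, pos) in enumerate([(r - 1, r + 1, r), (c - 1, c + 1, c)]):
            if lo < 0 or hi >= (h if axis == 0 else w):
                continue
            if axis == 0:
                fm, f0, fp = image[lo, c], image[r, c], image[hi, c]
            else:
                fm, f0, fp = image[r, lo], image[r, c], image[r, hi]
            denom = fm - 2.0 * f0 + fp
            if denom < 0:  # proper local maximum along this axis
                delta = 0.5 * (fm - fp) / denom
                refined[k, axis] = pos + np.clip(delta, -0.5, 0.5)
    return refined


def detect_cores(ref: WhiteReference | np.ndarray, min_distance: int = 3,
                 smooth_sigma: float = 0.7,
                 threshold_rel: float = 0.1) -> CoreMap:
    """Find core centers as local maxima of the lightly smoothed reference.

    Non-maximum suppression at ``min_distance`` (just under the core
    pitch), then subpixel refinement by a separable quadratic fit.
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    pixels = np.asarray(getattr(ref, "pixels", ref), dtype=np.float64)
    if pixels.max() == pixels.min():
        raise ValueError("constant reference: no strict local maxima")
    smoothed = ndimage.gaussian_filter(pixels, smooth_sigma, mode="nearest")
    peaks = peak_local_max(smoothed, min_distance=min_distance,
                           threshold_rel=threshold_rel, exclude_border=False)
    if len(peaks) == 0:
        raise ValueError("no local maxima found in reference")
    return CoreMap(centers=_subpixel_refine(smoothed, peaks))


def sample_cores(image: np.ndarray, cores: CoreMap) -> CoreMap:
    """Bilinearly sample ``image`` at each core center (new CoreMap)."""
    img = np.asarray(image, dtype=np.float64)
    values = ndimage.map_coordinates(img, cores.centers.T, order=1,
                                     mode="nearest")
    return CoreMap(centers=cores.centers, values=values,
                   triangulation=cores.triangulation)


def interpolation_restore(image: np.ndarray, cores: CoreMap) -> np.ndarray:
    """Barycentric interpolation of core samples over their triangulation.

    The raw image is sampled at each core center; every pixel inside the
    convex hull of the centers receives the barycentric combination of its
    Delaunay triangle's three core values.  Outside-hull pixels stay 0
    (the masked void region).
    """
    img = np.asarray(image, dtype=np.float64)
    if len(cores.centers) < 3:
        raise ValueError("need at least 3 cores")
    values = cores.values
    if values is None:
        values = ndimage.map_coordinates(img, cores.centers.T, order=1,
                                         mode="nearest")
    try:
        tri = Delaunay(cores.centers)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) core geometry") from exc
    cores.triangulation = tri.simplices

    h, w = img.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    simplex = tri.find_simplex(pts)
    inside = simplex >= 0
    out = np.zeros(h * w, dtype=np.float64)
    if np.any(inside):
        s = simplex[inside]
        transform = tri.transform[s]
        bary2 = np.einsum("nij,nj->ni", transform[:, :2, :],
                          pts[inside] - transform[:, 2, :])
        weights = np.concatenate(
            [bary2, 1.0 - bary2.sum(axis=1, keepdims=True)], axis=1)
        out[inside] = np.einsum("ni,ni->n", weights,
                                values[tri.simplices[s]])
    return out.reshape(h, w)
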