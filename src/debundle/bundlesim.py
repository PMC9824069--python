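"""Synthetic fiber-bundle simulator.

A coherent fiber bundle relays an image through thousands of individual
cores; the non-transmitting cladding between cores superimposes a dark
quasi-hexagonal mesh (the honeycomb artifact) on every frame.  This module
fabricates the calibration and test imagery such a system produces — white
references (bright cores on a hexagonal lattice inside a circular field of
view), bar targets standing in for a USAF 1951 resolution chart, and smooth
random textures standing in for ordinary photographs — so the rest of the
package can be exercised without hardware.

Geometry emulates a Fujikura-style bundle imaged at 1024x1024: core pitch
about 5-6 px with per-core position jitter (the lattice is only
quasi-hexagonal) and per-core transmission variation.  Coordinates are
0-based (row, col) with the origin at the top-left pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import RegionSpec

__all__ = [
    "BundleSpec",
    "WhiteReference",
    "generate_reference",
    "generate_bar_target",
    "generate_texture",
]


@dataclass(frozen=True)
class BundleSpec:
    """Parameters of a simulated fiber bundle.

    ``core_pitch`` is the center-to-center core distance in pixels,
    ``core_sigma`` the Gaussian half-width of one core's transmission
    profile, ``jitter_sigma`` the RMS displacement of each core from the
    ideal hexagonal lattice, ``intensity_jitter`` the fractional spread of
    per-core peak transmission, and ``fov_radius`` the circular
    field-of-view radius (defaults to ``min(H, W)/2 - 1``).
    ``background_level`` is the cladding transmission floor; real
    references have a small non-zero floor, the default assumes none.
    """

    image_size: tuple[int, int] = (256, 256)
    core_pitch: float = 5.5
    core_sigma: float = 1.1
    jitter_sigma: float = 0.3
    intensity_jitter: float = 0.2
    fov_radius: float | None = None
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size too small")
        if self.core_pitch <= 0 or self.core_sigma <= 0:
            raise ValueError("core_pitch and core_sigma must be positive")
        if not 0.0 <= self.intensity_jitter < 1.0:
            raise ValueError("intensity_jitter must lie in [0, 1)")
        if self.jitter_sigma < 0 or self.background_level < 0:
            raise ValueError("jitter_sigma and background_level must be >= 0")
        if self.fov_radius is not None and self.fov_radius > min(h, w) / 2:
            raise ValueError("fov_radius exceeds half the image size")

    @property
    def resolved_fov_radius(self) -> float:
        if self.fov_radius is not None:
            return float(self.fov_radius)
        return min(self.image_size) / 2.0 - 1.0


@dataclass
class WhiteReference:
    """A white-reference raster: bright at cores, dark at cladding.

    ``core_centers`` holds the ground-truth subpixel (row, col) core
    positions — known only for simulated references.
    """

    pixels: np.ndarray
    core_centers: np.ndarray | None = None
    ref_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("reference must be a 2-D raster")
        if self.pixels.min() < 0:
            raise ValueError("reference values must be non-negative")
        if self.pixels.max() <= 0:
            raise ValueError("reference must have a positive maximum")


def _hex_lattice(center: tuple[float, float], pitch: float,
                 extent: tuple[int, int]) -> np.ndarray:
    """Hexagonal lattice points covering ``extent``, one point at ``center``.

    Built from basis vectors a1 = (0, p) and a2 = (p*sqrt(3)/2, p/2), which
    makes the point set invariant under 60-degree rotation about the anchor.
    """
    h, w = extent
    row_step = pitch * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(max(h, w) / row_step)) + 2
    n_cols = int(np.ceil(max(h, w) / pitch)) + 2
    ii, jj = np.meshgrid(np.arange(-n_rows, n_rows + 1),
                         np.arange(-n_cols, n_cols + 1), indexing="ij")
    rows = center[0] + ii * row_step
    cols = center[1] + (jj + 0.5 * (np.abs(ii) % 2)) * pitch
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1)
    inside = (
        (pts[:, 0] > -pitch) & (pts[:, 0] < h + pitch)
        & (pts[:, 1] > -pitch) & (pts[:, 1] < w + pitch)
    )
    return pts[inside]


def generate_reference(spec: BundleSpec) -> WhiteReference:
    """Render a synthetic white reference for ``spec``.

    Cores sit on a jittered hexagonal lattice anchored at the image center;
    each is an isotropic Gaussian bump of width ``core_sigma`` and peak
    ``1 +- intensity_jitter``; everything is multiplied by the circular
    field-of-view mask.  Deterministic for a fixed seed.
    """
    if spec.core_pitch < 2.0 * spec.core_sigma:
        warnings.warn(
            "core_pitch < 2*core_sigma: cores merge and honeycomb contrast "
            "vanishes", stacklevel=2)
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    centers = _hex_lattice(center, spec.core_pitch, (h, w))
    if spec.jitter_sigma > 0:
        centers = centers + rng.normal(0.0, spec.jitter_sigma, centers.shape)
    radius = spec.resolved_fov_radius
    dist = np.hypot(centers[:, 0] - center[0], centers[:, 1] - center[1])
    keep = dist <= radius
    centers = centers[keep]
    peaks = 1.0 + rng.uniform(-spec.intensity_jitter, spec.intensity_jitter,
                              len(centers))

    pixels = np.full((h, w), spec.background_level, dtype=np.float64)
    support = max(3, int(np.ceil(4.0 * spec.core_sigma)))
    two_s2 = 2.0 * spec.core_sigma**2
    for (cr, cc), peak in zip(centers, peaks):
        r0 = max(0, int(np.floor(cr)) - support)
        r1 = min(h, int(np.ceil(cr)) + support + 1)
        c0 = max(0, int(np.floor(cc)) - support)
        c1 = min(w, int(np.ceil(cc)) + support + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=np.float64)[:, None]
        cc_ = np.arange(c0, c1, dtype=np.float64)[None, :]
        pixels[r0:r1, c0:c1] += peak * np.exp(
            -((rr - cr) ** 2 + (cc_ - cc) ** 2) / two_s2)

    from .synthesis import make_circular_mask

    mask = make_circular_mask((h, w), center=center, radius=radius)
    pixels *= mask
    return WhiteReference(pixels=pixels, core_centers=centers,
                          ref_id=f"sim-{spec.seed}-{h}x{w}")


def generate_bar_target(
    image_size: tuple[int, int],
    bar_period: float = 12.0,
    orientation: str = "horizontal",
    contrast: float = 1.0,
    high: float = 1.0,
) -> tuple[np.ndarray, dict[str, RegionSpec]]:
    """Square-wave bar pattern plus a flat bright region.

    Stands in for a resolution test chart: one half of the frame carries
    bars of the given period (bright level ``high``, dark level
    ``high*(1-contrast)``), the other half is uniformly bright.  Returns the
    raster together with a flat-kind and a lines-kind :class:`RegionSpec`,
    both placed centrally so they stay inside a centered circular field of
    view of radius ``min(H, W)/2``.
    """
    if bar_period < 2:
        raise ValueError("bar_period must be >= 2")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    h, w = image_size
    low = high * (1.0 - contrast)
    k = np.arange(h)
    bar_rows = (k % bar_period) < (bar_period / 2.0)
    image = np.full((h, w), high, dtype=np.float64)
    image[: h // 2] = np.where(bar_rows[: h // 2, None], high, low)

    m = min(h, w)
    a, b, c = int(m * 0.35), int(m * 0.06), int(m * 0.22)
    lines = RegionSpec("lines", rows=(h // 2 - a, h // 2 - b),
                       cols=(w // 2 - c, w // 2 + c), line_axis=0)
    flat = RegionSpec("flat", rows=(h // 2 + b, h // 2 + a),
                      cols=(w // 2 - c, w // 2 + c))
    if orientation == "horizontal":
        return image, {"flat": flat, "lines": lines}
    if orientation == "vertical":
        flat_t = RegionSpec("flat", rows=flat.cols, cols=flat.rows)
        lines_t = RegionSpec("lines", rows=lines.cols, cols=lines.rows,
                             line_axis=1)
        return image.T.copy(), {"flat": flat_t, "lines": lines_t}
    raise ValueError(f"unknown orientation {orientation!r}")


def generate_texture(
    image_size: tuple[int, int],
    correlation_length: float = 3.0,
    seed: int = 0,
    normalize: str = "fixed",
) -> np.ndarray:
    """Smooth Gaussian random field in [0, 1].

    White noise is low-pass filtered at ``correlation_length`` pixels.  With
    ``normalize="fixed"`` the field keeps a gain anchored to the unit
    correlation length, so longer correlation lengths yield flatter fields
    (a fixed-power process seen through increasing blur); ``"stretch"``
    min-max rescales to the full unit interval for maximum contrast.
    """
    if correlation_length < 1:
        raise ValueError("correlation_length must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(image_size)
    smooth = ndimage.gaussian_filter(noise, correlation_length, mode="reflect")
    if normalize == "fixed":
        # std of unit white noise after sigma=1 Gaussian smoothing
        sigma_ref = 1.0 / (2.0 * np.sqrt(np.pi))
        gain = 0.5 / (3.0 * sigma_ref)
        return np.clip(0.5 + gain * smooth, 0.0, 1.0)
    if normalize == "stretch":
        lo, hi = smooth.min(), smooth.max()
        if hi == lo:
            return np.full(image_size, 0.5)
        return (smooth - lo) / (hi - lo)
    raise ValueError(f"unknown normalize mode {normalize!r}")
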