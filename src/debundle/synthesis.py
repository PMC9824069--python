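"""Training-pair synthesis by white-reference multiplication.

Supervised artifact removal needs (bundle image, artifact-free image) pairs.
Instead of acquiring aligned ground truth with extra hardware, honeycomb
patterns are synthesized onto ordinary images: the image is converted to
grayscale, resized to the acquisition resolution, masked to the circular
field of view, and multiplied pixel-wise by the white reference normalized
to [0, 1].  Normalizing by the global maximum (rather than min-max) keeps
the transmission at core centers at unity, so core-pixel intensities of the
scene are preserved in the synthetic bundle image.

Intensities live in float [0, 1] throughout; 8/16-bit conversion happens
only at I/O boundaries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from skimage.transform import resize as _resize

if TYPE_CHECKING:  # avoid a runtime import cycle with bundlesim
    from .bundlesim import WhiteReference

__all__ = [
    "SyntheticPair",
    "normalize_reference",
    "make_circular_mask",
    "to_grayscale_unit",
    "synthesize",
]

#: ITU-R BT.601 luminance weights for RGB -> grayscale conversion.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class SyntheticPair:
    """One (ground truth, honeycomb-synthesized bundle image) unit.

    Both rasters share a shape and live in [0, 1]; the bundle image is the
    ground truth multiplied by the normalized reference, hence nowhere
    larger than the ground truth and zero outside the circular mask.
    """

    ground_truth: np.ndarray
    bundle_image: np.ndarray
    reference_id: str | None = None
    image_id: str | None = None

    def __post_init__(self) -> None:
        self.ground_truth = np.asarray(self.ground_truth, dtype=np.float64)
        self.bundle_image = np.asarray(self.bundle_image, dtype=np.float64)
        if self.ground_truth.shape != self.bundle_image.shape:
            raise ValueError("ground truth and bundle image shapes differ")


def normalize_reference(ref: "WhiteReference | np.ndarray") -> np.ndarray:
    """Scale a white reference to [0, 1] by its global maximum.

    Division by the maximum (not min-max) is deliberate: it leaves the
    brightest core at exactly 1 without inflating the cladding floor, so
    multiplying a scene by the result can only attenuate it.
    """
    pixels = np.asarray(getattr(ref, "pixels", ref), dtype=np.float64)
    top = pixels.max()
    if top <= 0:
        raise ValueError("reference has no positive values (no cores)")
    return pixels / top


def make_circular_mask(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> np.ndarray:
    """Binary mask: 1 strictly inside ``radius`` of ``center``, else 0.

    Defaults: center of the pixel grid and radius ``min(H, W)/2``.
    """
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if radius is None:
        radius = min(h, w) / 2.0
    if radius <= 0:
        raise ValueError("radius must be positive")
    rr = np.arange(h, dtype=np.float64)[:, None] - center[0]
    cc = np.arange(w, dtype=np.float64)[None, :] - center[1]
    return (rr**2 + cc**2 < radius**2).astype(np.float64)


def to_grayscale_unit(image: np.ndarray) -> np.ndarray:
    """Convert an 8/16-bit or float image, gray or RGB, to float [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise ValueError("color images must have exactly 3 channels")
        arr = np.tensordot(arr.astype(np.float64), LUMINANCE_WEIGHTS, axes=([2], [0]))
    elif arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale or 3-channel color image")
    arr = arr.astype(np.float64)
    dt = np.asarray(image).dtype
    if dt == np.uint8:
        arr /= 255.0
    elif dt == np.uint16:
        arr /= 65535.0
    return np.clip(arr, 0.0, 1.0)


def synthesize(
    image: np.ndarray,
    ref: "WhiteReference | np.ndarray",
    out_size: tuple[int, int] | None = None,
    mask_center: tuple[float, float] | None = None,
    mask_radius: float | None = None,
    image_id: str | None = None,
    aperture_sigma: float | None = None,
) -> SyntheticPair:
    """Turn an ordinary image into a (ground truth, bundle image) pair.

    Steps: grayscale conversion (luminance weights), bilinear resize to
    ``out_size`` (default: the reference's size), circular masking, and
    pixel-wise multiplication by the normalized reference.  The ground
    truth is the masked resized scene; the bundle image is that scene
    modulated by the honeycomb transmission pattern.

    ``aperture_sigma`` optionally blurs the scene before multiplication,
    emulating the finite collection aperture of each fiber core when a
    *physical* scene is imaged through the bundle; leave it ``None`` for
    training-pair synthesis from ordinary images, where the published
    scheme is a bare reference multiplication.  The ground truth keeps the
    unblurred scene either way.
    """
    ref_pixels = np.asarray(getattr(ref, "pixels", ref), dtype=np.float64)
    if ref_pixels.ndim != 2:
        raise ValueError("reference must be a 2-D raster")
    if out_size is None:
        out_size = ref_pixels.shape

    scene = to_grayscale_unit(image)
    if scene.shape != tuple(out_size):
        scene = _resize(scene, out_size, order=1, anti_aliasing=False,
                        preserve_range=True)
    nref = normalize_reference(ref_pixels)
    if nref.shape != tuple(out_size):
        nref = _resize(nref, out_size, order=1, anti_aliasing=False,
                       preserve_range=True)
        top = nref.max()
        if top <= 0:
            raise ValueError("reference vanished after resizing")
        nref = nref / top

    mask = make_circular_mask(tuple(out_size), center=mask_center,
                              radius=mask_radius)
    scene = np.clip(scene, 0.0, 1.0)
    ground_truth = scene * mask
    if aperture_sigma:
        from scipy import ndimage

        scene = ndimage.gaussian_filter(scene, aperture_sigma, mode="nearest")
    bundle = scene * mask * nref

    ref_id = getattr(ref, "ref_id", None)
    if ref_id is None:
        ref_id = "ref-" + hashlib.sha1(
            np.ascontiguousarray(ref_pixels)).hexdigest()[:10]
    return SyntheticPair(ground_truth=ground_truth, bundle_image=bundle,
                         reference_id=ref_id, image_id=image_id)
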