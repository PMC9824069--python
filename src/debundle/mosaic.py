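"""Feature-based mosaicking of restored bundle frames.

A handheld scan produces a stream of small circular-FOV frames; stitching
them needs inter-frame correspondences, which is exactly where honeycomb
artifacts hurt: the stationary core pattern is itself a dense field of
distinctive "corners", so matching on raw frames locks onto the bundle
instead of the moving scene.  The pipeline here is deliberately minimal: a
Shi-Tomasi corner detector (structure-tensor minimum eigenvalue), patch
descriptors matched by normalized cross-correlation within a search
radius, a translation-only motion model estimated as the inlier-median
displacement, and an averaging canvas compositor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_shi_tomasi, peak_local_max

__all__ = [
    "FeatureSet",
    "MosaicState",
    "MatchFailure",
    "detect_features",
    "match_and_shift",
    "composite",
]


class MatchFailure(RuntimeError):
    """Raised when too few inlier correspondences support a shift."""


@dataclass
class FeatureSet:
    """Corner points (row, col), responses in descending order, and
    fixed-size local patch descriptors.

    ``source`` keeps a reference to the frame the features came from so a
    matcher can correlate descriptors densely against it (block matching)
    rather than only at detected corner positions.
    """

    points: np.ndarray
    scores: np.ndarray
    descriptors: np.ndarray
    source: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MosaicState:
    """Accumulated mosaic: averaged canvas, contribution counts, and the
    per-frame (row, col) offsets relative to frame 0."""

    canvas: np.ndarray
    weights: np.ndarray
    offsets: list[tuple[float, float]] = field(default_factory=list)
    inlier_counts: list[int] = field(default_factory=list)


def detect_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    max_points: int = 200,
    min_distance: int = 5,
    descriptor_size: int = 9,
    sigma: float = 1.0,
    threshold_rel: float = 0.05,
    threshold_abs: float | None = None,
    border_erosion: int = 6,
) -> FeatureSet:
    """Strongest corner responses inside the (eroded) mask.

    The mask is eroded before use so the circular FOV boundary — itself a
    strong gradient — does not contribute spurious corners.  The peak
    threshold is relative to the image's own maximum response unless an
    absolute ``threshold_abs`` is given (useful for comparing feature
    counts across differently processed versions of the same frame).  An
    empty result is legal (e.g. on a constant image).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D raster")
    response = corner_shi_tomasi(img, sigma=sigma)
    valid = np.ones_like(img, dtype=bool)
    if mask is not None:
        valid = np.asarray(mask) > 0
    if border_erosion > 0:
        valid = ndimage.binary_erosion(valid, iterations=border_erosion)
    half = descriptor_size // 2
    valid[:half, :] = valid[-half:, :] = False
    valid[:, :half] = valid[:, -half:] = False
    response = np.where(valid, response, 0.0)
    if response.max() <= 0:
        empty = np.empty((0, 2))
        return FeatureSet(empty, np.empty(0), np.empty((0, descriptor_size**2)))
    if threshold_abs is not None:
        peaks = peak_local_max(response, min_distance=min_distance,
                               threshold_abs=threshold_abs,
                               exclude_border=False)
    else:
        peaks = peak_local_max(response, min_distance=min_distance,
                               threshold_rel=threshold_rel,
                               exclude_border=False)
    if len(peaks) == 0:
        empty = np.empty((0, 2))
        return FeatureSet(empty, np.empty(0), np.empty((0, descriptor_size**2)))
    scores = response[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(scores)[::-1][:max_points]
    peaks, scores = peaks[order], scores[order]
    descriptors = np.stack([
        img[r - half : r + half + 1, c - half : c + half + 1].ravel()
        for r, c in peaks
    ])
    return FeatureSet(peaks.astype(np.float64), scores, descriptors,
                      source=img)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _block_match(patch: np.ndarray, image: np.ndarray, center: np.ndarray,
                 radius: int, ncc_threshold: float):
    """Dense NCC of one descriptor patch over a search window in ``image``.

    Returns the subpixel displacement of the best correlation peak, or
    None when the peak is weaker than ``ncc_threshold``.  Subpixel offsets
    come from a separable parabolic fit around the integer peak.
    """
    half = patch.shape[0] // 2
    cr, cc = int(center[0]), int(center[1])
    pz = patch - patch.mean()
    pnorm = np.linalg.norm(pz)
    if pnorm == 0:
        return None
    n = 2 * radius + 1
    surface = np.full((n, n), -2.0)  # sentinel: candidate out of frame
    for i in range(n):
        rr = cr + i - radius
        if rr - half < 0 or rr + half >= image.shape[0]:
            continue
        for j in range(n):
            col = cc + j - radius
            if col - half < 0 or col + half >= image.shape[1]:
                continue
            cand = image[rr - half : rr + half + 1, col - half : col + half + 1]
            cz = cand - cand.mean()
            den = pnorm * np.linalg.norm(cz)
            if den > 0:
                surface[i, j] = float((pz * cz).sum() / den)
    peak = np.unravel_index(np.argmax(surface), surface.shape)
    if surface[peak] < ncc_threshold:
        return None
    offset = np.array(peak, dtype=np.float64)
    for axis in range(2):
        k = peak[axis]
        if 0 < k < n - 1:
            idx_m = list(peak)
            idx_p = list(peak)
            idx_m[axis] -= 1
            idx_p[axis] += 1
            fm, f0, fp = surface[tuple(idx_m)], surface[peak], surface[tuple(idx_p)]
            denom = fm - 2.0 * f0 + fp
            if fm > -2.0 and fp > -2.0 and denom < 0:
                offset[axis] += np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5)
    return offset - radius


def match_and_shift(
    a: FeatureSet,
    b: FeatureSet,
    search_radius: float = 20.0,
    ncc_threshold: float = 0.7,
    min_inliers: int = 3,
    max_features: int = 80,
) -> tuple[tuple[float, float], int]:
    """Estimate the translation mapping features of ``a`` onto ``b``.

    Each feature descriptor of ``a`` is correlated (NCC) against the next
    frame within ``search_radius`` and votes with the subpixel location of
    its best correlation peak; when ``b`` carries no source frame the
    descriptor is instead compared against ``b``'s detected features only.
    The shift is the median displacement over inliers (votes within 1 px
    of the overall median).  Raises :class:`MatchFailure` below
    ``min_inliers``.
    """
    if len(a) == 0 or len(b) == 0:
        raise MatchFailure("no features to match")
    radius = int(np.ceil(search_radius))
    displacements = []
    if b.source is not None:
        half = int(np.sqrt(a.descriptors.shape[1])) // 2
        size = 2 * half + 1
        for pa, da in zip(a.points[:max_features],
                          a.descriptors[:max_features]):
            disp = _block_match(da.reshape(size, size), b.source, pa,
                                radius, ncc_threshold)
            if disp is not None:
                displacements.append(disp)
    else:
        for pa, da in zip(a.points, a.descriptors):
            d = b.points - pa
            near = np.flatnonzero(np.hypot(d[:, 0], d[:, 1]) <= search_radius)
            best, best_ncc = None, ncc_threshold
            for j in near:
                score = _ncc(da, b.descriptors[j])
                if score > best_ncc:
                    best, best_ncc = j, score
            if best is not None:
                displacements.append(b.points[best] - pa)
    if len(displacements) < min_inliers:
        raise MatchFailure(f"only {len(displacements)} tentative matches")
    disp = np.asarray(displacements)
    med = np.median(disp, axis=0)
    inlier = np.max(np.abs(disp - med), axis=1) <= 1.0
    if int(inlier.sum()) < min_inliers:
        raise MatchFailure(f"only {int(inlier.sum())} inliers at 1 px")
    shift = np.median(disp[inlier], axis=0)
    return (float(shift[0]), float(shift[1])), int(inlier.sum())


def composite(
    frames: list[np.ndarray],
    mask: np.ndarray | None = None,
    search_radius: float = 20.0,
    max_points: int = 200,
    detect_kwargs: dict | None = None,
) -> MosaicState:
    """Chain pairwise shifts and average masked frames onto a canvas.

    Frame ``i`` is placed at minus the accumulated feature displacement
    (scene motion is opposite to the apparent feature motion).  A matching
    failure truncates the mosaic at the last successfully placed frame.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    kw = dict(detect_kwargs or {})
    feats = [detect_features(f, mask=mask, max_points=max_points, **kw)
             for f in frames]
    offsets = [(0.0, 0.0)]
    inliers = [0]
    for i in range(1, len(frames)):
        try:
            (dr, dc), n_in = match_and_shift(feats[i - 1], feats[i],
                                             search_radius=search_radius)
        except MatchFailure:
            break
        prev = offsets[-1]
        offsets.append((prev[0] - dr, prev[1] - dc))
        inliers.append(n_in)

    used = frames[: len(offsets)]
    m = np.ones_like(used[0]) if mask is None else np.asarray(mask, dtype=np.float64)
    rounded = [(int(round(r)), int(round(c))) for r, c in offsets]
    h, w = used[0].shape
    r0 = min(r for r, _ in rounded)
    c0 = min(c for _, c in rounded)
    r1 = max(r for r, _ in rounded) + h
    c1 = max(c for _, c in rounded) + w
    acc = np.zeros((r1 - r0, c1 - c0), dtype=np.float64)
    cnt = np.zeros_like(acc)
    for frame, (r, c) in zip(used, rounded):
        acc[r - r0 : r - r0 + h, c - c0 : c - c0 + w] += frame * m
        cnt[r - r0 : r - r0 + h, c - c0 : c - c0 + w] += m
    canvas = np.zeros_like(acc)
    np.divide(acc, cnt, out=canvas, where=cnt > 0)
    return MosaicState(canvas=canvas, weights=cnt, offsets=offsets,
                       inlier_counts=inliers)
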