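"""Quality metrics for honeycomb-artifact removal.

Restoration fidelity against a known ground truth is measured with PSNR and
SSIM.  When no ground truth exists (real bundle acquisitions of a resolution
target) two bespoke measures are used instead: a variance-based smoothness
``s`` computed on a flat region, a Rayleigh-style line-separation contrast
``r`` computed on a bar-patterned region, and their convex combination
``q = gamma*s + (1-gamma)*r``.

All rasters are expected as 2-D floats.  Images stored in the unit interval
are rescaled internally to the conventional 0-255 dynamic range (``peak``)
so that the printed dB values follow the usual 8-bit convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

__all__ = [
    "RegionSpec",
    "QualityReport",
    "psnr",
    "ssim",
    "smoothness",
    "line_separation",
    "weighted_quality",
    "evaluate",
]


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular region of interest, inclusive pixel ranges.

    ``kind`` is ``"flat"`` (uniform-scene region, used for smoothness) or
    ``"lines"`` (bar-patterned region, used for line separation).
    ``line_axis`` is the axis along which the bar pattern varies: 0 means the
    intensity profile is indexed by row and averaged across columns.
    """

    kind: str
    rows: tuple[int, int]
    cols: tuple[int, int]
    line_axis: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "lines"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.rows[1] < self.rows[0] or self.cols[1] < self.cols[0]:
            raise ValueError("empty region")
        if self.line_axis not in (0, 1):
            raise ValueError("line_axis must be 0 or 1")

    def extract(self, image: np.ndarray) -> np.ndarray:
        """Return the sub-image covered by this region (inclusive bounds)."""
        if self.rows[1] >= image.shape[0] or self.cols[1] >= image.shape[1]:
            raise ValueError("region exceeds image bounds")
        return image[self.rows[0] : self.rows[1] + 1, self.cols[0] : self.cols[1] + 1]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "rows": list(self.rows),
            "cols": list(self.cols),
            "line_axis": self.line_axis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        return cls(d["kind"], tuple(d["rows"]), tuple(d["cols"]), d.get("line_axis", 0))


@dataclass
class QualityReport:
    """Bundle of all quality measures for one restored image."""

    psnr: float | None = None
    ssim: float | None = None
    s: float | None = None
    r: float | None = None
    q: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "psnr": self.psnr,
            "ssim": self.ssim,
            "s": self.s,
            "r": self.r,
            "q": {str(g): v for g, v in self.q.items()},
        }


def psnr(truth: np.ndarray, estimate: np.ndarray, peak: float = 255.0,
         input_max: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, ``20*log10(peak/sqrt(MSE))``.

    ``input_max`` declares the scale the rasters are stored on; both images
    are mapped to the 0-``peak`` range before the MSE so that unit-interval
    and 8-bit inputs give the same dB value.  Identical images return +inf.
    """
    truth = np.asarray(truth, dtype=np.float64)
    estimate = np.asarray(estimate, dtype=np.float64)
    if truth.shape != estimate.shape:
        raise ValueError("shape mismatch")
    scale = peak / input_max
    mse = np.mean(((truth - estimate) * scale) ** 2)
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(peak / np.sqrt(mse)))


def ssim(x: np.ndarray, y: np.ndarray, L: float = 255.0, input_max: float = 1.0,
         window: str = "gaussian") -> float:
    """Mean structural similarity.

    ``window="gaussian"`` uses the standard 11x11 Gaussian-weighted window
    (sigma 1.5).  ``window="global"`` evaluates the SSIM statistic once with
    global means/SDs/cross-covariance over the whole image, i.e. the bare
    formula without local windowing.  ``L`` is the dynamic range entering
    the stabilising constants c1=(0.01 L)^2 and c2=(0.03 L)^2.
    """
    x = np.asarray(x, dtype=np.float64) * (L / input_max)
    y = np.asarray(y, dtype=np.float64) * (L / input_max)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if window == "gaussian":
        return float(
            _sk_ssim(x, y, data_range=L, gaussian_weights=True, sigma=1.5,
                     win_size=11, use_sample_covariance=False)
        )
    if window == "global":
        c1 = (0.01 * L) ** 2
        c2 = (0.03 * L) ** 2
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        num = (2 * mx * my + c1) * (2 * cxy + c2)
        den = (mx**2 + my**2 + c1) * (vx + vy + c2)
        return float(num / den)
    raise ValueError(f"unknown window mode {window!r}")


def smoothness(raw: np.ndarray, restored: np.ndarray, region: RegionSpec) -> float:
    """Variance-based smoothness ``s = 1 - sigma_restored / sigma_raw``.

    Both standard deviations are taken over the same flat region.  0 means
    the restoration left the honeycomb variance untouched; 1 means the
    region was flattened completely.
    """
    if region.kind != "flat":
        raise ValueError("smoothness requires a flat-kind region")
    sigma0 = float(np.std(region.extract(np.asarray(raw, dtype=np.float64))))
    if sigma0 == 0.0:
        raise ValueError("raw region has zero variance; smoothness undefined")
    sigma_s = float(np.std(region.extract(np.asarray(restored, dtype=np.float64))))
    return 1.0 - sigma_s / sigma0


def line_separation(restored: np.ndarray, region: RegionSpec) -> float:
    """Rayleigh-based line separation ``r = (max(Sl)-min(Sl))/max(Sl)``.

    ``Sl(k)`` is the intensity profile across the bar pattern, obtained by
    averaging along the bars (across columns for ``line_axis == 0``).
    """
    if region.kind != "lines":
        raise ValueError("line_separation requires a lines-kind region")
    sub = region.extract(np.asarray(restored, dtype=np.float64))
    profile = sub.mean(axis=1 - region.line_axis)
    top = float(profile.max())
    if top <= 0.0:
        raise ValueError("bar profile has non-positive maximum")
    return (top - float(profile.min())) / top


def weighted_quality(s: float, r: float, gamma: float) -> float:
    """Convex combination ``q = gamma*s + (1-gamma)*r``."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return gamma * s + (1.0 - gamma) * r


def evaluate(
    restored: np.ndarray,
    truth: np.ndarray | None = None,
    raw: np.ndarray | None = None,
    regions: dict[str, RegionSpec] | None = None,
    gammas: tuple[float, ...] = (0.5, 0.8),
    peak: float = 255.0,
) -> QualityReport:
    """Compute every applicable measure for one restored image.

    PSNR/SSIM need ``truth``; smoothness needs ``raw`` plus a flat region;
    line separation needs a lines region.  q(gamma) is filled for every
    requested gamma whenever both s and r are available.
    """
    report = QualityReport()
    if truth is not None:
        report.psnr = psnr(truth, restored, peak=peak)
        report.ssim = ssim(truth, restored, L=peak)
    if regions:
        flat = regions.get("flat")
        lines = regions.get("lines")
        if flat is not None and raw is not None:
            report.s = smoothness(raw, restored, flat)
        if lines is not None:
            report.r = line_separation(restored, lines)
        if report.s is not None and report.r is not None:
            report.q = {g: weighted_quality(report.s, report.r, g) for g in gammas}
    return report
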