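"""End-to-end desk-scale pipeline: simulate, synthesize, train, compare.

Wires every stage together the way the full study runs: simulate a white
reference and scenes, synthesize training pairs, build the patch dataset,
train the network, restore held-out images with all methods (raw pass-
through, median, Gaussian, interpolation, CNN) and score them with
PSNR/SSIM on the synthetic pairs plus smoothness / line separation /
weighted quality on a simulated bar target.

The default benchmark is a scaled-down analogue of the full protocol:
20 synthetic pairs at 256x256 (16 train / 4 validation), 2000 optimizer
steps.  The architecture, loss and patch geometry keep their published
values; the problem size and the training schedule are desk-scale
(batch 64, He-style fan-in initialization, SGD with momentum 0.9 and a
learning rate chosen for stable loss descent within the short budget).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import baselines, bundlesim, metrics, network, patches, synthesis

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "simulate_pairs",
    "restore_with",
    "acquire_bar_target",
    "compare_methods",
    "run_benchmark",
    "run_end_to_end",
]

METHODS = ("raw", "median", "gaussian", "interp", "harcnn")


@dataclass(frozen=True)
class RunConfig:
    """Desk-scale study conditions (see module docstring)."""

    image_size: tuple[int, int] = (256, 256)
    n_pairs: int = 20
    train_fraction: float = 0.8
    core_pitch: float = 5.5
    core_sigma: float = 1.1
    jitter_sigma: float = 0.3
    intensity_jitter: float = 0.2
    texture_lengths: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0)
    bar_period: float = 6.0
    bar_aperture_sigma: float = 1.1
    bar_stray_floor: float = 0.05
    bar_noise_sigma: float = 0.015
    steps: int = 2000
    batch_size: int = 64
    lr: float = 0.05
    momentum: float = 0.9
    init: str = "he"
    median_size: int = 7
    gaussian_sigma: float = 3.0
    gammas: tuple[float, ...] = (0.5, 0.8)
    seed: int = 0

    def model_config(self) -> network.ModelConfig:
        return network.ModelConfig(
            lr=self.lr, momentum=self.momentum, init=self.init,
            batch_size=self.batch_size, iterations=self.steps,
            seed=self.seed, log_interval=max(1, self.steps // 20),
        )

    def bundle_spec(self) -> bundlesim.BundleSpec:
        return bundlesim.BundleSpec(
            image_size=self.image_size, core_pitch=self.core_pitch,
            core_sigma=self.core_sigma, jitter_sigma=self.jitter_sigma,
            intensity_jitter=self.intensity_jitter, seed=self.seed,
        )


def simulate_pairs(
    config: RunConfig,
) -> tuple[bundlesim.WhiteReference, list[synthesis.SyntheticPair]]:
    """One white reference plus ``n_pairs`` texture-scene synthetic pairs.

    Scenes are smooth random textures at a rotation of correlation
    lengths, contrast-stretched to the full unit interval the way ordinary
    photographs span their dynamic range.
    """
    ref = bundlesim.generate_reference(config.bundle_spec())
    pairs = []
    for i in range(config.n_pairs):
        corr = config.texture_lengths[i % len(config.texture_lengths)]
        scene = bundlesim.generate_texture(
            config.image_size, correlation_length=corr,
            seed=config.seed * 100_003 + i, normalize="stretch")
        pairs.append(synthesis.synthesize(scene, ref, image_id=f"tex-{i}"))
    return ref, pairs


def restore_with(
    method: str,
    image: np.ndarray,
    params: network.ModelParams | None = None,
    cores: baselines.CoreMap | None = None,
    median_size: int = 7,
    gaussian_sigma: float = 3.0,
) -> np.ndarray:
    """Dispatch one restoration method on one raw bundle image."""
    if method == "raw":
        return np.asarray(image, dtype=np.float64)
    if method == "median":
        return baselines.median_restore(image, size=median_size)
    if method == "gaussian":
        return baselines.gaussian_restore(image, sigma=gaussian_sigma)
    if method == "interp":
        if cores is None:
            raise ValueError("interp needs a CoreMap")
        return baselines.interpolation_restore(image, cores)
    if method == "harcnn":
        if params is None:
            raise ValueError("harcnn needs trained ModelParams")
        return network.restore(params, image)
    raise ValueError(f"unknown method {method!r}")


def acquire_bar_target(
    ref: bundlesim.WhiteReference, config: RunConfig,
) -> tuple[np.ndarray, dict[str, metrics.RegionSpec]]:
    """Simulate a real acquisition of the bar target through the bundle.

    Unlike training-pair synthesis (a bare reference multiplication, as
    published), a physical acquisition sees three first-order effects:
    each core integrates the scene over its finite aperture (Gaussian
    pre-blur of width ``bar_aperture_sigma``), diffuse stray light adds a
    constant floor inside the FOV, and the sensor adds Gaussian read/shot
    noise.  Without these the line-separation measure degenerates
    (exact-zero dark bars pin min(Sl) = 0, so r saturates at 1).
    """
    scene, regions = bundlesim.generate_bar_target(
        config.image_size, bar_period=config.bar_period)
    pair = synthesis.synthesize(scene, ref, image_id="bar-target",
                                aperture_sigma=config.bar_aperture_sigma)
    mask = synthesis.make_circular_mask(config.image_size)
    rng = np.random.default_rng(config.seed + 500_009)
    raw = pair.bundle_image + config.bar_stray_floor * mask
    if config.bar_noise_sigma > 0:
        raw = raw + config.bar_noise_sigma * rng.standard_normal(
            config.image_size) * mask
    return np.clip(raw, 0.0, 1.0), regions


def compare_methods(
    val: list[synthesis.SyntheticPair],
    bar_raw: np.ndarray,
    bar_regions: dict[str, metrics.RegionSpec],
    params: network.ModelParams,
    cores: baselines.CoreMap,
    config: RunConfig,
) -> dict[str, dict[str, float]]:
    """Score every method: mean PSNR/SSIM over the validation pairs and
    s / r / q(gamma) on the simulated bar-target acquisition."""
    results: dict[str, dict[str, float]] = {}
    for method in METHODS:
        t0 = time.perf_counter()
        psnrs, ssims = [], []
        for pair in val:
            restored = restore_with(
                method, pair.bundle_image, params=params, cores=cores,
                median_size=config.median_size,
                gaussian_sigma=config.gaussian_sigma)
            psnrs.append(metrics.psnr(pair.ground_truth, restored))
            ssims.append(metrics.ssim(pair.ground_truth, restored))
        bar_restored = restore_with(
            method, bar_raw, params=params, cores=cores,
            median_size=config.median_size,
            gaussian_sigma=config.gaussian_sigma)
        s = metrics.smoothness(bar_raw, bar_restored, bar_regions["flat"])
        r = metrics.line_separation(bar_restored, bar_regions["lines"])
        row = {
            "psnr": float(np.mean(psnrs)),
            "ssim": float(np.mean(ssims)),
            "s": s,
            "r": r,
        }
        for g in config.gammas:
            row[f"q{g}"] = metrics.weighted_quality(s, r, g)
        results[method] = row
        logger.info("%s scored in %.1fs: %s", method,
                    time.perf_counter() - t0, row)
    return results


def run_benchmark(config: RunConfig | None = None) -> dict:
    """Full scaled-down study; returns every intermediate artifact."""
    config = config or RunConfig()
    ref, pairs = simulate_pairs(config)
    n_train = int(round(config.train_fraction * len(pairs)))
    train_ds, val = patches.build_dataset(
        pairs, split=(n_train, len(pairs) - n_train), seed=config.seed)
    logger.info("training on %d patches from %d images", len(train_ds), n_train)
    params, history = network.train(config.model_config(), train_ds, val=val)

    cores = baselines.detect_cores(ref)
    bar_raw, bar_regions = acquire_bar_target(ref, config)
    results = compare_methods(val, bar_raw, bar_regions, params, cores, config)
    return {
        "config": config,
        "reference": ref,
        "pairs": pairs,
        "train_dataset": train_ds,
        "val": val,
        "params": params,
        "history": history,
        "cores": cores,
        "bar_raw": bar_raw,
        "bar_regions": bar_regions,
        "results": results,
    }


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha1(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:12]


def run_end_to_end(config: RunConfig | None = None,
                   outdir: str | Path = "debundle-run") -> dict:
    """Run the benchmark and persist a comparison table plus manifest.

    Writes ``comparison.csv`` (one row per method), ``model.bin``,
    ``history.json`` and ``manifest.json`` (config, its hash, seed) into
    ``outdir`` — enough to reproduce the run.
    """
    from . import __version__

    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bench = run_benchmark(config)

    results = bench["results"]
    fields = ["method", "psnr", "ssim", "s", "r"] + [
        f"q{g}" for g in config.gammas]
    with open(outdir / "comparison.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for method in METHODS:
            writer.writerow({"method": method, **{
                k: f"{v:.4f}" for k, v in results[method].items()}})
    network.save_model(bench["params"], outdir / "model.bin")
    with open(outdir / "history.json", "w") as fh:
        json.dump(bench["history"], fh)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        }, fh, indent=2)
    logger.info("artifacts written to %s", outdir)
    return bench
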