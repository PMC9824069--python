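"""Sub-image decomposition for network training.

Training operates on aligned 33x33 (input, target) sub-images cut from each
synthetic pair on a stride-14 grid.  Start offsets are the multiples of the
stride that keep the patch inside the image, plus a final boundary-aligned
start so the last rows/columns are always covered; on a 1024-pixel axis
this yields 72 starts and hence 5184 patches per image.  The train/
validation split is done at image level so no patch of a validation image
leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthesis import SyntheticPair

__all__ = [
    "PatchDataset",
    "patch_starts",
    "extract_patches",
    "place_back",
    "build_dataset",
]

PATCH_SIZE = 33
PATCH_STRIDE = 14


@dataclass
class PatchDataset:
    """Aligned stacks of (input, target) patches with provenance.

    ``inputs`` are bundle-image patches, ``targets`` the corresponding
    ground-truth patches, both float32 of shape (N, p, p).  ``provenance``
    records one ``(image_id, row_start, col_start)`` triple per patch.
    """

    inputs: np.ndarray
    targets: np.ndarray
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float32)
        self.targets = np.asarray(self.targets, dtype=np.float32)
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must have equal shapes")
        if len(self.provenance) not in (0, len(self.inputs)):
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def image_ids(self) -> set[str]:
        return {p[0] for p in self.provenance}

    def extend(self, other: "PatchDataset") -> "PatchDataset":
        return PatchDataset(
            np.concatenate([self.inputs, other.inputs]),
            np.concatenate([self.targets, other.targets]),
            self.provenance + other.provenance,
        )

    def save(self, path) -> None:
        ids = np.array([p[0] for p in self.provenance])
        rows = np.array([p[1] for p in self.provenance], dtype=np.int64)
        cols = np.array([p[2] for p in self.provenance], dtype=np.int64)
        np.savez_compressed(path, inputs=self.inputs, targets=self.targets,
                            image_ids=ids, rows=rows, cols=cols)

    @classmethod
    def load(cls, path) -> "PatchDataset":
        with np.load(path, allow_pickle=False) as z:
            prov = list(zip(z["image_ids"].tolist(),
                            z["rows"].tolist(), z["cols"].tolist()))
            return cls(z["inputs"], z["targets"], prov)


def patch_starts(length: int, patch: int = PATCH_SIZE,
                 stride: int = PATCH_STRIDE) -> list[int]:
    """Start offsets along one axis: stride multiples plus the aligned tail.

    ``{0, stride, 2*stride, ...} <= length - patch`` with ``length - patch``
    appended when it is not already a multiple of the stride, so coverage
    always reaches the boundary.
    """
    if patch > length:
        raise ValueError("patch larger than axis length")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = list(range(0, length - patch + 1, stride))
    if starts[-1] != length - patch:
        starts.append(length - patch)
    return starts


def extract_patches(pair: SyntheticPair, patch: int = PATCH_SIZE,
                    stride: int = PATCH_STRIDE,
                    image_id: str | None = None) -> PatchDataset:
    """Cut one synthetic pair into aligned (input, target) patches."""
    h, w = pair.bundle_image.shape
    rows = patch_starts(h, patch, stride)
    cols = patch_starts(w, patch, stride)
    img_id = image_id or pair.image_id or "image"
    n = len(rows) * len(cols)
    inputs = np.empty((n, patch, patch), dtype=np.float32)
    targets = np.empty((n, patch, patch), dtype=np.float32)
    prov: list[tuple[str, int, int]] = []
    k = 0
    for r in rows:
        for c in cols:
            inputs[k] = pair.bundle_image[r : r + patch, c : c + patch]
            targets[k] = pair.ground_truth[r : r + patch, c : c + patch]
            prov.append((img_id, r, c))
            k += 1
    return PatchDataset(inputs, targets, prov)


def place_back(patches: np.ndarray, provenance: list[tuple[str, int, int]],
               shape: tuple[int, int]) -> np.ndarray:
    """Reassemble patches onto a canvas, averaging overlapping pixels.

    The inverse of :func:`extract_patches` for a single image; with the
    boundary-aligned start convention coverage is total, so the original
    raster is reproduced exactly wherever patches agree.
    """
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    p = patches.shape[1]
    for tile, (_, r, c) in zip(patches, provenance):
        acc[r : r + p, c : c + p] += tile
        cnt[r : r + p, c : c + p] += 1.0
    out = np.zeros(shape, dtype=np.float64)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out


def build_dataset(
    pairs: list[SyntheticPair],
    split: float | tuple[int, int] = 100 / 130,
    seed: int = 0,
    patch: int = PATCH_SIZE,
    stride: int = PATCH_STRIDE,
) -> tuple[PatchDataset, list[SyntheticPair]]:
    """Image-level train/validation split, then patchify the training side.

    ``split`` is either the training fraction or an explicit
    ``(n_train, n_val)`` pair.  Validation images are kept whole for
    full-image PSNR/SSIM evaluation.  The shuffle is seeded, so the split
    is reproducible.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split")
    n = len(pairs)
    if isinstance(split, tuple):
        n_train, n_val = split
        if n_train + n_val != n:
            raise ValueError("explicit split does not sum to len(pairs)")
    else:
        n_train = int(round(split * n))
        n_val = n - n_train
    if n_train < 1 or n_val < 1:
        raise ValueError("split leaves one side empty")

    order = np.random.default_rng(seed).permutation(n)
    train_idx, val_idx = order[:n_train], order[n_train:]
    train = None
    for i in train_idx:
        ds = extract_patches(pairs[i], patch, stride,
                             image_id=pairs[i].image_id or f"img-{i}")
        train = ds if train is None else train.extend(ds)
    val = [pairs[i] for i in val_idx]
    for i in val_idx:
        if pairs[i].image_id is None:
            pairs[i].image_id = f"img-{i}"
    return train, val
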